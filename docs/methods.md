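# Methods

## Model

All stages assume the single-trait animal model

    y = Xb + u + e,    u ~ N(0, K sigma_a^2),    e ~ N(0, I sigma_e^2)

with one record per animal, `X` a full-rank reference-coded design for
herd, birth year/season and calving year/season, and `K` either the
pedigree numerator relationship matrix **A** or the VanRaden genomic
matrix **G**.  Marker-based prediction operates on adjusted phenotypes
`yc = y − X(X'X)⁻¹X'y`: ordinary-least-squares residuals of the fixed
effects only.  The random effect is deliberately not removed in this
adjustment — the downstream models re-estimate it — and the OLS fit uses
all phenotyped animals at once.  This mirrors the two-stage workflow that
is standard in applied genomic evaluation; it does leak a small amount of
information between cross-validation folds through the shared fixed-effect
estimates, which matters only at the O(p/n) level.

## Synthetic data

The generator emulates a commercial Hanwoo cow population typed on a 50K
bovine chip.  Genotypes are Binomial(2, p) per SNP under Hardy–Weinberg
proportions with p ~ Uniform(0.05, 0.5), assigned round-robin to 29
autosomes.  Markers are in linkage equilibrium: this keeps every variance
expectation analytic (Var(u) = Σ 2pᵢqᵢ gᵢ²) and makes oracle tests exact,
at the cost of not reproducing LD-driven phenomena (effective marker count,
LD decay of accuracy across generations).  Breeding values for genotyped
animals are marker-realized, u = (calls − 2p)g, so samplers are evaluated
against the exact quantity they model; without genotypes, u is drawn from
N(0, A sigma_a^2) on the pedigree.

Trait archetypes (mean, SD, h², envelope) are calibrated to the four
reproductive traits of the genotyped Hanwoo cohort: AFC (736.18 d, 64.43,
h² 0.070), CI (370.56, 40.04, 0.026), GL (286.62, 4.91, 0.102), NAIPC
(1.44, 0.79, 0.055).  Fixed effects contribute 10% of the phenotypic
variance, split equally over the five factors (nine herds, eight years,
four seasons); h² is defined net of fixed effects, sigma_a² =
h²·0.9·SD².  NAIPC is generated on a latent Gaussian and discretized to an
integer ≥ 1 by shifted rounding, then analyzed as Gaussian, as linear-model
treatments of insemination counts do.  Discretization attenuates the
realized heritability slightly, which the analysis is *not* told about.

Planted defects (monomorphic SNPs, low-call-rate SNPs at ~0.3–0.45 call
rate, heterozygote-free HWE violators, duplicated animals) are recorded in
a manifest that the QC cascade must reproduce exactly.

What passing tests do show: unbiasedness and calibration of every
estimator under the assumed model at desk scale.  What they do not show:
behaviour under LD, selection, heterogeneous variances or pedigree errors
found in real data.

## Quality control

Cascade order: map exclusions (non-autosomal / duplicate positions) →
caller-supplied pedigree-discordant animals → MAF < 0.05 → SNP call rate
< 0.90 → animal call rate < 0.90 → exact HWE p < 10⁻⁶ → IBS similarity
> 0.99.  Statistics are recomputed on the surviving set after animal
removals; the report telescopes and re-running the cascade on its own
output removes nothing.  The HWE test is the exact conditional test
(enumeration of heterozygote counts given allele counts, summing
configurations no more probable than the observed), matching the PLINK
toolchain; the asymptotic chi-square is available as a cross-check.
QC write-ups occasionally describe the HWE cut as excluding "p > alpha";
taken literally that would discard nearly the whole panel, so the
conventional direction (exclude p < alpha) is implemented.  Within an IBS
duplicate pair the lower-call-rate animal is removed (ties: the
later-indexed one).

## REML

`fit_reml` maximizes the restricted likelihood over (sigma_a², sigma_e²)
by average-information updates with step-halving, falling back to the EM
update (always inside the parameter space) when the AI step fails or
degrades the likelihood.  A single symmetric eigendecomposition of K
rotates the model so every iteration costs O(n p²); a precomputed
eigenbasis can be shared across traits on the same kinship.  Variances are
kept non-negative by boundary projection — not a log reparameterization —
so sigma_a² = 0 is reachable, which matters for null and very-low-h²
traits.  Convergence: change in restricted log-likelihood < 1e-8 and
relative parameter change < 1e-6, max 200 iterations.  SE(h²) comes from
the inverse AI matrix by the delta method.  A kinship numerically
proportional to the identity is flagged unidentifiable rather than fitted.

## GBLUP and SNP-BLUP

GBLUP solves the training system V = sigma_g² G_tt + sigma_e² I with a GLS
mean and carries all animals in G through the genomic covariances
(`joint`), or equivalently predicts validation animals as
G_vt G_tt⁻¹ ĝ_train (`condition`); both paths are exposed and tested equal.
The ridge-regression SNP-BLUP with per-marker variance sigma_g²/2Σpq is an
independent solution path kept solely as a test oracle for the model
equivalence.  G is built once on all genotyped animals with global allele
frequencies; inside cross-validation only phenotypes are masked.  This
shares genotype (not phenotype) information across folds, exactly as a
single-GRM workflow does.

## Bayesian samplers

All three samplers share the regression yc = 1mu + Z g + e on
frequency-centered dosages, a sampled mean, and a flat scaled-inverse-chi²
residual update, with single-site sweeps and residual updating.  Numba
compiles the kernels; Z is held in float32 (the sweeps are memory-bound)
with float64 accumulators.  Chains are bit-reproducible given seed,
settings and data.

* **BayesB**: locus indicator and variance move by independence
  Metropolis–Hastings from the prior (pi = 0.95 default; scaled-inv-chi²
  with nu = 4.2), accepting on the marginal likelihood of the locus with
  the effect integrated out; the effect is then drawn from its normal full
  conditional.  The prior scale S is derived from a target genetic
  variance: E[sigma_gi²] = var_g/((1−pi)Σ2pq).
* **BayesLASSO**: Park–Casella scale mixture; gi ~ N(0, tau_i²),
  tau_i² ~ Exp(lambda²/2), 1/tau_i² inverse-Gaussian full conditional,
  lambda² Gamma full conditional (weakly-informative hyperprior centered
  on the value implied by the target genetic variance).  tau_i² is floored
  at 1e-12 with a counter.
* **BayesR**: four-component normal mixture with variance multipliers
  (0, 1e-4, 1e-3, 1e-2)·sigma_g²; categorical membership from the
  marginal likelihood, Dirichlet(1,1,1,1)-updated proportions, and
  sigma_g² resampled each iteration from a scaled-inv-chi² (nu0 = 4)
  anchored on the target genetic variance so the component variances
  rescale with the chain.  Fixed-sigma_g², fixed-proportion, fixed-mean
  and fixed-residual modes exist; the last two make the sampler exactly
  comparable to a brute-force enumerated posterior on toy problems, which
  the suite exploits (total-variation distance < 0.05 on a 2-SNP,
  10-animal fixture).

The default target genetic variance is half the phenotypic variance; in
the cross-validation study it is set to the REML estimate for the trait,
which is how these samplers are parameterized in practice.  One honest
caveat: with 10⁻⁴·sigma_g² as the smallest non-null component, that
component is likelihood-indistinguishable from the point mass at desk (and
even at 50K-chip) scale, so the mixture proportion on the null component
is only weakly identified under a null trait.  Null behaviour is therefore
asserted on identified quantities — the fitted genomic variance and the
inclusion probabilities — not on the proportions themselves.

Chain-length profiles: production 41,000 iterations / 1,000 burn-in /
thin 100 (400 retained); desk profile 4,100 / 100 / 10 for tests and
recovery checks; the cross-validation study uses 1,200 / 200 / 10, at
which point fold accuracy is dominated by validation-set noise rather than
Monte Carlo error.

The per-method genomic variance is the across-animal variance of Zg per
retained draw, averaged over draws; the linkage-equilibrium estimator
Σ2pᵢqᵢ E[gᵢ²] agrees within 10% on equilibrium panels and is kept as a
cross-check.

## Cross-validation and reporting

`make_folds` deals animals into k near-equal folds, independently per
repetition.  Accuracy is Pearson r between validation adjusted phenotypes
and GEBVs divided by sqrt(h²) of the trait — the pedigree/design
heritability, fixed across folds — and can exceed 1 (not clipped).  Bias
is the OLS slope of (adjusted) phenotype on GEBV.  The empirical SE is the
SD of the k fold accuracies divided by sqrt(k), averaged over repetitions.
A failing fold is logged and skipped; completeness is reported rather than
aborting a long run.

The desk-scale study in the acceptance suite uses n = 1,500 animals and
m = 3,000 markers with all four trait archetypes: GBLUP runs the full
10 × 5-fold protocol with REML variance components estimated once per
trait; the three samplers run 2 × 5 folds with the short chain profile.
At this scale the accuracy of a single method × trait cell carries a
sampling SD of roughly 0.05–0.15 (largest for CI, h² = 0.026), an order of
magnitude larger than in a 100-repetition study on 11k animals — the
regime check is therefore meaningful in aggregate but individual low-h²
cells sit within noise of zero.

## Numerical choices

* Missing genotype sentinel −9; mean imputation (2p) only at modeling
  time, never at I/O time.
* Minor-allele coding with lexicographic tie-break; the generator emits
  panels already in canonical minor-allele form so PLINK round-trips are
  exact identities.
* G inversion adds a 1e-6 diagonal ridge only when the plain Cholesky
  fails, and logs it.
* Exact HWE probabilities use the standard two-sided recurrence; agreement
  with a rational-arithmetic enumeration is 1e-12 or better for n ≤ 200.
* All randomness flows from explicit integer seeds; numpy `SeedSequence`
  spawning derives per-repetition and per-fold streams.

## Known limitations

Linkage equilibrium only by default (no LD block mode yet); single-trait
models only; the exact HWE test assumes autosomal biallelic markers; the
CLI stores matrices as `.npy` with id sidecars rather than a portable
binary standard; NAIPC's integer support is modeled only through the
latent-Gaussian approximation.
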