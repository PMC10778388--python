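# gselect

Genomic prediction toolkit for low-heritability reproductive traits in
beef cattle, modeled on the data regime of commercial Korean Hanwoo cow
populations typed on a ~50K SNP chip.

Breeders of monotocous livestock care about traits like age at first
calving (AFC), calving interval (CI), gestation length (GL) and the number
of artificial inseminations per conception (NAIPC).  These traits have
heritabilities in the 0.03–0.10 range, so marker-based selection is both
attractive (phenotypes accrue slowly) and statistically hard (weak signal).
`gselect` implements the full analysis pipeline used to study this setting:

* **Synthetic data** — genotypes in Hardy–Weinberg linkage equilibrium on 29
  autosomes, discrete-generation pedigrees, herd/year/season fixed effects,
  and trait archetypes calibrated to the four reproductive traits above.
* **Quality control** — MAF, SNP/animal call rate, exact Hardy–Weinberg
  test, identity-by-state duplicate detection; ordered cascade with a
  telescoping removal ledger.
* **Relationship matrices** — pedigree numerator matrix **A** (tabular
  method with inbreeding) and VanRaden genomic matrix
  **G** = MM′ / 2Σpᵢ(1−pᵢ).
* **Variance components** — average-information REML for the single-trait
  animal model y = Xb + u + e, u ~ N(0, Aσ²ₐ), plus fixed-effect-adjusted
  phenotypes y_c = y − X(X′X)⁻¹X′y.
* **GBLUP** — mixed-model GEBVs from G, algebraically identical to
  ridge-regression SNP-BLUP (tested).
* **Bayesian alphabet** — from-scratch MCMC samplers for BayesB (point mass
  + scaled-t), BayesLASSO (double exponential) and BayesR (four-component
  normal mixture with variances (0, 10⁻⁴, 10⁻³, 10⁻²)·σ²_g).
* **Evaluation** — repeated fivefold cross-validation; accuracy
  r(y_c, GEBV)/√h², bias slope of phenotype on GEBV, empirical SEs, and
  genomic heritability h²_g = h²·σ²_g/σ²ₐ.

## Worked example

```python
import numpy as np, gselect as gs

gm, phenos, truth = gs.simulate_study(1000, 1500, seed=3)  # four traits
G = gs.build_grm(gm)

des = gs.build_design(phenos, "gl")
y = phenos.frame.set_index("animal_id").loc[list(des.animal_ids), "gl"]
yc = gs.adjust_phenotypes(y, des).values.rename("gl")

est = gs.fit_reml(yc.to_numpy(), np.ones((len(yc), 1)), G, ids=list(yc.index))
print(f"h2 = {est.h2:.3f} (sigma_a2 = {est.sigma_a2:.2f}, "
      f"sigma_e2 = {est.sigma_e2:.2f})")

folds = gs.make_folds(list(yc.index), k=5, repetitions=5, seed=1)
res = gs.cross_validate(yc, "gblup", folds, truth["gl"].h2_true, G=G,
                        gblup_variances=(est.sigma_a2, est.sigma_e2))
print(f"accuracy = {res.mean_accuracy:.3f} +/- {res.empirical_se:.3f}, "
      f"bias = {res.mean_bias:.2f}")
```

Output from this exact script:

```
h2 = 0.101 (sigma_a2 = 1.98, sigma_e2 = 17.72)
accuracy = 0.267 +/- 0.100, bias = 1.15
```

The REML heritability (0.101) recovers the generating value (0.102) for
gestation length.  The cross-validated accuracy of 0.27 is typical of the
low-heritability regime: positive and useful, far from the ceiling of 1.
A bias slope near 1 means the GEBVs are on the right scale.  At this
sample size a single replicate is noisy — other simulation seeds give
heritabilities from ~0.06 to ~0.25 and accuracies from ~0.1 to ~0.5.

The same pipeline is scriptable from the shell (`gselect simulate`,
`qc`, `grm`, `nrm`, `reml`, `adjust`, `cv`); every subcommand logs its
resolved configuration and seed and is deterministic given both.

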