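"""Bayesian whole-genome regression: BayesB, BayesLASSO and BayesR.

All three fit yc = 1 mu + sum_i z_i g_i + e on frequency-centered marker
covariates and differ only in the prior on the marker effects:

* BayesB — point mass at zero with probability pi, scaled-inverse-chi-square
  locus variance otherwise (effects marginally scaled-t); locus inclusion
  and variance move by independence Metropolis-Hastings on the marginal
  likelihood, the effect by its normal full conditional.
* BayesLASSO — double-exponential effects via the normal / exponential
  scale-mixture; all full conditionals are conjugate (Gibbs), with the
  penalty lambda^2 given a Gamma hyperprior.
* BayesR — four-component normal mixture with variances
  (0, 1e-4, 1e-3, 1e-2) x sigma_g^2, Dirichlet-updated proportions and a
  rescaled sigma_g^2 each iteration.

Chains are bit-reproducible given (seed, settings, data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _samplers
from .synthetic_data import DEFAULT_MULTIPLIERS


class SamplerError(RuntimeError):
    pass


@dataclass
class MCMCSettings:
    """Chain length controls; defaults match a full-scale production run."""

    iterations: int = 41_000
    burn_in: int = 1_000
    thinning: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


#: shortened settings for desk-scale runs and continuous testing
DESK_MCMC = dict(iterations=4_100, burn_in=100, thinning=10)


@dataclass
class BayesBPrior:
    pi: float = 0.95
    nu: float = 4.2
    scale: float | None = None  # derived from genetic_variance when None
    genetic_variance: float | None = None  # default: half of var(yc)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi < 1.0:
            raise ValueError("pi must lie in [0, 1); pi = 1 is degenerate")
        if self.nu <= 2.0:
            raise ValueError("nu must exceed 2 for a finite prior mean")


@dataclass
class BayesLassoPrior:
    lambda2: float | None = None      # initial / fixed penalty; derived when None
    sample_lambda: bool = True
    shape: float = 1.0                # Gamma hyperprior on lambda^2
    rate: float | None = None         # default: shape / lambda2_init
    genetic_variance: float | None = None


@dataclass
class BayesRPrior:
    multipliers: tuple = DEFAULT_MULTIPLIERS
    proportions: tuple = (0.25, 0.25, 0.25, 0.25)
    nu0: float = 4.0
    genetic_variance: float | None = None
    sample_sigma_g2: bool = True
    sample_proportions: bool = True
    sample_mu: bool = True
    sample_sigma_e2: bool = True
    sigma_e2: float | None = None  # initial (or fixed) residual variance

    def __post_init__(self) -> None:
        if list(self.multipliers) != sorted(self.multipliers):
            raise ValueError("variance multipliers must be ordered")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")


@dataclass
class MarkerPosterior:
    effect_mean: np.ndarray
    effect_var: np.ndarray
    samples: np.ndarray               # retained iterations x SNPs
    inclusion: np.ndarray | None = None       # BayesB
    component_probs: np.ndarray | None = None  # BayesR, SNPs x 4
    extras: dict = field(default_factory=dict)


@dataclass
class PredictionResult:
    gebv: pd.Series
    mu: float
    sigma_g2_hat: float
    sigma_e2_hat: float
    settings: MCMCSettings


def _prepare(yc_train, Z_train):
    if isinstance(yc_train, pd.Series):
        ids = np.asarray(yc_train.index, dtype=object)
        y = yc_train.to_numpy(dtype=float)
    else:
        y = np.asarray(yc_train, dtype=float)
        ids = np.arange(y.size)
    # float32 marker matrix: the sweeps are memory-bound and the kernels
    # accumulate in float64, so this costs no meaningful precision
    Z = np.asfortranarray(np.asarray(Z_train), dtype=np.float32)
    if Z.shape[0] != y.size:
        raise ValueError("Z rows must match phenotype length")
    if not np.isfinite(Z).all():
        raise ValueError("Z contains non-finite entries")
    zsq = np.einsum("ij,ij->j", Z, Z, dtype=np.float64)
    sum2pq = float(zsq.sum()) / Z.shape[0]
    return y, ids, Z, zsq, sum2pq


def _check(err_iter: int, name: str) -> None:
    if err_iter >= 0:
        raise SamplerError(f"{name} chain became non-finite at iteration {err_iter}")


def genomic_variance_from_samples(samples: np.ndarray, Z: np.ndarray) -> float:
    """Mean over retained iterations of the across-animal variance of Z g(t)."""
    samples = np.asarray(samples, dtype=float)
    if samples.shape[0] < 2:
        raise ValueError("need at least 2 retained samples")
    U = np.asarray(Z, dtype=float) @ samples.T  # animals x iterations
    return float(np.var(U, axis=0, ddof=1).mean())


def genomic_variance_sum2pq(samples: np.ndarray, p: np.ndarray) -> float:
    """Alternative estimator sum_i 2 p_i q_i E[g_i^2] (linkage-equilibrium form)."""
    w = 2.0 * np.asarray(p) * (1.0 - np.asarray(p))
    return float(w @ np.mean(np.asarray(samples) ** 2, axis=0))


def run_bayesb(yc_train, Z_train, prior: BayesBPrior | None = None,
               settings: MCMCSettings | None = None):
    prior = prior or BayesBPrior()
    settings = settings or MCMCSettings()
    y, ids, Z, zsq, sum2pq = _prepare(yc_train, Z_train)
    var_g = prior.genetic_variance if prior.genetic_variance is not None \
        else 0.5 * float(np.var(y, ddof=1))
    scale = prior.scale
    if scale is None:
        e_locus = var_g / max((1.0 - prior.pi) * sum2pq, 1e-12)
        scale = e_locus * (prior.nu - 2.0) / prior.nu
    g_out, mu_out, sige_out, incl, err = _samplers.bayesb_kernel(
        y, Z, zsq, prior.pi, prior.nu, scale,
        settings.iterations, settings.burn_in, settings.thinning,
        settings.seed % 2**31)
    _check(err, "BayesB")
    post = MarkerPosterior(g_out.mean(axis=0), g_out.var(axis=0, ddof=1),
                           g_out, inclusion=incl,
                           extras={"scale": scale, "pi": prior.pi})
    pred = PredictionResult(pd.Series(Z @ post.effect_mean, index=ids),
                            float(mu_out.mean()),
                            genomic_variance_from_samples(g_out, Z),
                            float(sige_out.mean()), settings)
    return post, pred


def run_bayeslasso(yc_train, Z_train, prior: BayesLassoPrior | None = None,
                   settings: MCMCSettings | None = None):
    prior = prior or BayesLassoPrior()
    settings = settings or MCMCSettings()
    y, ids, Z, zsq, sum2pq = _prepare(yc_train, Z_train)
    var_g = prior.genetic_variance if prior.genetic_variance is not None \
        else 0.5 * float(np.var(y, ddof=1))
    lam2 = prior.lambda2
    if lam2 is None:
        # prior mean per-locus variance 2/lambda^2 matched to var_g / sum2pq
        lam2 = 2.0 * sum2pq / max(var_g, 1e-12)
    rate = prior.rate if prior.rate is not None else prior.shape / lam2
    g_out, mu_out, sige_out, lam2_out, n_floor, err = _samplers.bayeslasso_kernel(
        y, Z, zsq, lam2, prior.shape, rate, int(prior.sample_lambda),
        settings.iterations, settings.burn_in, settings.thinning,
        settings.seed % 2**31)
    _check(err, "BayesLASSO")
    post = MarkerPosterior(g_out.mean(axis=0), g_out.var(axis=0, ddof=1), g_out,
                           extras={"lambda2_samples": lam2_out,
                                   "tau2_floor_events": int(n_floor)})
    pred = PredictionResult(pd.Series(Z @ post.effect_mean, index=ids),
                            float(mu_out.mean()),
                            genomic_variance_from_samples(g_out, Z),
                            float(sige_out.mean()), settings)
    return post, pred


def run_bayesr(yc_train, Z_train, prior: BayesRPrior | None = None,
               settings: MCMCSettings | None = None):
    prior = prior or BayesRPrior()
    settings = settings or MCMCSettings()
    y, ids, Z, zsq, sum2pq = _prepare(yc_train, Z_train)
    var_g = prior.genetic_variance if prior.genetic_variance is not None \
        else 0.5 * float(np.var(y, ddof=1))
    nu0 = prior.nu0
    S0 = var_g * (nu0 - 2.0) / nu0
    gam = np.asarray(prior.multipliers, dtype=float)
    pi0 = np.asarray(prior.proportions, dtype=float)
    (g_out, mu_out, sige_out, sigg_out, pi_out, comp_probs, err) = \
        _samplers.bayesr_kernel(
            y, Z, zsq, gam, pi0, nu0, S0,
            int(prior.sample_sigma_g2), int(prior.sample_proportions),
            int(prior.sample_mu), int(prior.sample_sigma_e2),
            -1.0 if prior.sigma_e2 is None else float(prior.sigma_e2),
            settings.iterations, settings.burn_in, settings.thinning,
            settings.seed % 2**31)
    _check(err, "BayesR")
    post = MarkerPosterior(g_out.mean(axis=0), g_out.var(axis=0, ddof=1), g_out,
                           component_probs=comp_probs,
                           extras={"multipliers": tuple(gam),
                                   "pi_samples": pi_out,
                                   "sigma_g2_scale_samples": sigg_out})
    pred = PredictionResult(pd.Series(Z @ post.effect_mean, index=ids),
                            float(mu_out.mean()),
                            genomic_variance_from_samples(g_out, Z),
                            float(sige_out.mean()), settings)
    return post, pred


def predict_gebv(Z_any, posterior: MarkerPosterior) -> np.ndarray:
    """Posterior-mean GEBV for any centered genotype rows (e.g. validation)."""
    return np.asarray(Z_any, dtype=float) @ posterior.effect_mean


RUNNERS = {"bayesb": run_bayesb, "bayeslasso": run_bayeslasso, "bayesr": run_bayesr}
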