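"""Repeated k-fold cross-validation of GEBV accuracy, bias and genomic h2.

Accuracy is Pearson's correlation between validation-set adjusted
phenotypes and GEBVs divided by sqrt(h2) of the trait (the pedigree-based
heritability, fixed across folds), so values above 1 are possible and are
not clipped.  Bias is the OLS slope of phenotype on GEBV (1 = unbiased).
The empirical SE of a repetition is SD of its k fold accuracies / sqrt(k),
averaged over repetitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import DESK_MCMC, MCMCSettings, RUNNERS, predict_gebv
from .gblup import fit_gblup
from .relationship import RelationshipMatrix

log = logging.getLogger(__name__)

METHODS = ("gblup", "bayesb", "bayeslasso", "bayesr")


class EvaluationError(ValueError):
    pass


@dataclass
class FoldPlan:
    repetition: int
    assignment: pd.Series  # animal id -> fold in 1..k
    seed: int

    @property
    def k(self) -> int:
        return int(self.assignment.max())

    def validation_ids(self, fold: int) -> np.ndarray:
        return np.asarray(self.assignment.index[self.assignment == fold], dtype=object)

    def training_ids(self, fold: int) -> np.ndarray:
        return np.asarray(self.assignment.index[self.assignment != fold], dtype=object)


def make_folds(animal_ids, k: int = 5, repetitions: int = 1, seed: int = 0
               ) -> list[FoldPlan]:
    """Independent random partitions into k near-equal folds per repetition."""
    ids = np.asarray(animal_ids, dtype=object)
    n = ids.size
    if k > n:
        raise EvaluationError(f"k={k} exceeds {n} animals")
    plans = []
    for rep, ss in enumerate(np.random.SeedSequence(seed).spawn(repetitions)):
        rng = np.random.default_rng(ss)
        perm = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        # deal animals round-robin so fold sizes differ by at most 1
        folds[perm] = np.arange(n) % k + 1
        plans.append(FoldPlan(rep, pd.Series(folds, index=ids),
                              int(ss.generate_state(1)[0] % 2**31)))
    return plans


def accuracy(yc_val, gebv_val, h2: float) -> float:
    """cor(yc, GEBV) / sqrt(h2); undefined when either vector is constant."""
    if not 0.0 < h2 <= 1.0:
        raise EvaluationError("h2 must lie in (0, 1]")
    y = np.asarray(yc_val, dtype=float)
    g = np.asarray(gebv_val, dtype=float)
    if y.size < 3:
        raise EvaluationError("need at least 3 validation animals")
    if np.std(y) == 0.0 or np.std(g) == 0.0:
        raise EvaluationError("zero variance in validation fold")
    r = float(np.corrcoef(y, g)[0, 1])
    return r / float(np.sqrt(h2))


def bias_slope(phenotype_val, gebv_val) -> float:
    """OLS slope of phenotype on GEBV; <1 inflated, >1 deflated predictions."""
    y = np.asarray(phenotype_val, dtype=float)
    g = np.asarray(gebv_val, dtype=float)
    vg = np.var(g)
    if vg == 0.0:
        raise EvaluationError("zero GEBV variance; slope undefined")
    return float(np.cov(y, g, ddof=1)[0, 1] / np.var(g, ddof=1))


def genomic_h2(h2_pedigree: float, sigma_g2: float, sigma_a2: float
               ) -> tuple[float, float]:
    """Genomic heritability h2 * (sigma_g2 / sigma_a2) and the ratio itself."""
    if sigma_a2 <= 0:
        raise EvaluationError("sigma_a2 must be positive")
    ratio = sigma_g2 / sigma_a2
    return h2_pedigree * ratio, ratio


@dataclass
class CVResult:
    method: str
    trait: str
    records: pd.DataFrame   # repetition, fold, n_val, accuracy, bias, ok
    mean_accuracy: float
    empirical_se: float
    mean_bias: float
    completeness: float
    fold_sigma_g2: pd.Series | None = None


def cross_validate(yc: pd.Series, method: str, folds: list[FoldPlan], h2: float,
                   *, G: RelationshipMatrix | None = None,
                   Z: np.ndarray | None = None, z_ids=None,
                   gblup_variances: tuple | None = None,
                   mcmc: dict | None = None, prior=None,
                   bias_phenotype: pd.Series | None = None) -> CVResult:
    """Run repeated k-fold CV for one trait and one method.

    GBLUP needs ``G`` (built once on all genotyped animals with global
    frequencies; only phenotypes are masked per fold).  The Bayesian methods
    need the centered dosage matrix ``Z`` with ``z_ids`` giving its row ids.
    A failing fold is logged and skipped; completeness reports the fraction
    of folds that succeeded.
    """
    method = method.lower()
    if method not in METHODS:
        raise EvaluationError(f"unknown method {method!r}; choose from {METHODS}")
    if method == "gblup" and G is None:
        raise EvaluationError("GBLUP cross-validation requires G")
    if method != "gblup" and (Z is None or z_ids is None):
        raise EvaluationError(f"{method} cross-validation requires Z and z_ids")
    mcmc = dict(DESK_MCMC) if mcmc is None else dict(mcmc)
    bias_y = yc if bias_phenotype is None else bias_phenotype
    if Z is not None:
        zpos = {a: i for i, a in enumerate(np.asarray(z_ids, dtype=object))}

    rows = []
    fold_sg2 = {}
    for plan in folds:
        for fold in range(1, plan.k + 1):
            tr = [a for a in plan.training_ids(fold) if a in yc.index]
            va = [a for a in plan.validation_ids(fold) if a in yc.index]
            try:
                if method == "gblup":
                    res = fit_gblup(yc.loc[tr], G, tr, variances=gblup_variances)
                    gv = res.gebv.loc[va].to_numpy()
                    fold_sg2[(plan.repetition, fold)] = res.sigma_g2
                else:
                    seed = (plan.seed * 1000 + fold) % 2**31
                    settings = MCMCSettings(seed=seed, **mcmc)
                    post, pred = RUNNERS[method](
                        yc.loc[tr], Z[[zpos[a] for a in tr]], prior, settings)
                    gv = predict_gebv(Z[[zpos[a] for a in va]], post)
                    fold_sg2[(plan.repetition, fold)] = pred.sigma_g2_hat
                acc = accuracy(yc.loc[va], gv, h2)
                slope = bias_slope(bias_y.loc[va], gv)
                rows.append({"repetition": plan.repetition, "fold": fold,
                             "n_val": len(va), "accuracy": acc, "bias": slope,
                             "ok": True})
            except Exception as exc:  # a pathological fold must not kill the run
                log.warning("fold %d of repetition %d failed: %s",
                            fold, plan.repetition, exc)
                rows.append({"repetition": plan.repetition, "fold": fold,
                             "n_val": len(va), "accuracy": np.nan,
                             "bias": np.nan, "ok": False})
    rec = pd.DataFrame(rows)
    ok = rec[rec["ok"]]
    per_rep_se = ok.groupby("repetition")["accuracy"].agg(
        lambda a: a.std(ddof=1) / np.sqrt(len(a)))
    result = CVResult(
        method=method, trait=getattr(yc, "name", "") or "",
        records=rec,
        mean_accuracy=float(ok["accuracy"].mean()),
        empirical_se=float(per_rep_se.mean()),
        mean_bias=float(ok["bias"].mean()),
        completeness=float(len(ok)) / len(rec) if len(rec) else 0.0,
        fold_sigma_g2=pd.Series(fold_sg2) if fold_sg2 else None)
    if result.completeness < 1.0:
        log.warning("CV completeness %.0f%% for %s/%s",
                    100 * result.completeness, method, result.trait)
    return result


def report_tables(variance_estimates: dict | None = None,
                  genomic_variances: dict | None = None,
                  cv_results: list | None = None) -> dict[str, pd.DataFrame]:
    """Assemble the study's summary tables.

    * ``variance_components``: trait, h2, SE, sigma_a2, sigma_e2, sigma_p2
    * ``genomic_heritability``: method, trait, sigma_g2, sigma_g2/sigma_a2, hg2
    * ``accuracy`` / ``bias``: method x trait means with empirical SEs
    """
    tables: dict[str, pd.DataFrame] = {}
    if variance_estimates:
        rows = []
        for trait, est in variance_estimates.items():
            rows.append({"trait": trait, "h2": round(est.h2, 3),
                         "se": round(est.h2_se, 3) if np.isfinite(est.h2_se) else np.nan,
                         "sigma_a2": est.sigma_a2, "sigma_e2": est.sigma_e2,
                         "sigma_p2": est.sigma_p2})
        tables["variance_components"] = pd.DataFrame(rows)
    if genomic_variances and variance_estimates:
        rows = []
        for (method, trait), sg2 in genomic_variances.items():
            est = variance_estimates[trait]
            hg2, ratio = genomic_h2(est.h2, sg2, est.sigma_a2)
            rows.append({"method": method, "trait": trait, "sigma_g2": sg2,
                         "ratio": ratio, "hg2": hg2})
        tables["genomic_heritability"] = pd.DataFrame(rows)
    if cv_results:
        acc_rows, bias_rows = [], []
        for r in cv_results:
            acc_rows.append({"method": r.method, "trait": r.trait,
                             "accuracy": r.mean_accuracy, "se": r.empirical_se,
                             "completeness": r.completeness})
            bias_rows.append({"method": r.method, "trait": r.trait,
                              "bias": r.mean_bias})
        tables["accuracy"] = pd.DataFrame(acc_rows)
        tables["bias"] = pd.DataFrame(bias_rows)
    return tables


def write_report(tables: dict[str, pd.DataFrame], outdir) -> list:
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, frame in tables.items():
        p = out / f"{name}.csv"
        frame.to_csv(p, index=False, float_format="%.6g")
        paths.append(p)
    return paths
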