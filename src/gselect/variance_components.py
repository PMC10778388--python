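"""REML variance components for the single-trait animal model.

Model: y = Xb + u + e with u ~ N(0, K sigma_a^2) and e ~ N(0, I sigma_e^2),
K a pedigree (A) or genomic (G) relationship matrix with one record per
animal.  The restricted likelihood is maximized by average-information
(AI) updates with an EM fallback, performed in the eigenbasis of K so each
iteration is O(n p^2) after a single symmetric eigendecomposition.

Adjusted phenotypes are ordinary-least-squares residuals of the fixed
effects only, yc = y - X (X'X)^{-1} X'y; the random effect is deliberately
not subtracted, matching how adjusted phenotypes are commonly fed to
marker-based prediction models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .data_io import FIXED_FACTORS, PhenotypeTable

log = logging.getLogger(__name__)


@dataclass
class FixedEffectsDesign:
    """Full-rank reference-coded design matrix for the fixed effects."""

    X: np.ndarray
    animal_ids: np.ndarray
    columns: list
    dropped_factors: list = field(default_factory=list)


@dataclass
class VarianceEstimate:
    sigma_a2: float
    sigma_e2: float
    h2_se: float
    converged: bool
    n_iter: int
    loglik_trace: list = field(default_factory=list)
    boundary: bool = False
    identifiable: bool = True

    @property
    def sigma_p2(self) -> float:
        return self.sigma_a2 + self.sigma_e2

    @property
    def h2(self) -> float:
        return self.sigma_a2 / self.sigma_p2


@dataclass
class AdjustedPhenotypes:
    values: pd.Series
    design: FixedEffectsDesign


def build_design(phenos: PhenotypeTable, trait: str) -> FixedEffectsDesign:
    """Intercept plus reference-coded herd/year/season factors.

    Rows are the animals with a record for ``trait``; the first-observed
    level of each factor is the baseline.  Single-level factors are dropped
    with a warning rather than raising.
    """
    f = phenos.frame
    mask = f[trait].notna()
    sub = f.loc[mask]
    ids = sub["animal_id"].to_numpy(dtype=object)
    cols: list[str] = ["intercept"]
    blocks = [np.ones((len(sub), 1))]
    dropped = []
    for fac in FIXED_FACTORS:
        levels = list(dict.fromkeys(sub[fac]))  # first-observed order
        if len(levels) < 2:
            dropped.append(fac)
            log.warning("factor %s has a single level; dropped from design", fac)
            continue
        for lev in levels[1:]:
            blocks.append((sub[fac] == lev).to_numpy(dtype=float)[:, None])
            cols.append(f"{fac}[{lev}]")
    X = np.hstack(blocks)
    return FixedEffectsDesign(X, ids, cols, dropped)


def adjust_phenotypes(y, X_or_design) -> AdjustedPhenotypes:
    """OLS residuals yc = y - X(X'X)^{-1}X'y (pseudo-inverse if rank-deficient)."""
    design = X_or_design
    if not isinstance(design, FixedEffectsDesign):
        X = np.asarray(design, dtype=float)
        design = FixedEffectsDesign(X, np.arange(X.shape[0]), list(range(X.shape[1])))
    X = design.X
    y_arr = np.asarray(y, dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        log.warning("design matrix rank-deficient (%d < %d); using pseudo-inverse",
                    rank, X.shape[1])
    beta, *_ = np.linalg.lstsq(X, y_arr, rcond=None)
    yc = y_arr - X @ beta
    idx = y.index if isinstance(y, pd.Series) else design.animal_ids
    return AdjustedPhenotypes(pd.Series(yc, index=idx), design)


def pedigree_h2_from_components(sigma_a2: float, sigma_e2: float) -> float:
    """Narrow-sense heritability sigma_a^2 / (sigma_a^2 + sigma_e^2)."""
    tot = sigma_a2 + sigma_e2
    if tot <= 0:
        raise ValueError("total variance must be positive")
    return sigma_a2 / tot


@dataclass
class REMLOptions:
    max_iter: int = 200
    tol_loglik: float = 1e-8
    tol_param: float = 1e-6
    verbose: bool = False


def fit_reml(y, X, K, options: REMLOptions | None = None, ids=None,
             eig: tuple | None = None) -> VarianceEstimate:
    """AI-REML for (sigma_a^2, sigma_e^2) with EM fallback.

    ``K`` may be a :class:`~gselect.relationship.RelationshipMatrix` or a
    plain symmetric array aligned with ``y``.  ``eig`` optionally supplies a
    precomputed ``(eigenvalues, eigenvectors)`` of K (useful when many
    traits share one kinship matrix).  Variances are kept non-negative by
    boundary projection, so sigma_a^2 = 0 is reachable for null traits.
    """
    opts = options or REMLOptions()
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if hasattr(K, "values") and hasattr(K, "animal_ids"):
        if ids is None:
            Kv = K.values
        else:
            Kv = K.submatrix(ids)
        if ids is not None and len(set(ids)) != len(list(ids)):
            raise ValueError("duplicate animal ids in REML input")
    else:
        Kv = np.asarray(K, dtype=float)
    if ids is not None and not hasattr(K, "animal_ids"):
        if len(set(ids)) != len(list(ids)):
            raise ValueError("duplicate animal ids in REML input")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need more records than fixed-effect parameters")

    if eig is None:
        d, U = eigh(Kv)
    else:
        d, U = eig
    d = np.maximum(d, 0.0)
    identifiable = bool(np.ptp(d) > 1e-8 * max(d.max(), 1.0))
    if not identifiable:
        # K proportional to I: only sigma_a2 + sigma_e2 is estimable
        log.warning("kinship matrix is (numerically) a multiple of the identity; "
                    "variance components are not separately identifiable")
    yt = U.T @ y
    Xt = U.T @ X

    vary = float(np.var(y, ddof=1))
    theta = np.array([0.5 * vary, 0.5 * vary])  # (sigma_a2, sigma_e2)
    floor = 1e-10 * vary

    def core(th):
        w = th[0] * d + th[1]
        w = np.maximum(w, 1e-12 * vary)
        wi = 1.0 / w
        B = Xt.T @ (Xt * wi[:, None])
        Bi = np.linalg.inv(B)
        XtWy = Xt.T @ (yt * wi)
        Py = yt * wi - (Xt * wi[:, None]) @ (Bi @ XtWy)
        ll = -0.5 * (np.log(w).sum() + np.linalg.slogdet(B)[1] + float(yt @ Py))
        return w, wi, Bi, Py, ll

    def trace_PV(wi, Bi, v):
        # tr(P diag(v)) with P = W^-1 - W^-1 Xt Bi Xt' W^-1
        t1 = float(np.sum(v * wi))
        Xw = Xt * wi[:, None]
        t2 = float(np.einsum("ij,jk,ik->", Xw * v[:, None], Bi, Xw))
        return t1 - t2

    def P_apply(wi, Bi, q):
        return q * wi - (Xt * wi[:, None]) @ (Bi @ (Xt.T @ (q * wi)))

    w, wi, Bi, Py, ll = core(theta)
    trace = [ll]
    converged = False
    ai_inv = None
    for it in range(1, opts.max_iter + 1):
        # gradients
        PVaPy = P_apply(wi, Bi, d * Py)
        PPy = P_apply(wi, Bi, Py)
        grad = np.array([
            -0.5 * (trace_PV(wi, Bi, d) - float(Py @ (d * Py))),
            -0.5 * (trace_PV(wi, Bi, np.ones(len(d))) - float(Py @ Py)),
        ])
        # average information
        q1, q2 = d * Py, Py
        AI = 0.5 * np.array([
            [float(q1 @ P_apply(wi, Bi, q1)), float(q1 @ P_apply(wi, Bi, q2))],
            [float(q2 @ P_apply(wi, Bi, q1)), float(q2 @ P_apply(wi, Bi, q2))],
        ])
        step = None
        try:
            ai_inv = np.linalg.inv(AI)
            step = ai_inv @ grad
        except np.linalg.LinAlgError:
            pass
        accepted = False
        if step is not None:
            frac = 1.0
            for _ in range(12):  # step-halving
                cand = theta + frac * step
                if (cand >= 0).all() and cand.sum() > 0:
                    wc, wic, Bic, Pyc, llc = core(np.maximum(cand, floor))
                    if llc >= ll - 1e-10:
                        theta_new = np.maximum(cand, floor)
                        w, wi, Bi, Py, ll_new = wc, wic, Bic, Pyc, llc
                        accepted = True
                        break
                frac *= 0.5
        if not accepted:
            # EM-REML updates (guaranteed in the parameter space)
            em = np.array([
                theta[0] + theta[0] ** 2 * (float(Py @ (d * Py)) - trace_PV(wi, Bi, d)) / n,
                theta[1] + theta[1] ** 2 * (float(Py @ Py) - trace_PV(wi, Bi, np.ones(len(d)))) / n,
            ])
            theta_new = np.maximum(em, floor)
            w, wi, Bi, Py, ll_new = core(theta_new)
        dll = ll_new - trace[-1]
        rel = np.abs(theta_new - theta) / np.maximum(theta.sum(), 1e-30)
        trace.append(ll_new)
        theta, ll = theta_new, ll_new
        if opts.verbose:
            log.info("REML iter %d: ll=%.6f theta=%s", it, ll, theta)
        if abs(dll) < opts.tol_loglik and rel.max() < opts.tol_param:
            converged = True
            break

    boundary = bool(theta[0] <= floor * 1.5)
    if boundary:
        theta[0] = 0.0
    se = np.nan
    if ai_inv is not None and np.isfinite(ai_inv).all() and theta.sum() > 0:
        sa, se2 = theta
        sp = sa + se2
        grad_h = np.array([se2, -sa]) / sp ** 2
        var_h2 = float(grad_h @ ai_inv @ grad_h)
        se = float(np.sqrt(max(var_h2, 0.0)))
    return VarianceEstimate(float(theta[0]), float(theta[1]), se,
                            converged=converged and identifiable,
                            n_iter=len(trace) - 1, loglik_trace=trace,
                            boundary=boundary, identifiable=identifiable)
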