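"""GBLUP: genomic breeding values from a relationship matrix.

Model on adjusted phenotypes: yc = 1 mu + Z g + e with var(g) = G sigma_g^2
and var(e) = I sigma_e^2.  Training animals carry records; GEBVs are defined
for every animal in G, so validation animals are predicted jointly.  Two
algebraically equivalent solution paths are exposed: ``joint`` solves the
training system and carries all animals through G's cross-covariances,
``condition`` predicts validation animals as G_vt G_tt^{-1} g_hat_train.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .relationship import RelationshipMatrix
from .variance_components import REMLOptions, fit_reml


@dataclass
class GBLUPResult:
    mu: float
    gebv: pd.Series  # all animals in G
    sigma_g2: float
    sigma_e2: float
    diagnostics: dict = field(default_factory=dict)


def fit_gblup(yc_train: pd.Series, G: RelationshipMatrix, train_ids=None,
              variances: tuple[float, float] | None = None,
              method: str = "joint", reml_options: REMLOptions | None = None,
              ) -> GBLUPResult:
    """Solve the GBLUP mixed model on the training records.

    ``variances`` supplies (sigma_g2, sigma_e2); when None they are
    estimated by REML on the training block of G with an intercept-only
    design.  ``yc_train`` must be indexed by animal id (ids present in G).
    """
    if train_ids is None:
        train_ids = list(yc_train.index)
    y = yc_train.loc[list(train_ids)].to_numpy(dtype=float)
    t = G.index_of(train_ids)
    Gtt = G.values[np.ix_(t, t)]
    nt = len(t)

    diagnostics: dict = {}
    if variances is None:
        est = fit_reml(y, np.ones((nt, 1)), Gtt, options=reml_options)
        sigma_g2, sigma_e2 = est.sigma_a2, est.sigma_e2
        diagnostics["reml"] = est
    else:
        sigma_g2, sigma_e2 = map(float, variances)

    if sigma_g2 <= 0:
        mu = float(np.mean(y))
        gebv = pd.Series(np.zeros(G.animal_ids.size), index=G.animal_ids)
        return GBLUPResult(mu, gebv, sigma_g2, sigma_e2, diagnostics)

    V = sigma_g2 * Gtt + sigma_e2 * np.eye(nt)
    try:
        c = cho_factor(V)
    except np.linalg.LinAlgError:
        diagnostics["ridge"] = 1e-6
        c = cho_factor(V + 1e-6 * np.eye(nt))
    ones = np.ones(nt)
    Vi1 = cho_solve(c, ones)
    mu = float(ones @ cho_solve(c, y) / (ones @ Vi1))
    w = cho_solve(c, y - mu)

    if method == "joint":
        ghat = sigma_g2 * (G.values[:, t] @ w)
    elif method == "condition":
        g_train = sigma_g2 * (Gtt @ w)
        Gtt_inv_g = np.linalg.solve(Gtt, g_train)
        ghat = G.values[:, t] @ Gtt_inv_g
    else:
        raise ValueError(f"unknown method {method!r}; use 'joint' or 'condition'")
    gebv = pd.Series(ghat, index=G.animal_ids)
    return GBLUPResult(mu, gebv, sigma_g2, sigma_e2, diagnostics)


def snp_blup(yc_train, M_train, M_all, sigma_g2: float, sigma_e2: float,
             sum2pq: float) -> tuple[float, np.ndarray]:
    """Ridge-regression SNP-BLUP with per-SNP variance sigma_g2 / sum2pq.

    Equivalent to GBLUP with G = M M' / sum2pq; kept as an independent
    solution path (normal equations in marker space).
    """
    y = np.asarray(yc_train, dtype=float)
    Mt = np.asarray(M_train, dtype=float)
    n, m = Mt.shape
    lam = sigma_e2 * sum2pq / sigma_g2
    # GLS intercept under V = sigma_a2/sum2pq * Mt Mt' + sigma_e2 I
    V = (sigma_g2 / sum2pq) * (Mt @ Mt.T) + sigma_e2 * np.eye(n)
    Vi = np.linalg.inv(V)
    ones = np.ones(n)
    mu = float(ones @ Vi @ y / (ones @ Vi @ ones))
    r = y - mu
    alpha = np.linalg.solve(Mt.T @ Mt + lam * np.eye(m), Mt.T @ r)
    return mu, np.asarray(M_all, dtype=float) @ alpha
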