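"""Pedigree (A) and genomic (G) relationship matrices.

A is built by the tabular (recursive) method with inbreeding; G is
VanRaden's first method, G = M M' / (2 * sum_i p_i (1 - p_i)) with M the
frequency-centered dosage matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .data_io import MISSING, UNKNOWN_PARENT, GenotypeMatrix, PedigreeTable
from .synthetic_data import centered_dosages

log = logging.getLogger(__name__)


@dataclass
class RelationshipMatrix:
    """Dense symmetric kinship keyed by animal ids."""

    kind: str  # "pedigree" or "genomic"
    animal_ids: np.ndarray
    values: np.ndarray
    allele_freq: np.ndarray | None = None
    denominator: float | None = None

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = self.animal_ids.size
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape mismatch with ids")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-10:
            raise ValueError("relationship matrix is not symmetric")

    def index_of(self, ids) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        return np.array([pos[a] for a in ids], dtype=np.int64)

    def submatrix(self, rows, cols=None) -> np.ndarray:
        r = self.index_of(rows)
        c = r if cols is None else self.index_of(cols)
        return self.values[np.ix_(r, c)]


@njit(cache=True)
def _tabular_nrm(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    n = sire.size
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        for j in range(i):
            a = A[j, s] if s >= 0 else 0.0
            b = A[j, d] if d >= 0 else 0.0
            A[i, j] = 0.5 * (a + b)
            A[j, i] = A[i, j]
    return A


def build_nrm(pedigree: PedigreeTable) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Founders are unrelated and non-inbred; a(i,i) = 1 + 0.5 a(sire, dam).
    """
    f = pedigree.frame
    ids = f["animal"].to_numpy(dtype=object)
    pos = {a: i for i, a in enumerate(ids)}
    sire = np.empty(len(ids), dtype=np.int64)
    dam = np.empty(len(ids), dtype=np.int64)
    for i, (s, d) in enumerate(zip(f["sire"], f["dam"])):
        for arr, parent in ((sire, s), (dam, d)):
            if parent == UNKNOWN_PARENT:
                arr[i] = -1
            elif parent in pos:
                if pos[parent] >= i:
                    raise ValueError(f"pedigree not sorted: parent {parent!r} after offspring")
                arr[i] = pos[parent]
            else:
                raise ValueError(f"unknown parent id {parent!r} not in pedigree")
    return RelationshipMatrix("pedigree", ids, _tabular_nrm(sire, dam))


def build_grm(gm: GenotypeMatrix, freq_source="observed") -> RelationshipMatrix:
    """VanRaden genomic relationship matrix.

    Missing calls are mean-imputed (2p) before centering.  ``freq_source``
    is either ``"observed"`` or an explicit frequency vector (use a fixed
    vector to keep train/validation scaling consistent).
    """
    if isinstance(freq_source, str):
        if freq_source != "observed":
            raise ValueError(f"unknown freq_source {freq_source!r}")
        p = gm.allele_freq()
    else:
        p = np.asarray(freq_source, dtype=float)
        if p.shape != (gm.n_snps,):
            raise ValueError("frequency vector length mismatch")
    mono = ~((p > 0.0) & (p < 1.0))
    if mono.any():
        bad = gm.map.snp_id[mono][:5]
        raise ValueError(
            f"monomorphic SNPs in GRM input (e.g. {list(bad)}); run QC first")
    M = centered_dosages(gm, p)
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    G = (M @ M.T) / denom
    return RelationshipMatrix("genomic", gm.animal_ids, G, allele_freq=p, denominator=denom)


def inverse(rel: RelationshipMatrix, ridge: float = 1e-6) -> np.ndarray:
    """Inverse of the relationship matrix, with a logged diagonal ridge
    applied only when the plain factorization fails."""
    from scipy.linalg import cho_factor, cho_solve
    n = rel.values.shape[0]
    try:
        c = cho_factor(rel.values)
        return cho_solve(c, np.eye(n))
    except np.linalg.LinAlgError:
        pass
    except Exception:
        pass
    log.warning("relationship matrix numerically singular; adding ridge %.1e", ridge)
    c = cho_factor(rel.values + ridge * np.eye(n))
    return cho_solve(c, np.eye(n))
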