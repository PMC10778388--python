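"""SNP and animal quality control for 50K-chip genotype panels.

The cascade follows the order standard in cattle genomic-selection
pipelines: map-based exclusions, pedigree-discordant animals, minor allele
frequency, SNP call rate, animal call rate, exact Hardy-Weinberg test, and
identity-by-state duplicate detection.  Each step operates on the surviving
set and is recorded in a :class:`QCReport` whose bookkeeping telescopes.

The Hardy-Weinberg filter excludes SNPs with exact-test p < alpha (the
PLINK convention).  Genotype-chip QC write-ups sometimes phrase this as
excluding "p-value greater than" the threshold; read literally that would
discard almost the entire panel, so the conventional direction is used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import AUTOSOMES, MISSING, GenotypeMatrix


class QCError(ValueError):
    pass


@dataclass
class QCThresholds:
    """Default thresholds typical for bovine 50K panels."""

    maf_min: float = 0.05
    snp_call_min: float = 0.90
    animal_call_min: float = 0.90
    hwe_alpha: float = 1e-6
    ibs_max: float = 0.99
    drop_nonautosomal: bool = True

    def __post_init__(self) -> None:
        for name in ("maf_min", "snp_call_min", "animal_call_min", "hwe_alpha", "ibs_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise QCError(f"threshold {name}={v} outside [0, 1]")


@dataclass
class QCStep:
    name: str
    axis: str  # "snp" or "animal"
    n_removed: int
    n_snps_remaining: int
    n_animals_remaining: int
    removed_ids: list = field(default_factory=list)


@dataclass
class QCReport:
    initial_snps: int
    initial_animals: int
    steps: list = field(default_factory=list)

    @property
    def final_snps(self) -> int:
        return self.steps[-1].n_snps_remaining if self.steps else self.initial_snps

    @property
    def final_animals(self) -> int:
        return self.steps[-1].n_animals_remaining if self.steps else self.initial_animals

    def add(self, name: str, axis: str, removed_ids, n_snps: int, n_animals: int) -> None:
        removed_ids = list(removed_ids)
        prev_s = self.steps[-1].n_snps_remaining if self.steps else self.initial_snps
        prev_a = self.steps[-1].n_animals_remaining if self.steps else self.initial_animals
        expect = prev_s - len(removed_ids) if axis == "snp" else prev_a - len(removed_ids)
        got = n_snps if axis == "snp" else n_animals
        if expect != got:
            raise QCError(f"bookkeeping broken at step {name!r}: {expect} != {got}")
        self.steps.append(QCStep(name, axis, len(removed_ids), n_snps, n_animals, removed_ids))

    @classmethod
    def from_step_counts(cls, initial_snps: int, initial_animals: int,
                         steps: list[tuple[str, str, int]]) -> "QCReport":
        """Build a count-only removal ledger (ids unknown); telescoping checked."""
        rep = cls(initial_snps, initial_animals)
        s, a = initial_snps, initial_animals
        for name, axis, k in steps:
            if axis == "snp":
                s -= k
            else:
                a -= k
            rep.steps.append(QCStep(name, axis, k, s, a))
        return rep

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame([{
            "step": s.name, "axis": s.axis, "removed": s.n_removed,
            "snps_remaining": s.n_snps_remaining,
            "animals_remaining": s.n_animals_remaining} for s in self.steps])


# ---------------------------------------------------------------------------
# per-SNP statistics
# ---------------------------------------------------------------------------


def compute_maf(calls) -> float:
    """Minor allele frequency of one SNP's call vector; missing excluded."""
    calls = np.asarray(calls)
    obs = calls[calls != MISSING]
    if obs.size == 0:
        raise QCError("MAF undefined: all calls missing")
    p = obs.sum() / (2.0 * obs.size)
    return float(min(p, 1.0 - p))


def hwe_test(n0: int, n1: int, n2: int, midp: bool = False) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one (Wigginton-style exact test; mid-p optional).
    """
    if min(n0, n1, n2) < 0:
        raise QCError("negative genotype counts")
    n = n0 + n1 + n2
    if n < 1:
        raise QCError("empty genotype counts")
    n_rare = 2 * min(n0, n2) + n1
    probs = _het_probabilities(n, n_rare)
    obs = probs[n1]
    tol = 1.0 + 1e-12
    p = float(probs[probs <= obs * tol].sum())
    if midp:
        p -= 0.5 * float(obs)
    return min(1.0, p)


def _het_probabilities(n: int, n_rare: int) -> np.ndarray:
    """P(het count = h | allele counts), for h = 0..n with matching parity."""
    probs = np.zeros(n + 1)
    h0 = n_rare % 2  # lowest feasible het count has the parity of n_rare
    probs[h0] = 1.0
    # recurrence: P(h+2)/P(h) = (nr-h)(nc-h) / ((h+2)(h+1)) with
    # nr = rare alleles in hom+het, using counts a = (n_rare - h)/2 rare homs,
    # b = n - h - a common homs
    h = h0
    while h + 2 <= min(n_rare, 2 * n - n_rare):
        a = (n_rare - h) // 2
        b = n - h - a
        probs[h + 2] = probs[h] * 4.0 * a * b / ((h + 2.0) * (h + 1.0))
        h += 2
    total = probs.sum()
    if total <= 0:
        raise QCError("degenerate HWE configuration")
    return probs / total


def hwe_chi2(n0: int, n1: int, n2: int) -> float:
    """Asymptotic chi-square (1 df) HWE p-value; cross-check for the exact test."""
    from scipy.stats import chi2
    n = n0 + n1 + n2
    p = (2 * n2 + n1) / (2.0 * n)
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p ** 2])
    obs = np.array([n0, n1, n2], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.nansum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0))
    return float(chi2.sf(stat, 1))


def ibs_similarity(gm: GenotypeMatrix, pair: tuple) -> float:
    """Mean over co-observed SNPs of (2 - |g_i - g_j|) / 2 for one pair."""
    idx = {a: i for i, a in enumerate(gm.animal_ids)}
    i, j = idx[pair[0]], idx[pair[1]]
    gi, gj = gm.calls[i], gm.calls[j]
    co = (gi != MISSING) & (gj != MISSING)
    if not co.any():
        raise QCError(f"no co-observed SNPs for pair {pair}")
    d = np.abs(gi[co].astype(int) - gj[co].astype(int))
    return float((2.0 - d).mean() / 2.0)


def _ibs_matrix(calls: np.ndarray) -> np.ndarray:
    """All-pairs IBS similarity with pairwise-complete missing handling."""
    obs = (calls != MISSING).astype(np.float64)
    g = np.where(calls != MISSING, calls, 0).astype(np.float64)
    g2 = g * g * obs
    co = obs @ obs.T
    # sum over co-observed of (gi - gj)^2
    sq = (g2 * 1.0) @ obs.T + obs @ g2.T - 2.0 * (g @ g.T)
    # |d| = d^2 - 2 * [one is 0 and the other 2]
    i0 = (calls == 0).astype(np.float64)
    i2 = (calls == 2).astype(np.float64)
    n02 = i0 @ i2.T + i2 @ i0.T
    sum_abs = sq - 2.0 * n02
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(co > 0, (2.0 * co - sum_abs) / (2.0 * co), np.nan)
    return sim


def find_duplicates(gm: GenotypeMatrix, threshold: float = 0.99) -> list[dict]:
    """Pairs with IBS similarity above ``threshold``.

    Within a pair the animal with the lower call rate is flagged for
    removal; on ties, the later-indexed animal.
    """
    sim = _ibs_matrix(gm.calls)
    cr = gm.animal_call_rate()
    out = []
    n = gm.n_animals
    iu, ju = np.triu_indices(n, k=1)
    hits = np.flatnonzero(sim[iu, ju] > threshold)
    for h in hits:
        i, j = int(iu[h]), int(ju[h])
        if cr[i] < cr[j]:
            rm, keep = i, j
        elif cr[j] < cr[i]:
            rm, keep = j, i
        else:
            rm, keep = max(i, j), min(i, j)
        out.append({"kept": gm.animal_ids[keep], "removed": gm.animal_ids[rm],
                    "similarity": float(sim[i, j])})
    return out


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------


def apply_qc(gm: GenotypeMatrix, thresholds: QCThresholds | None = None,
             discordant_ids=()) -> tuple[GenotypeMatrix, QCReport]:
    """Run the full cascade and return the cleaned matrix plus the report.

    Steps, each on the current surviving set: (1) non-autosomal or
    duplicate-position SNPs, (2) caller-supplied pedigree-discordant
    animals, (3) MAF, (4) SNP call rate, (5) animal call rate, (6) exact
    HWE, (7) IBS duplicates.
    """
    th = thresholds or QCThresholds()
    report = QCReport(gm.n_snps, gm.n_animals)

    def drop_snps(name, mask_drop):
        nonlocal gm
        ids = list(gm.map.snp_id[mask_drop])
        gm = gm.subset(snp_idx=np.flatnonzero(~mask_drop))
        report.add(name, "snp", ids, gm.n_snps, gm.n_animals)
        if gm.n_snps == 0:
            raise QCError(f"no SNPs left after step {name!r}")

    def drop_animals(name, mask_drop):
        nonlocal gm
        ids = list(gm.animal_ids[mask_drop])
        gm = gm.subset(animal_idx=np.flatnonzero(~mask_drop))
        report.add(name, "animal", ids, gm.n_snps, gm.n_animals)
        if gm.n_animals == 0:
            raise QCError(f"no animals left after step {name!r}")

    # 1. map-based exclusions
    if th.drop_nonautosomal:
        non_auto = ~np.isin(gm.map.chromosome.astype(str), AUTOSOMES)
        pos_key = list(zip(gm.map.chromosome, gm.map.position_bp))
        seen: dict = {}
        dup_pos = np.zeros(gm.n_snps, dtype=bool)
        for k, key in enumerate(pos_key):
            if key in seen:
                dup_pos[k] = True
            else:
                seen[key] = k
        drop_snps("map_exclusions", non_auto | dup_pos)

    # 2. pedigree-discordant animals
    disc = np.isin(gm.animal_ids, list(discordant_ids))
    drop_animals("pedigree_discordant", disc)

    # 3. MAF
    obs = gm.observed()
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, gm.calls, 0).sum(axis=0) / (2.0 * n_obs)
    maf = np.minimum(p, 1.0 - p)
    drop_snps("maf", (n_obs == 0) | (maf < th.maf_min))

    # 4. SNP call rate
    drop_snps("snp_call_rate", gm.snp_call_rate() < th.snp_call_min)

    # 5. animal call rate
    drop_animals("animal_call_rate", gm.animal_call_rate() < th.animal_call_min)

    # 6. exact HWE
    pvals = np.ones(gm.n_snps)
    for j in range(gm.n_snps):
        col = gm.calls[:, j]
        col = col[col != MISSING]
        n0 = int((col == 0).sum()); n1 = int((col == 1).sum()); n2 = int((col == 2).sum())
        pvals[j] = hwe_test(n0, n1, n2)
    drop_snps("hwe", pvals < th.hwe_alpha)

    # 7. IBS duplicates
    dup = find_duplicates(gm, th.ibs_max)
    rm_ids = sorted({d["removed"] for d in dup})
    drop_animals("ibs_duplicates", np.isin(gm.animal_ids, rm_ids))

    return gm, report
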