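"""Synthetic genotype / pedigree / phenotype generator.

Emulates the data regime of a commercial Korean Hanwoo cow population typed
on a ~50K bovine chip: 29 autosomes, multi-herd categorical fixed effects,
and four Gaussian-scale reproductive traits with low heritability (age at
first calving, calving interval, gestation length, inseminations per
conception).  Markers are simulated in linkage equilibrium under
Hardy-Weinberg proportions, which keeps every downstream expectation
analytically tractable; breeding values for genotyped animals are realized
from the markers themselves (u = M g with centered M), so the generator's
truth is exactly the quantity the whole-genome regression models estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import (MISSING, FIXED_FACTORS, GenotypeMatrix, MarkerMap,
                      PedigreeTable, PhenotypeTable, TRAITS)

#: BayesR-style variance-class multipliers (fractions of sigma_g^2)
DEFAULT_MULTIPLIERS = (0.0, 1e-4, 1e-3, 1e-2)


@dataclass
class ArchitectureSpec:
    """Genetic architecture of the simulated trait.

    ``polygenic`` gives every SNP a normal effect; ``mixture`` draws each
    SNP's class from ``proportions`` over the four variance multipliers.
    """

    kind: str = "polygenic"
    proportions: tuple = (0.99, 0.005, 0.003, 0.002)
    multipliers: tuple = DEFAULT_MULTIPLIERS

    def __post_init__(self) -> None:
        if self.kind not in ("polygenic", "mixture"):
            raise ValueError(f"unknown architecture kind {self.kind!r}")
        if self.kind == "mixture":
            if abs(sum(self.proportions) - 1.0) > 1e-9:
                raise ValueError("mixture proportions must sum to 1")
            if any(m < 0 for m in self.multipliers):
                raise ValueError("variance multipliers must be non-negative")


@dataclass
class TraitSpec:
    """Target distribution of one trait.

    ``h2`` is the narrow-sense heritability sigma_a^2/(sigma_a^2+sigma_e^2);
    the categorical fixed effects add ``fixed_fraction`` of the total
    phenotypic variance on top, so the raw SD matches ``sd``.
    """

    name: str
    mean: float
    sd: float
    h2: float
    min_value: float
    max_value: float
    integer_valued: bool = False
    fixed_fraction: float = 0.10
    n_herds: int = 9
    n_years: int = 8
    n_seasons: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if not (self.min_value < self.mean < self.max_value):
            raise ValueError("envelope requires min < mean < max")
        if not 0.0 <= self.fixed_fraction < 1.0:
            raise ValueError("fixed_fraction must lie in [0, 1)")


#: desk-scale archetypes of the four Hanwoo cow reproductive traits
TRAIT_PRESETS: dict[str, TraitSpec] = {
    "afc": TraitSpec("afc", mean=736.18, sd=64.43, h2=0.070, min_value=556, max_value=934),
    "ci": TraitSpec("ci", mean=370.56, sd=40.04, h2=0.026, min_value=300, max_value=497),
    "gl": TraitSpec("gl", mean=286.62, sd=4.91, h2=0.102, min_value=275, max_value=303),
    "naipc": TraitSpec("naipc", mean=1.44, sd=0.79, h2=0.055, min_value=1, max_value=7,
                       integer_valued=True),
}


@dataclass
class PlantedDefects:
    """Deliberate data-quality defects, recorded in a manifest for QC tests."""

    n_monomorphic: int = 0
    n_low_call_snps: int = 0
    n_hwe_violators: int = 0
    n_duplicate_animals: int = 0
    low_call_rate: float = 0.5


@dataclass
class SimulatedDataset:
    """One simulated trait with its ground truth."""

    genotypes: GenotypeMatrix | None
    pedigree: PedigreeTable | None
    phenotypes: PhenotypeTable
    trait: str
    marker_effects: np.ndarray | None
    breeding_values: pd.Series
    residuals: pd.Series
    fixed_part: pd.Series
    h2_true: float
    h2_realized: float
    sigma_a2_true: float
    sigma_e2_true: float
    seed: int


# ---------------------------------------------------------------------------


def simulate_genotypes(n_animals: int, n_snps: int, maf_sampler=None,
                       missing_rate: float = 0.0, n_chromosomes: int = 29,
                       seed: int = 0, defects: PlantedDefects | None = None,
                       ) -> tuple[GenotypeMatrix, dict]:
    """HWE genotypes in linkage equilibrium, plus a planted-defect manifest.

    Per SNP an allele frequency p is drawn from ``maf_sampler`` (default
    Uniform(0.05, 0.5)) and calls are Binomial(2, p).  SNPs are assigned
    round-robin to chromosomes with increasing positions.  The manifest maps
    each defect class to the snp/animal ids it was planted on.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if maf_sampler is None:
        maf_sampler = lambda r, size: r.uniform(0.05, 0.5, size=size)
    p = np.asarray(maf_sampler(rng, n_snps), dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("maf_sampler produced frequencies outside (0, 1)")
    calls = rng.binomial(2, p, size=(n_animals, n_snps)).astype(np.int8)

    defects = defects or PlantedDefects()
    manifest: dict[str, list] = {"monomorphic_snps": [], "low_call_snps": [],
                                 "hwe_snps": [], "duplicate_animals": []}
    snp_ids = np.array([f"snp{j:06d}" for j in range(n_snps)], dtype=object)
    cursor = 0

    k = defects.n_monomorphic
    if k:
        cols = np.arange(cursor, cursor + k); cursor += k
        calls[:, cols] = 0
        manifest["monomorphic_snps"] = list(snp_ids[cols])
    k = defects.n_hwe_violators
    if k:
        cols = np.arange(cursor, cursor + k); cursor += k
        # complete heterozygote deficit at intermediate frequency
        pf = rng.uniform(0.3, 0.5, size=k)
        calls[:, cols] = 2 * rng.binomial(1, pf, size=(n_animals, k)).astype(np.int8)
        manifest["hwe_snps"] = list(snp_ids[cols])
    if missing_rate > 0:
        mask = rng.random((n_animals, n_snps)) < missing_rate
        calls[mask] = MISSING
    k = defects.n_low_call_snps
    if k:
        cols = np.arange(cursor, cursor + k); cursor += k
        p_keep = rng.uniform(0.3, 0.45, size=k)  # safely below a 0.90 call-rate cut
        mask = rng.random((n_animals, k)) < (1.0 - p_keep)
        sub = calls[:, cols]
        sub[mask] = MISSING
        calls[:, cols] = sub
        manifest["low_call_snps"] = list(snp_ids[cols])

    animal_ids = np.array([f"a{i:06d}" for i in range(n_animals)], dtype=object)
    k = defects.n_duplicate_animals
    if k:
        if 2 * k > n_animals:
            raise ValueError("too many duplicate animals requested")
        for d in range(k):
            src, dst = d, n_animals - 1 - d
            calls[dst] = calls[src]
            manifest["duplicate_animals"].append(
                {"kept": animal_ids[src], "removed": animal_ids[dst]})

    # canonicalize to minor-allele coding (matches what the PLINK readers derive)
    allele_a = np.full(n_snps, "A", dtype=object)
    allele_b = np.full(n_snps, "G", dtype=object)
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(obs, calls, 0).sum(axis=0) / np.maximum(2.0 * n_obs, 1)
    flip = (freq > 0.5) | ((freq == 0.5) & (allele_b > allele_a))
    calls[:, flip] = np.where(calls[:, flip] == MISSING, MISSING, 2 - calls[:, flip])
    allele_a[flip], allele_b[flip] = allele_b[flip], allele_a[flip]

    chrom = np.array([str(j % n_chromosomes + 1) for j in range(n_snps)], dtype=object)
    pos = np.array([(j // n_chromosomes + 1) * 1000 for j in range(n_snps)], dtype=np.int64)
    mm = MarkerMap(snp_ids, chrom, pos, allele_a, allele_b)
    order = mm.sort_order()
    gm = GenotypeMatrix(animal_ids, calls[:, order], mm.take(order))
    return gm, manifest


def simulate_pedigree(n_founders: int, n_generations: int,
                      offspring_per_mating: int = 1, seed: int = 0) -> PedigreeTable:
    """Discrete-generation pedigree: each generation adds
    ``(n_founders // 2) * offspring_per_mating`` offspring whose sire and dam
    are drawn from the previous generation."""
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    rng = np.random.default_rng(seed)
    records = []
    males = [f"g0m{i}" for i in range(n_founders - n_founders // 2)]
    females = [f"g0f{i}" for i in range(n_founders // 2)]
    for a in males + females:
        records.append((a, "0", "0"))
    n_matings = n_founders // 2
    for g in range(1, n_generations + 1):
        new_m, new_f = [], []
        for mt in range(n_matings):
            sire = males[rng.integers(len(males))]
            dam = females[rng.integers(len(females))]
            for o in range(offspring_per_mating):
                aid = f"g{g}x{mt}o{o}"
                records.append((aid, sire, dam))
                (new_m if (mt + o) % 2 == 0 else new_f).append(aid)
        males = new_m or males
        females = new_f or females
    return PedigreeTable(pd.DataFrame(records, columns=["animal", "sire", "dam"]))


def _draw_marker_effects(m: int, sum2pq: float, sigma_g2: float,
                         arch: ArchitectureSpec, rng) -> np.ndarray:
    """Effects scaled so E[sum_j 2 p_j q_j g_j^2] = sigma_g2 (LE variance)."""
    if arch.kind == "polygenic":
        return rng.normal(0.0, np.sqrt(sigma_g2 / sum2pq), size=m)
    pi = np.asarray(arch.proportions)
    mult = np.asarray(arch.multipliers)
    mean_mult = float(pi @ mult)
    if mean_mult <= 0:
        raise ValueError("mixture has zero expected variance but sigma_g2 > 0")
    scale = sigma_g2 / (sum2pq * mean_mult)
    classes = rng.choice(len(pi), size=m, p=pi)
    sd = np.sqrt(mult[classes] * scale)
    g = rng.normal(0.0, 1.0, size=m) * sd
    return g


def centered_dosages(gm: GenotypeMatrix, freqs: np.ndarray | None = None) -> np.ndarray:
    """Mean-imputed, frequency-centered dosage matrix M = calls - 2p."""
    p = gm.allele_freq() if freqs is None else np.asarray(freqs, dtype=float)
    M = gm.calls.astype(float)
    miss = gm.calls == MISSING
    if miss.any():
        M[miss] = np.broadcast_to(2.0 * p, M.shape)[miss]
    return M - 2.0 * p


def simulate_trait(genotypes: GenotypeMatrix | None, pedigree: PedigreeTable | None,
                   trait_spec: TraitSpec, architecture: ArchitectureSpec | None = None,
                   seed: int = 0, factor_assignments: dict | None = None,
                   ) -> SimulatedDataset:
    """Simulate one trait under the single-trait animal model.

    With genotypes, breeding values are marker-realized (u = M g); without
    genotypes, u is drawn from N(0, A sigma_a^2) on the pedigree.  Residuals
    are i.i.d. normal scaled so the expected heritability equals the target;
    herd/year/season effects are level draws adding ``fixed_fraction`` of the
    phenotypic variance.
    """
    if genotypes is None and pedigree is None:
        raise ValueError("need genotypes or a pedigree to simulate from")
    arch = architecture or ArchitectureSpec()
    rng = np.random.default_rng(seed)
    spec = trait_spec

    sigma_p2 = spec.sd ** 2
    sigma_fix2 = spec.fixed_fraction * sigma_p2
    sigma_a2 = spec.h2 * (sigma_p2 - sigma_fix2)
    sigma_e2 = (1.0 - spec.h2) * (sigma_p2 - sigma_fix2)

    if genotypes is not None:
        ids = genotypes.animal_ids
        n = genotypes.n_animals
        if sigma_a2 > 0:
            p = genotypes.allele_freq()
            poly = (p > 0) & (p < 1)
            sum2pq = float(np.sum(2.0 * p[poly] * (1.0 - p[poly])))
            effects = np.zeros(genotypes.n_snps)
            effects[poly] = _draw_marker_effects(int(poly.sum()), sum2pq, sigma_a2,
                                                 arch, rng)
            u = centered_dosages(genotypes) @ effects
        else:
            effects = np.zeros(genotypes.n_snps)
            u = np.zeros(n)
    else:
        from .relationship import build_nrm  # local import; no cycle at module load
        A = build_nrm(pedigree)
        ids = A.animal_ids
        n = ids.size
        effects = None
        if sigma_a2 > 0:
            L = np.linalg.cholesky(A.values + 1e-10 * np.eye(n))
            u = np.sqrt(sigma_a2) * (L @ rng.standard_normal(n))
        else:
            u = np.zeros(n)

    e = rng.normal(0.0, np.sqrt(sigma_e2), size=n)

    per_factor_var = sigma_fix2 / len(FIXED_FACTORS)
    levels = {"herd": spec.n_herds, "birth_year": spec.n_years,
              "birth_season": spec.n_seasons, "calving_year": spec.n_years,
              "calving_season": spec.n_seasons}
    fixed = np.zeros(n)
    factors = {}
    for fac in FIXED_FACTORS:
        k = levels[fac]
        eff = rng.normal(0.0, np.sqrt(per_factor_var), size=k)
        if factor_assignments is not None:
            assign = np.asarray(factor_assignments[fac])
            k = int(assign.max()) + 1
            eff = rng.normal(0.0, np.sqrt(per_factor_var), size=k)
        else:
            assign = rng.integers(k, size=n)
        fixed += eff[assign]
        factors[fac] = np.array([f"{fac[0]}{v}" for v in assign], dtype=object)

    y = spec.mean + fixed + u + e
    if spec.integer_valued:
        y = np.maximum(1.0, np.rint(y))

    var_u = float(np.var(u, ddof=1)) if n > 1 else 0.0
    var_ue = float(np.var(u + e, ddof=1)) if n > 1 else 0.0
    h2_realized = var_u / var_ue if var_ue > 0 else 0.0

    frame = pd.DataFrame({"animal_id": ids})
    for t in TRAITS:
        frame[t] = np.nan
    frame[spec.name] = y
    for fac in FIXED_FACTORS:
        frame[fac] = factors[fac]
    phenos = PhenotypeTable(frame)

    return SimulatedDataset(
        genotypes=genotypes, pedigree=pedigree, phenotypes=phenos,
        trait=spec.name, marker_effects=effects,
        breeding_values=pd.Series(u, index=ids),
        residuals=pd.Series(e, index=ids),
        fixed_part=pd.Series(fixed, index=ids),
        h2_true=spec.h2, h2_realized=h2_realized,
        sigma_a2_true=sigma_a2, sigma_e2_true=sigma_e2, seed=seed)


def simulate_study(n_animals: int, n_snps: int, traits=TRAITS, seed: int = 0,
                   architecture: ArchitectureSpec | None = None,
                   missing_rate: float = 0.0,
                   ) -> tuple[GenotypeMatrix, PhenotypeTable, dict[str, SimulatedDataset]]:
    """One genotype panel shared by the four preset traits.

    Returns the genotypes, a merged phenotype table (shared fixed-effect
    columns from the first trait's assignment) and per-trait ground truth.
    """
    gm, _ = simulate_genotypes(n_animals, n_snps, seed=seed, missing_rate=missing_rate)
    seeds = np.random.SeedSequence(seed).spawn(len(traits) + 1)
    # one herd/year/season assignment per animal, shared by every trait,
    # as in real records
    rng = np.random.default_rng(seeds[-1])
    first = TRAIT_PRESETS[traits[0]]
    shared = {"herd": rng.integers(first.n_herds, size=n_animals),
              "birth_year": rng.integers(first.n_years, size=n_animals),
              "birth_season": rng.integers(first.n_seasons, size=n_animals),
              "calving_year": rng.integers(first.n_years, size=n_animals),
              "calving_season": rng.integers(first.n_seasons, size=n_animals)}
    datasets = {}
    merged = None
    for t, ss in zip(traits, seeds):
        ds = simulate_trait(gm, None, TRAIT_PRESETS[t], architecture,
                            seed=int(ss.generate_state(1)[0] % 2**31),
                            factor_assignments=shared)
        datasets[t] = ds
        f = ds.phenotypes.frame
        if merged is None:
            merged = f.copy()
        else:
            merged[t] = f[t].to_numpy()
    return gm, PhenotypeTable(merged), datasets
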