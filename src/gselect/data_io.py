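"""Readers, writers and containers for genotype, pedigree and phenotype data.

Genotypes travel as additive codes (0/1/2 copies of the counted allele, with a
single missing sentinel) plus a marker map; pedigree and phenotype tables are
thin validated wrappers around :class:`pandas.DataFrame`.  PLINK text
(.ped/.map) and binary (.bed/.bim/.fam, SNP-major) layouts are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: reserved integer marking an unobserved genotype call
MISSING = np.int8(-9)

#: chromosome labels treated as autosomal for cattle (Bos taurus, 29 pairs)
AUTOSOMES = tuple(str(c) for c in range(1, 30))

#: reproductive traits handled by the pipeline
TRAITS = ("afc", "ci", "gl", "naipc")

#: categorical fixed effects entering the animal model
FIXED_FACTORS = ("herd", "birth_year", "birth_season", "calving_year", "calving_season")

#: sentinel for an unknown parent in pedigree files
UNKNOWN_PARENT = "0"


class DataFormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class MarkerMap:
    """Per-SNP metadata: identifier, chromosome, physical position, alleles.

    ``allele_b`` is the counted allele of the additive coding (the minor
    allele as determined at load time); ``allele_a`` is the other allele.
    Positions are 1-based.  Rows are kept ordered by (chromosome, position).
    """

    snp_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.allele_a = np.asarray(self.allele_a, dtype=object)
        self.allele_b = np.asarray(self.allele_b, dtype=object)
        if len(set(self.snp_id)) != self.snp_id.size:
            raise DataFormatError("duplicate snp_id in marker map")
        if (self.position_bp < 0).any():
            raise DataFormatError("negative bp position in marker map")

    def __len__(self) -> int:
        return self.snp_id.size

    def sort_order(self) -> np.ndarray:
        """Stable order by (chromosome, position); autosomes numerically."""

        def chrom_key(c: str) -> tuple[int, str]:
            return (int(c), "") if str(c).isdigit() else (10**6, str(c))

        keys = [(chrom_key(c), p, i) for i, (c, p) in enumerate(zip(self.chromosome, self.position_bp))]
        return np.array([i for _, _, i in sorted(keys, key=lambda t: (t[0], t[1]))], dtype=np.int64)

    def take(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.snp_id[idx], self.chromosome[idx], self.position_bp[idx],
                         self.allele_a[idx], self.allele_b[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": self.snp_id, "chromosome": self.chromosome,
            "position_bp": self.position_bp, "allele_a": self.allele_a,
            "allele_b": self.allele_b,
        })


@dataclass
class GenotypeMatrix:
    """Animals x SNPs additive genotype codes with a marker map.

    ``calls[i, j]`` counts copies of ``map.allele_b[j]`` in animal ``i``
    (0, 1, 2) or equals :data:`MISSING` when both alleles are unobserved.
    """

    animal_ids: np.ndarray
    calls: np.ndarray
    map: MarkerMap

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if len(set(self.animal_ids)) != self.animal_ids.size:
            raise DataFormatError("duplicate animal ids")
        if self.calls.ndim != 2 or self.calls.shape != (self.animal_ids.size, len(self.map)):
            raise DataFormatError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{self.animal_ids.size} animals x {len(self.map)} SNPs")
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise DataFormatError("genotype codes must be 0/1/2 or the missing sentinel")

    @property
    def n_animals(self) -> int:
        return self.animal_ids.size

    @property
    def n_snps(self) -> int:
        return len(self.map)

    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.calls != MISSING

    def snp_call_rate(self) -> np.ndarray:
        return self.observed().mean(axis=0)

    def animal_call_rate(self) -> np.ndarray:
        return self.observed().mean(axis=1)

    def allele_freq(self) -> np.ndarray:
        """Observed frequency of the counted allele (allele_b) per SNP.

        SNPs with no observed calls get NaN.
        """
        obs = self.observed()
        n_obs = obs.sum(axis=0).astype(float)
        counts = np.where(obs, self.calls, 0).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, counts / (2.0 * n_obs), np.nan)

    def subset(self, animal_idx=None, snp_idx=None) -> "GenotypeMatrix":
        a = np.arange(self.n_animals) if animal_idx is None else np.asarray(animal_idx)
        s = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(self.animal_ids[a], self.calls[np.ix_(a, s)], self.map.take(s))


@dataclass
class PedigreeTable:
    """Pedigree records (animal, sire, dam); unknown parent is ``"0"``.

    Records are stored topologically sorted: parents precede offspring.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        required = ["animal", "sire", "dam"]
        if list(f.columns[:3]) != required:
            f = f.rename(columns=dict(zip(f.columns[:3], required)))
        f = f[required].astype(str)
        f = f.replace({"": UNKNOWN_PARENT, "nan": UNKNOWN_PARENT, "<NA>": UNKNOWN_PARENT})
        if f["animal"].duplicated().any():
            dup = f.loc[f["animal"].duplicated(), "animal"].iloc[0]
            raise DataFormatError(f"duplicate pedigree row for animal {dup!r}")
        self.frame = _toposort_pedigree(f)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def animals(self) -> np.ndarray:
        return self.frame["animal"].to_numpy(dtype=object)

    def founders(self) -> np.ndarray:
        f = self.frame
        m = (f["sire"] == UNKNOWN_PARENT) & (f["dam"] == UNKNOWN_PARENT)
        return f.loc[m, "animal"].to_numpy(dtype=object)


def _toposort_pedigree(f: pd.DataFrame) -> pd.DataFrame:
    """Kahn topological sort; raises listing one cycle if the pedigree is cyclic."""
    animals = list(f["animal"])
    known = set(animals)
    parents = {a: [p for p in (s, d) if p in known]
               for a, s, d in zip(f["animal"], f["sire"], f["dam"])}
    indeg = {a: len(parents[a]) for a in animals}
    children: dict[str, list[str]] = {a: [] for a in animals}
    for a, ps in parents.items():
        for p in ps:
            children[p].append(a)
    order = [a for a in animals if indeg[a] == 0]
    queue = list(order)
    while queue:
        p = queue.pop()
        for c in children[p]:
            indeg[c] -= 1
            if indeg[c] == 0:
                order.append(c)
                queue.append(c)
    if len(order) != len(animals):
        leftover = [a for a in animals if indeg[a] > 0]
        cycle = _find_cycle(leftover, parents)
        raise DataFormatError(f"cyclic pedigree: {' -> '.join(cycle)}")
    pos = {a: i for i, a in enumerate(order)}
    return f.iloc[np.argsort([pos[a] for a in f["animal"]], kind="stable")].reset_index(drop=True)


def _find_cycle(nodes: list, parents: dict) -> list:
    node = nodes[0]
    seen: dict[str, int] = {}
    path = []
    while node not in seen:
        seen[node] = len(path)
        path.append(node)
        nxt = [p for p in parents[node] if p in parents]
        node = nxt[0]
    return path[seen[node]:] + [node]


@dataclass
class PhenotypeTable:
    """Trait records plus categorical fixed effects, one row per animal.

    Traits (``afc``, ``ci``, ``gl`` in days; ``naipc`` a count >= 1) may be
    absent (NaN) per animal; the fixed-effect factors must be non-empty for
    any animal with at least one trait record.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame.copy()
        if "animal_id" not in f.columns:
            raise DataFormatError("phenotype table needs an animal_id column")
        f["animal_id"] = f["animal_id"].astype(str)
        if f["animal_id"].duplicated().any():
            raise DataFormatError("duplicate animal_id in phenotype table")
        for t in TRAITS:
            if t not in f.columns:
                f[t] = np.nan
            f[t] = pd.to_numeric(f[t], errors="raise")
        naipc = f["naipc"].dropna()
        if (naipc < 1).any():
            bad = f.loc[f["naipc"] < 1, "animal_id"].iloc[0]
            raise DataFormatError(f"naipc must be >= 1 (animal {bad!r})")
        for t in ("afc", "ci", "gl"):
            vals = f[t].dropna()
            if (vals <= 0).any():
                raise DataFormatError(f"{t} must be strictly positive")
        phenotyped = f[list(TRAITS)].notna().any(axis=1)
        for fac in FIXED_FACTORS:
            if fac not in f.columns:
                raise DataFormatError(f"missing fixed-effect column {fac!r}")
            f[fac] = f[fac].astype(str)
            empty = phenotyped & ((f[fac] == "") | (f[fac] == "nan"))
            if empty.any():
                bad = f.loc[empty, "animal_id"].iloc[0]
                raise DataFormatError(f"empty {fac} level for phenotyped animal {bad!r}")
        self.frame = f.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def animal_ids(self) -> np.ndarray:
        return self.frame["animal_id"].to_numpy(dtype=object)

    def trait_values(self, trait: str) -> pd.Series:
        if trait not in TRAITS:
            raise KeyError(f"unknown trait {trait!r}; expected one of {TRAITS}")
        s = self.frame.set_index("animal_id")[trait]
        return s.dropna()


@dataclass
class RunConfig:
    """Run configuration: paths, QC thresholds, MCMC and CV settings, seed."""

    seed: int = 0
    paths: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    mcmc: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, val in self.qc.items():
            if key.endswith(("_min", "_max")) and not (0.0 <= float(val) <= 1.0):
                raise ValueError(f"QC threshold {key}={val} outside [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# PLINK text layout
# ---------------------------------------------------------------------------


def _read_map(map_path) -> pd.DataFrame:
    m = pd.read_csv(map_path, sep=r"\s+", header=None,
                    names=["chromosome", "snp_id", "cm", "position_bp"],
                    dtype={"chromosome": str, "snp_id": str})
    return m


def read_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Read a .ped/.map pair into a :class:`GenotypeMatrix`.

    The counted allele per SNP is the minor allele among observed calls
    (ties broken lexicographically); ``0 0`` allele pairs become missing.
    """
    mp = _read_map(map_path)
    m = len(mp)
    ids, rows = [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise DataFormatError(
                    f"{ped_path}: line {lineno} has {len(parts)} fields, expected {6 + 2 * m}")
            ids.append(parts[1])
            rows.append(parts[6:])
    alleles = np.array(rows, dtype=object).reshape(len(ids), m, 2) if ids else np.empty((0, m, 2), object)
    calls = np.full((len(ids), m), MISSING, dtype=np.int8)
    allele_a = np.empty(m, dtype=object)
    allele_b = np.empty(m, dtype=object)
    for j in range(m):
        a1 = alleles[:, j, 0]
        a2 = alleles[:, j, 1]
        half = (a1 == "0") != (a2 == "0")
        if half.any():
            i = int(np.flatnonzero(half)[0])
            raise DataFormatError(
                f"half-missing genotype for snp {mp['snp_id'][j]!r}, animal {ids[i]!r}")
        obs = (a1 != "0")
        observed = np.concatenate([a1[obs], a2[obs]])
        uniq, counts = np.unique(observed, return_counts=True)
        if uniq.size > 2:
            raise DataFormatError(f"snp {mp['snp_id'][j]!r} is not biallelic: {sorted(uniq)}")
        if uniq.size == 0:
            allele_a[j], allele_b[j] = "0", "0"
            continue
        if uniq.size == 1:
            allele_a[j], allele_b[j] = uniq[0], "0"
            calls[obs, j] = 0
            continue
        order = sorted(zip(counts, uniq))  # minor first; lexicographic on ties
        allele_b[j] = order[0][1]
        allele_a[j] = order[1][1]
        calls[obs, j] = (a1[obs] == allele_b[j]).astype(np.int8) + (a2[obs] == allele_b[j]).astype(np.int8)
    mm = MarkerMap(mp["snp_id"].to_numpy(object), mp["chromosome"].to_numpy(object),
                   mp["position_bp"].to_numpy(), allele_a, allele_b)
    order = mm.sort_order()
    return GenotypeMatrix(np.array(ids, dtype=object), calls[:, order], mm.take(order))


def write_plink_text(gm: GenotypeMatrix, ped_path, map_path) -> None:
    with open(map_path, "w") as fh:
        for c, s, p in zip(gm.map.chromosome, gm.map.snp_id, gm.map.position_bp):
            fh.write(f"{c}\t{s}\t0\t{p}\n")
    codes = {0: "aa", 1: "ab", 2: "bb"}
    with open(ped_path, "w") as fh:
        for i, aid in enumerate(gm.animal_ids):
            fields = [str(aid), str(aid), "0", "0", "0", "-9"]
            for j in range(gm.n_snps):
                c = gm.calls[i, j]
                if c == MISSING:
                    fields += ["0", "0"]
                else:
                    a, b = gm.map.allele_a[j], gm.map.allele_b[j]
                    pair = codes[int(c)]
                    fields += [a if x == "a" else b for x in pair]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# PLINK binary layout (SNP-major)
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b"
# 2-bit codes in a .bed byte, least significant pair first:
# 00 hom allele_1, 01 missing, 10 het, 11 hom allele_2
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def read_plink_binary(bed_path, bim_path, fam_path) -> GenotypeMatrix:
    """Read a .bed/.bim/.fam triple (SNP-major mode only).

    The .bim allele_1 column is taken as the counted allele, so a triple
    written by :func:`write_plink_binary` round-trips exactly.
    """
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None,
                      names=["chromosome", "snp_id", "cm", "position_bp", "a1", "a2"],
                      dtype=str)
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    ids = fam.iloc[:, 1].to_numpy(dtype=object)
    n, m = len(ids), len(bim)
    raw = Path(bed_path).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise DataFormatError(f"{bed_path}: bad magic bytes {raw[:2]!r}")
    if raw[2:3] == b"\x00":
        raise DataFormatError(f"{bed_path}: individual-major mode is not supported")
    if raw[2:3] != b"\x01":
        raise DataFormatError(f"{bed_path}: unknown mode byte {raw[2:3]!r}")
    per_snp = (n + 3) // 4
    expected = 3 + per_snp * m
    if len(raw) != expected:
        raise DataFormatError(f"{bed_path}: expected {expected} bytes, found {len(raw)}")
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, per_snp)
    # expand each byte into four 2-bit codes
    codes = np.empty((m, per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (data >> (2 * k)) & 0b11
    calls = _BED_DECODE[codes[:, :n]].T.copy()
    mm = MarkerMap(bim["snp_id"].to_numpy(object), bim["chromosome"].to_numpy(object),
                   bim["position_bp"].astype(np.int64).to_numpy(),
                   bim["a2"].to_numpy(object), bim["a1"].to_numpy(object))
    order = mm.sort_order()
    return GenotypeMatrix(ids, calls[:, order], mm.take(order))


def write_plink_binary(gm: GenotypeMatrix, bed_path, bim_path, fam_path) -> None:
    with open(bim_path, "w") as fh:
        for j in range(gm.n_snps):
            fh.write(f"{gm.map.chromosome[j]}\t{gm.map.snp_id[j]}\t0\t"
                     f"{gm.map.position_bp[j]}\t{gm.map.allele_b[j]}\t{gm.map.allele_a[j]}\n")
    with open(fam_path, "w") as fh:
        for aid in gm.animal_ids:
            fh.write(f"{aid} {aid} 0 0 0 -9\n")
    n, m = gm.n_animals, gm.n_snps
    encode = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
    per_snp = (n + 3) // 4
    out = bytearray(_BED_MAGIC + b"\x01")
    for j in range(m):
        col = gm.calls[:, j]
        buf = np.zeros(per_snp, dtype=np.uint8)
        for i in range(n):
            buf[i // 4] |= encode[int(col[i])] << (2 * (i % 4))
        out += buf.tobytes()
    Path(bed_path).write_bytes(bytes(out))


# ---------------------------------------------------------------------------
# pedigree and phenotype tables
# ---------------------------------------------------------------------------


def read_pedigree(path, delimiter: str = ",") -> PedigreeTable:
    f = pd.read_csv(path, sep=delimiter, dtype=str).fillna(UNKNOWN_PARENT)
    return PedigreeTable(f)


def write_pedigree(ped: PedigreeTable, path, delimiter: str = ",") -> None:
    ped.frame.to_csv(path, sep=delimiter, index=False)


def read_phenotypes(path, delimiter: str = ",") -> PhenotypeTable:
    f = pd.read_csv(path, sep=delimiter, dtype={"animal_id": str})
    return PhenotypeTable(f)


def write_phenotypes(ph: PhenotypeTable, path, delimiter: str = ",") -> None:
    ph.frame.to_csv(path, sep=delimiter, index=False)


def describe_phenotypes(ph: PhenotypeTable) -> pd.DataFrame:
    """Per-trait N, mean, sample SD (n-1), min, max; blank moments when N < 2."""
    rows = []
    for t in TRAITS:
        v = ph.frame[t].dropna().to_numpy(dtype=float)
        n = v.size
        rows.append({
            "trait": t, "n": n,
            "mean": v.mean() if n else np.nan,
            "sd": v.std(ddof=1) if n > 1 else np.nan,
            "min": v.min() if n else np.nan,
            "max": v.max() if n else np.nan,
        })
    return pd.DataFrame(rows).set_index("trait")
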