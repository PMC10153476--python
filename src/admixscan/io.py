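"""Domain containers and readers/writers for pseudohaploid genotype data.

The on-disk dialect is EIGENSTRAT: a ``.geno`` file with one line per SNP and
one genotype character per individual, a ``.snp`` file with per-site metadata
(id, chromosome, genetic position in morgans, physical position, ref, alt) and
an ``.ind`` file with individual id, sex and population label.  Genotypes are
pseudohaploid: a single sequencing read's allele is sampled per site, so calls
are coded 0 (ref allele sampled), 2 (alt allele sampled) or 9 (missing).  True
diploid heterozygote codes (1) are rejected by default and can optionally be
collapsed to a random allele with a seeded draw.

Interval filters (e.g. a pre-thresholded mappability mask) are consumed as BED;
BED coordinates are 0-based half-open and SNP positions are 1-based, so a SNP
at position p lies in interval [start, end) iff start <= p - 1 < end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("admixscan")

MESOLITHIC = "MESOLITHIC"
NEOLITHIC = "NEOLITHIC"
ADMIXED = "ADMIXED"
POPULATIONS = (MESOLITHIC, NEOLITHIC, ADMIXED)

#: pseudohaploid genotype codes
REF, ALT, MISSING = 0, 2, 9
VALID_CODES = frozenset({REF, ALT, MISSING})


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SNPTable:
    """Per-site metadata for a panel of SNPs.

    Positions are 1-based physical coordinates, strictly increasing within a
    chromosome; genetic positions are in morgans and non-decreasing within a
    chromosome. Chromosomes are kept in first-appearance order.
    """

    snp_id: np.ndarray          # str
    chromosome: np.ndarray      # str
    position_bp: np.ndarray     # int64, 1-based
    genetic_pos: np.ndarray     # float64, morgans
    ref_allele: np.ndarray      # str (single char)
    alt_allele: np.ndarray      # str (single char)

    def __post_init__(self) -> None:
        n = len(self.snp_id)
        arrays = (self.chromosome, self.position_bp, self.genetic_pos,
                  self.ref_allele, self.alt_allele)
        if any(len(a) != n for a in arrays):
            raise ValueError("SNPTable column lengths differ")
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.genetic_pos = np.asarray(self.genetic_pos, dtype=np.float64)
        if np.any(self.genetic_pos < 0):
            raise ValueError("genetic positions must be non-negative")
        for chrom in self.chromosomes:
            idx = self.chrom_slice(chrom)
            pos = self.position_bp[idx]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}")
            if np.any(np.diff(self.genetic_pos[idx]) < 0):
                raise ValueError(
                    f"genetic positions decrease on chromosome {chrom}")

    def __len__(self) -> int:
        return len(self.snp_id)

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chromosome:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_slice(self, chrom: str) -> np.ndarray:
        """Indices of SNPs on `chrom` (contiguous in a valid table)."""
        return np.flatnonzero(self.chromosome == chrom)

    def take(self, indices: np.ndarray) -> "SNPTable":
        return SNPTable(
            snp_id=self.snp_id[indices],
            chromosome=self.chromosome[indices],
            position_bp=self.position_bp[indices],
            genetic_pos=self.genetic_pos[indices],
            ref_allele=self.ref_allele[indices],
            alt_allele=self.alt_allele[indices],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": self.snp_id, "chromosome": self.chromosome,
            "position_bp": self.position_bp, "genetic_pos": self.genetic_pos,
            "ref": self.ref_allele, "alt": self.alt_allele,
        })


@dataclass
class GenotypeMatrix:
    """Pseudohaploid calls (SNPs x individuals) with population labels."""

    snps: SNPTable
    individual_ids: np.ndarray   # str
    populations: np.ndarray     # str, parallel to individual_ids
    calls: np.ndarray           # int8 (n_snps, n_individuals), codes {0,2,9}

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n_snps, n_ind = self.calls.shape
        if n_snps != len(self.snps):
            raise ValueError("call matrix rows do not match SNP table")
        if n_ind != len(self.individual_ids) or n_ind != len(self.populations):
            raise ValueError("call matrix columns do not match individuals")
        bad = set(np.unique(self.calls)) - VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes {sorted(bad)}; "
                             "pseudohaploid calls must be 0, 2 or 9")
        ids, counts = np.unique(self.individual_ids, return_counts=True)
        dups = ids[counts > 1]
        if len(dups):
            raise ValueError(f"duplicate individual ids: {list(dups[:5])}")

    @property
    def n_snps(self) -> int:
        return self.calls.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[1]

    def population_mask(self, population: str) -> np.ndarray:
        return self.populations == population

    def take_snps(self, indices: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.snps.take(indices), self.individual_ids,
                              self.populations, self.calls[indices])


@dataclass
class FrequencyTable:
    """Per-SNP alternate-allele counts and frequencies, per population.

    ``frequency`` is NaN where a population has no non-missing calls.
    """

    populations: tuple[str, ...]
    alt_count: np.ndarray   # int64 (n_snps, n_pops)
    obs_count: np.ndarray   # int64 (n_snps, n_pops)
    frequency: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.alt_count = np.asarray(self.alt_count, dtype=np.int64)
        self.obs_count = np.asarray(self.obs_count, dtype=np.int64)
        if np.any(self.alt_count > self.obs_count):
            raise ValueError("alt_count exceeds obs_count")
        with np.errstate(invalid="ignore", divide="ignore"):
            self.frequency = np.where(
                self.obs_count > 0, self.alt_count / self.obs_count, np.nan)

    def _col(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError as exc:
            raise KeyError(f"no population {population!r}") from exc

    def freq(self, population: str) -> np.ndarray:
        return self.frequency[:, self._col(population)]

    def obs(self, population: str) -> np.ndarray:
        return self.obs_count[:, self._col(population)]

    def alt(self, population: str) -> np.ndarray:
        return self.alt_count[:, self._col(population)]


@dataclass
class IntervalSet:
    """Half-open [start, end) intervals per chromosome, 0-based like BED.

    Normalized on construction: sorted and overlap-merged per chromosome.
    """

    intervals: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (starts, ends)

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in tuples:
            if end <= start:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            merged: list[list[int]] = []
            for s, e in ivals:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[chrom] = (np.array([m[0] for m in merged], dtype=np.int64),
                          np.array([m[1] for m in merged], dtype=np.int64))
        return cls(out)

    @classmethod
    def from_bed(cls, path: str | Path) -> "IntervalSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                rows.append((parts[0], int(parts[1]), int(parts[2])))
        return cls.from_tuples(rows)

    def contains_positions(self, chromosome: np.ndarray,
                           position_bp: np.ndarray) -> np.ndarray:
        """Membership of 1-based positions, vectorized per chromosome."""
        pos0 = np.asarray(position_bp, dtype=np.int64) - 1  # to 0-based
        out = np.zeros(len(pos0), dtype=bool)
        for chrom, (starts, ends) in self.intervals.items():
            mask = chromosome == chrom
            if not mask.any():
                continue
            idx = np.searchsorted(starts, pos0[mask], side="right") - 1
            hit = (idx >= 0) & (pos0[mask] < ends[np.clip(idx, 0, None)])
            out[np.flatnonzero(mask)[hit]] = True
        return out

    def total_span(self) -> int:
        return int(sum((e - s).sum() for s, e in self.intervals.values()))


# ---------------------------------------------------------------------------
# EIGENSTRAT reading and writing
# ---------------------------------------------------------------------------

def read_eigenstrat(geno_path: str | Path, snp_path: str | Path,
                    ind_path: str | Path, *, allow_diploid: bool = False,
                    seed: int | None = None) -> GenotypeMatrix:
    """Read an EIGENSTRAT triplet into a :class:`GenotypeMatrix`.

    Diploid heterozygote codes (``1``) raise unless ``allow_diploid`` is set,
    in which case each is replaced by a random allele drawn with ``seed``.
    """
    snp_rows = []
    with open(snp_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 6:
                sid, chrom, gpos, pos, ref, alt = parts
            elif len(parts) == 4:
                sid, chrom, gpos, pos = parts
                ref, alt = "N", "N"
            else:
                raise ValueError(f"malformed .snp line: {line!r}")
            snp_rows.append((sid, chrom, float(gpos), int(pos), ref, alt))
    snps = SNPTable(
        snp_id=np.array([r[0] for r in snp_rows], dtype=object),
        chromosome=np.array([r[1] for r in snp_rows], dtype=object),
        position_bp=np.array([r[3] for r in snp_rows], dtype=np.int64),
        genetic_pos=np.array([r[2] for r in snp_rows], dtype=np.float64),
        ref_allele=np.array([r[4] for r in snp_rows], dtype=object),
        alt_allele=np.array([r[5] for r in snp_rows], dtype=object),
    )

    ind_ids, pops = [], []
    with open(ind_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3:
                raise ValueError(f"malformed .ind line: {line!r}")
            ind_ids.append(parts[0])
            pops.append(parts[2])
    n_ind = len(ind_ids)

    lines = []
    with open(geno_path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                lines.append(line)
    if len(lines) != len(snps):
        raise ValueError(
            f".geno has {len(lines)} rows but .snp has {len(snps)} sites")
    calls = np.empty((len(snps), n_ind), dtype=np.int8)
    rng = np.random.default_rng(seed) if allow_diploid else None
    for i, line in enumerate(lines):
        if len(line) != n_ind:
            raise ValueError(
                f".geno line {i + 1} has {len(line)} genotypes, "
                f"expected {n_ind}")
        row = np.frombuffer(line.encode("ascii"), dtype=np.uint8) - ord("0")
        bad = ~np.isin(row, (0, 1, 2, 9))
        if bad.any():
            raise ValueError(
                f"unknown genotype character {line[int(np.argmax(bad))]!r} "
                f"on .geno line {i + 1}")
        het = row == 1
        if het.any():
            if rng is None:
                raise ValueError(
                    "diploid heterozygote code 1 encountered; pass "
                    "allow_diploid=True to sample a random allele")
            row = row.copy()
            row[het] = rng.choice((REF, ALT), size=int(het.sum()))
        calls[i] = row
    return GenotypeMatrix(snps, np.array(ind_ids, dtype=object),
                          np.array(pops, dtype=object), calls)


def write_eigenstrat(gm: GenotypeMatrix, out_prefix: str | Path
                     ) -> tuple[Path, Path, Path]:
    """Write a GenotypeMatrix as ``<prefix>.geno/.snp/.ind``; roundtrip-exact."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    geno_path = prefix.with_suffix(".geno")
    snp_path = prefix.with_suffix(".snp")
    ind_path = prefix.with_suffix(".ind")

    digits = np.array([str(d) for d in range(10)], dtype=object)
    with open(geno_path, "w") as fh:
        for row in gm.calls:
            fh.write("".join(digits[row]) + "\n")
    s = gm.snps
    with open(snp_path, "w") as fh:
        for i in range(len(s)):
            fh.write(f"{s.snp_id[i]}\t{s.chromosome[i]}\t"
                     f"{s.genetic_pos[i]:.10g}\t{s.position_bp[i]}\t"
                     f"{s.ref_allele[i]}\t{s.alt_allele[i]}\n")
    with open(ind_path, "w") as fh:
        for iid, pop in zip(gm.individual_ids, gm.populations):
            fh.write(f"{iid}\tU\t{pop}\n")
    return geno_path, snp_path, ind_path


# ---------------------------------------------------------------------------
# Derived tables and site filters
# ---------------------------------------------------------------------------

def compute_frequencies(gm: GenotypeMatrix,
                        populations: Sequence[str] | None = None
                        ) -> FrequencyTable:
    """Alternate-allele counts per population.

    Each pseudohaploid individual contributes exactly one allele per
    non-missing site, so obs_count is the number of non-missing calls and
    alt_count the number of code-2 calls.
    """
    if populations is None:
        populations = [p for p in POPULATIONS
                       if p in set(gm.populations)]
        extra = sorted(set(gm.populations) - set(populations))
        populations = list(populations) + extra
    pops = tuple(populations)
    n_snps = gm.n_snps
    alt = np.zeros((n_snps, len(pops)), dtype=np.int64)
    obs = np.zeros((n_snps, len(pops)), dtype=np.int64)
    for j, pop in enumerate(pops):
        cols = gm.population_mask(pop)
        sub = gm.calls[:, cols]
        obs[:, j] = (sub != MISSING).sum(axis=1)
        alt[:, j] = (sub == ALT).sum(axis=1)
    return FrequencyTable(pops, alt, obs)


def filter_sites(gm: GenotypeMatrix,
                 mappability: IntervalSet | None = None,
                 min_neolithic_obs: int = 20,
                 maf_min: float = 0.0) -> GenotypeMatrix:
    """Site filters applied before any scan.

    Keeps SNPs that (a) lie inside the retained-mappability intervals, (b)
    have at least ``min_neolithic_obs`` non-missing Neolithic pseudohaploid
    genotypes, and (c), when ``maf_min > 0``, have pooled (all individuals)
    minor-allele frequency strictly above ``maf_min``. SNP order is preserved;
    the operation is idempotent.
    """
    keep = np.ones(gm.n_snps, dtype=bool)
    if mappability is not None:
        keep &= mappability.contains_positions(gm.snps.chromosome,
                                               gm.snps.position_bp)
    if min_neolithic_obs > 0:
        freqs = compute_frequencies(gm)
        if NEOLITHIC in freqs.populations:
            keep &= freqs.obs(NEOLITHIC) >= min_neolithic_obs
        else:
            logger.warning("no NEOLITHIC individuals; skipping the "
                           "min-observation filter")
    if maf_min > 0:
        obs = (gm.calls != MISSING).sum(axis=1)
        alt = (gm.calls == ALT).sum(axis=1)
        with np.errstate(invalid="ignore"):
            p = np.where(obs > 0, alt / np.maximum(obs, 1), np.nan)
        maf = np.minimum(p, 1.0 - p)
        keep &= np.nan_to_num(maf, nan=-1.0) > maf_min
    logger.info("filter_sites: kept %d of %d SNPs", int(keep.sum()), gm.n_snps)
    return gm.take_snps(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# Recombination map
# ---------------------------------------------------------------------------

DEFAULT_CM_PER_MB = 1.0


def read_recombination_map(path: str | Path) -> pd.DataFrame:
    """Tab-separated map: chromosome, position_bp, cumulative morgans."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chromosome", "position_bp", "morgans"],
                     dtype={"chromosome": str})
    for chrom, grp in df.groupby("chromosome", sort=False):
        if np.any(np.diff(grp["position_bp"].to_numpy()) <= 0):
            raise ValueError(f"map positions not increasing on {chrom}")
        if np.any(np.diff(grp["morgans"].to_numpy()) < 0):
            raise ValueError(f"map morgans decrease on {chrom}")
    return df


def interpolate_genetic_positions(snps: SNPTable,
                                  recmap: pd.DataFrame | None) -> np.ndarray:
    """Genetic positions (morgans) for every SNP.

    Linear interpolation within the map; chromosomes absent from the map fall
    back to a constant 1 cM/Mb and the fallback is logged.
    """
    out = np.empty(len(snps), dtype=np.float64)
    groups = ({chrom: grp for chrom, grp in recmap.groupby("chromosome",
                                                           sort=False)}
              if recmap is not None else {})
    for chrom in snps.chromosomes:
        idx = snps.chrom_slice(chrom)
        pos = snps.position_bp[idx]
        grp = groups.get(chrom)
        if grp is None:
            logger.warning("no recombination map for chromosome %s; "
                           "applying constant %g cM/Mb", chrom,
                           DEFAULT_CM_PER_MB)
            out[idx] = pos * (DEFAULT_CM_PER_MB / 100.0 / 1e6)
        else:
            out[idx] = np.interp(pos, grp["position_bp"].to_numpy(),
                                 grp["morgans"].to_numpy())
    return out
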