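"""Synthetic admixed cohorts with known ground truth.

The generator emulates the study system: two diverged source populations
(Mesolithic-like hunter-gatherers and Neolithic-like farmers) and a cohort
admixed in a single pulse of proportion ``alpha`` (default 0.3 Mesolithic),
``t`` generations (default 35) before sampling, genotyped as low-coverage
pseudohaploid data with missingness.

Source allele frequencies follow the Balding-Nichols model: an ancestral
frequency p0 drawn uniformly, then per-source frequencies
Beta(p0*(1-F)/F, (1-p0)*(1-F)/F) with drift parameters F per source.  Each
admixed haplotype's ancestry along the genetic map is a two-state Markov jump
process — recombination events at rate t per morgan, each redrawing ancestry
from Bernoulli(alpha) — which is exactly the generative model the local
ancestry HMM assumes, so simulator-vs-inference consistency is exact.

Loci under post-admixture selection are injected by conditioning the tract
process: at a focal SNP the haplotype's ancestry is Mesolithic with
probability alpha + delta and the chain is simulated outward from the focal
point (the jump process is reversible, so this is the exact conditional law
for one locus per chromosome; with several loci per chromosome, segments are
joined at midpoints between foci, exact when foci are several tract lengths
apart).  An optional frequency shift additionally perturbs the admixed
cohort's allele emissions around the focal SNP, mimicking direct selection on
the allele itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ADMIXED, ALT, MESOLITHIC, MISSING, NEOLITHIC, REF, \
    GenotypeMatrix, SNPTable

logger = logging.getLogger("admixscan")


# ---------------------------------------------------------------------------
# Configuration and truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectedLocus:
    """A post-admixture selection target.

    ``ancestry_shift`` moves the focal Mesolithic ancestry probability from
    alpha to alpha + shift (positive = Mesolithic excess); ``frequency_shift``
    additionally moves admixed allele emissions toward the alternate allele
    within ``SimulationConfig.freq_shift_radius_bp`` of the focal position.
    """

    chromosome: str
    position_bp: int
    ancestry_shift: float
    frequency_shift: float = 0.0


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the admixture model under study (alpha = 0.3, t = 35
    generations) at desk scale: six 100 Mb chromosomes of 1 morgan each
    (1 cM/Mb), 2,000 SNPs per chromosome, source panels of 125 and 55
    individuals, 150 admixed individuals, and 30% pseudohaploid missingness
    typical of ancient-DNA capture data.
    """

    n_chromosomes: int = 6
    n_snps_per_chrom: int = 2_000
    chrom_length_bp: int = 100_000_000
    chrom_length_morgans: float = 1.0
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    f_mes: float = 0.15
    f_neo: float = 0.10
    alpha: float = 0.3
    t_generations: float = 35.0
    n_mesolithic: int = 125
    n_neolithic: int = 55
    n_admixed: int = 150
    miss_rate: float = 0.3
    coverage_mode: str = "pseudohaploid"     # or "read_counts"
    mean_depth: float = 1.0
    selected_loci: tuple[SelectedLocus, ...] = ()
    freq_shift_radius_bp: int = 1_500_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.t_generations < 1:
            raise ValueError("pulse time must be >= 1 generation")
        for name, f in (("f_mes", self.f_mes), ("f_neo", self.f_neo)):
            if not 0.0 < f < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not 0.0 <= self.miss_rate <= 1.0:
            raise ValueError("miss_rate must lie in [0, 1]")
        if self.mean_depth < 0:
            raise ValueError("mean read depth must be non-negative")
        if self.coverage_mode not in ("pseudohaploid", "read_counts"):
            raise ValueError("coverage_mode must be 'pseudohaploid' or "
                             "'read_counts'")
        for locus in self.selected_loci:
            if not -self.alpha <= locus.ancestry_shift <= 1.0 - self.alpha:
                raise ValueError("ancestry_shift must keep the focal "
                                 "probability in [0, 1]")

    @property
    def chromosome_names(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]


@dataclass
class SourceFrequencies:
    """Simulated site list with ancestral and per-source frequencies."""

    snps: SNPTable
    p_ancestral: np.ndarray
    p_mes: np.ndarray
    p_neo: np.ndarray


@dataclass
class TruthSet:
    """Simulator ground truth for downstream validation.

    ``tracts`` tiles each chromosome per haplotype with 1-based inclusive
    [start_bp, end_bp] ancestry segments; ``true_mesolithic_fraction`` is the
    cohort-mean haplotype ancestry indicator per SNP.
    """

    snps: SNPTable
    p_mes: np.ndarray
    p_neo: np.ndarray
    haplotype_states: np.ndarray        # bool (n_snps, n_haplotypes)
    true_mesolithic_fraction: np.ndarray
    tracts: pd.DataFrame
    selected_loci: tuple[SelectedLocus, ...]

    def fraction_from_tracts(self) -> np.ndarray:
        """Recompute per-SNP cohort ancestry fraction from tract boundaries."""
        n_hap = int(self.tracts["haplotype"].max()) + 1
        counts = np.zeros(len(self.snps))
        mes = self.tracts[self.tracts["ancestry"] == MESOLITHIC]
        for chrom, grp in mes.groupby("chromosome", sort=False):
            idx = self.snps.chrom_slice(chrom)
            pos = self.snps.position_bp[idx]
            for start, end in zip(grp["start_bp"], grp["end_bp"]):
                lo, hi = np.searchsorted(pos, (start, end + 1))
                counts[idx[lo:hi]] += 1
        return counts / n_hap


@dataclass
class SimulationResult:
    genotypes: GenotypeMatrix
    truth: TruthSet
    source: SourceFrequencies
    read_counts: tuple[np.ndarray, np.ndarray] | None = None  # (ref, alt)


# ---------------------------------------------------------------------------
# Source frequencies
# ---------------------------------------------------------------------------

def _simulate_snp_table(config: SimulationConfig,
                        rng: np.random.Generator) -> SNPTable:
    """Jittered-grid SNP positions with a constant-rate genetic map."""
    chroms, positions, gpos = [], [], []
    spacing = config.chrom_length_bp / config.n_snps_per_chrom
    for chrom in config.chromosome_names:
        offs = rng.uniform(0.0, spacing, size=config.n_snps_per_chrom)
        pos = (np.arange(config.n_snps_per_chrom) * spacing + offs).astype(
            np.int64) + 1
        chroms.append(np.full(config.n_snps_per_chrom, chrom, dtype=object))
        positions.append(pos)
        gpos.append(pos / config.chrom_length_bp
                    * config.chrom_length_morgans)
    chrom_arr = np.concatenate(chroms)
    pos_arr = np.concatenate(positions)
    n = len(pos_arr)
    return SNPTable(
        snp_id=np.array([f"snp_{c}_{p}" for c, p in zip(chrom_arr, pos_arr)],
                        dtype=object),
        chromosome=chrom_arr,
        position_bp=pos_arr,
        genetic_pos=np.concatenate(gpos),
        ref_allele=np.full(n, "A", dtype=object),
        alt_allele=np.full(n, "G", dtype=object),
    )


def simulate_source_frequencies(config: SimulationConfig,
                                rng: np.random.Generator | None = None
                                ) -> SourceFrequencies:
    """Balding-Nichols source frequencies around a uniform ancestral p0."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    snps = _simulate_snp_table(config, rng)
    lo, hi = config.ancestral_freq_range
    p0 = rng.uniform(lo, hi, size=len(snps))
    freqs = {}
    for name, f in (("mes", config.f_mes), ("neo", config.f_neo)):
        c = (1.0 - f) / f
        freqs[name] = rng.beta(p0 * c, (1.0 - p0) * c)
    return SourceFrequencies(snps, p0, freqs["mes"], freqs["neo"])


# ---------------------------------------------------------------------------
# Ancestry tract process
# ---------------------------------------------------------------------------

def _chain_step(state: np.ndarray, s: float, alpha: float,
                rng: np.random.Generator) -> np.ndarray:
    """One interval of the jump process: switch w.p. s, redraw Bern(alpha)."""
    event = rng.random(len(state)) < s
    redraw = rng.random(len(state)) < alpha
    return np.where(event, redraw, state)


def _simulate_chrom_states(switch: np.ndarray, alpha: float, n_hap: int,
                           focal: list[tuple[int, float]],
                           rng: np.random.Generator) -> np.ndarray:
    """Ancestry states (m, n_hap) for one chromosome.

    ``switch[i]`` is the switch probability over the interval between SNPs i
    and i+1.  ``focal`` lists (snp_index, mesolithic_probability) conditioning
    points; without any, a plain forward chain is drawn.  With conditioning,
    each focal point owns the segment up to the midpoint toward its
    neighbours and the (reversible) chain is run outward from the focal SNP.
    """
    m = len(switch) + 1
    states = np.empty((m, n_hap), dtype=bool)
    if not focal:
        states[0] = rng.random(n_hap) < alpha
        for i in range(1, m):
            states[i] = _chain_step(states[i - 1], switch[i - 1], alpha, rng)
        return states

    focal = sorted(focal)
    js = [j for j, _ in focal]
    bounds = [0] + [(js[k] + js[k + 1]) // 2 + 1 for k in range(len(js) - 1)] + [m]
    for (j, prob), seg_lo, seg_hi in zip(focal, bounds[:-1], bounds[1:]):
        states[j] = rng.random(n_hap) < prob
        for i in range(j + 1, seg_hi):
            states[i] = _chain_step(states[i - 1], switch[i - 1], alpha, rng)
        for i in range(j - 1, seg_lo - 1, -1):
            states[i] = _chain_step(states[i + 1], switch[i], alpha, rng)
    return states


def _tracts_from_states(states: np.ndarray, pos: np.ndarray, chrom: str,
                        chrom_length: int, hap_offset: int) -> pd.DataFrame:
    """Collapse per-SNP states into tract segments tiling [1, chrom_length]."""
    rows = []
    m, n_hap = states.shape
    # tract boundaries at midpoints between adjacent SNPs of differing state
    for h in range(n_hap):
        col = states[:, h]
        change = np.flatnonzero(col[1:] != col[:-1])
        cuts = ((pos[change] + pos[change + 1]) // 2).astype(np.int64)
        starts = np.concatenate(([1], cuts + 1))
        ends = np.concatenate((cuts, [chrom_length]))
        anc_idx = np.concatenate(([0], change + 1))
        for s, e, a in zip(starts, ends, col[anc_idx]):
            rows.append((hap_offset + h, chrom, int(s), int(e),
                         MESOLITHIC if a else NEOLITHIC))
    return pd.DataFrame(rows, columns=["haplotype", "chromosome", "start_bp",
                                       "end_bp", "ancestry"])


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_admixed_cohort(config: SimulationConfig,
                            source: SourceFrequencies,
                            rng: np.random.Generator | None = None
                            ) -> SimulationResult:
    """Draw the full three-group cohort and its truth set.

    Source-group genotypes are drawn directly from the source frequencies;
    admixed genotypes follow the tract process.  Calls are pseudohaploidized
    (or reduced to read counts) according to the coverage model.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    snps = source.snps
    n_snps = len(snps)
    n_hap = 2 * config.n_admixed

    # map selected loci to focal SNP indices
    focal_by_chrom: dict[str, list[tuple[int, float]]] = {}
    for locus in config.selected_loci:
        idx = snps.chrom_slice(locus.chromosome)
        if len(idx) == 0 or not (snps.position_bp[idx[0]]
                                 <= locus.position_bp
                                 <= snps.position_bp[idx[-1]]):
            raise ValueError(f"selected locus {locus.chromosome}:"
                             f"{locus.position_bp} outside simulated SNPs")
        local = int(np.argmin(np.abs(snps.position_bp[idx]
                                     - locus.position_bp)))
        focal_by_chrom.setdefault(locus.chromosome, []).append(
            (local, config.alpha + locus.ancestry_shift))

    states = np.empty((n_snps, n_hap), dtype=bool)
    tract_frames = []
    for chrom in snps.chromosomes:
        idx = snps.chrom_slice(chrom)
        gpos = snps.genetic_pos[idx]
        switch = 1.0 - np.exp(-config.t_generations * np.diff(gpos))
        st = _simulate_chrom_states(switch, config.alpha, n_hap,
                                    focal_by_chrom.get(chrom, []), rng)
        states[idx] = st
        tract_frames.append(_tracts_from_states(
            st, snps.position_bp[idx], chrom, config.chrom_length_bp, 0))
    tracts = pd.concat(tract_frames, ignore_index=True)

    # admixed haplotype allele emission probabilities
    p_emit = np.where(states, source.p_mes[:, None], source.p_neo[:, None])
    for locus in config.selected_loci:
        if locus.frequency_shift == 0.0:
            continue
        near = ((snps.chromosome == locus.chromosome)
                & (np.abs(snps.position_bp - locus.position_bp)
                   <= config.freq_shift_radius_bp))
        p_emit[near] = np.clip(p_emit[near] + locus.frequency_shift, 0.0, 1.0)
    adm_alleles = rng.random((n_snps, n_hap)) < p_emit

    # source individuals: two alleles each, straight from source frequencies
    mes_h1 = rng.random((n_snps, config.n_mesolithic)) < source.p_mes[:, None]
    mes_h2 = rng.random((n_snps, config.n_mesolithic)) < source.p_mes[:, None]
    neo_h1 = rng.random((n_snps, config.n_neolithic)) < source.p_neo[:, None]
    neo_h2 = rng.random((n_snps, config.n_neolithic)) < source.p_neo[:, None]

    h1 = np.concatenate([mes_h1, neo_h1, adm_alleles[:, 0::2]], axis=1)
    h2 = np.concatenate([mes_h2, neo_h2, adm_alleles[:, 1::2]], axis=1)
    calls, read_counts = pseudohaploidize(
        h1, h2, miss_rate=config.miss_rate, rng=rng,
        mode=config.coverage_mode, mean_depth=config.mean_depth)

    ids = np.array(
        [f"MES{i:04d}" for i in range(config.n_mesolithic)]
        + [f"NEO{i:04d}" for i in range(config.n_neolithic)]
        + [f"ADM{i:04d}" for i in range(config.n_admixed)], dtype=object)
    pops = np.array([MESOLITHIC] * config.n_mesolithic
                    + [NEOLITHIC] * config.n_neolithic
                    + [ADMIXED] * config.n_admixed, dtype=object)
    gm = GenotypeMatrix(snps, ids, pops, calls)

    truth = TruthSet(snps, source.p_mes, source.p_neo, states,
                     states.mean(axis=1), tracts, config.selected_loci)
    return SimulationResult(gm, truth, source, read_counts)


def pseudohaploidize(hap1_alt: np.ndarray, hap2_alt: np.ndarray, *,
                     miss_rate: float, rng: np.random.Generator,
                     mode: str = "pseudohaploid", mean_depth: float = 1.0
                     ) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray] | None]:
    """Reduce diploid allele truth to pseudohaploid calls.

    In ``pseudohaploid`` mode each site emits one uniformly sampled allele of
    the two, or 9 with probability ``miss_rate`` — single-allele sampling is
    unbiased for the allele frequency.  In ``read_counts`` mode reads are
    Poisson(mean_depth) split binomially by the individual's allele dosage;
    the call transcribes one random read (9 when no reads survive), and the
    per-site (ref, alt) read counts are returned alongside.
    """
    hap1_alt = np.asarray(hap1_alt, dtype=bool)
    hap2_alt = np.asarray(hap2_alt, dtype=bool)
    if hap1_alt.shape != hap2_alt.shape:
        raise ValueError("haplotype matrices differ in shape")
    if mean_depth < 0:
        raise ValueError("mean read depth must be non-negative")
    shape = hap1_alt.shape

    if mode == "pseudohaploid":
        pick_second = rng.random(shape) < 0.5
        alt = np.where(pick_second, hap2_alt, hap1_alt)
        calls = np.where(alt, ALT, REF).astype(np.int8)
        miss = rng.random(shape) < miss_rate
        calls[miss] = MISSING
        return calls, None
    if mode != "read_counts":
        raise ValueError("mode must be 'pseudohaploid' or 'read_counts'")

    depth = rng.poisson(mean_depth, size=shape)
    miss = rng.random(shape) < miss_rate
    depth[miss] = 0
    dosage = hap1_alt.astype(np.int64) + hap2_alt
    alt_reads = rng.binomial(depth, dosage / 2.0)
    ref_reads = depth - alt_reads
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(depth > 0, alt_reads / np.maximum(depth, 1), 0.0)
    calls = np.where(rng.random(shape) < p_alt, ALT, REF).astype(np.int8)
    calls[depth == 0] = MISSING
    return calls, (ref_reads, alt_reads)


def simulate_cohort(config: SimulationConfig,
                    source: SourceFrequencies | None = None
                    ) -> SimulationResult:
    """End-to-end seeded simulation: source frequencies, cohort, truth."""
    rng = np.random.default_rng(config.seed)
    if source is None:
        source = simulate_source_frequencies(config, rng)
    return simulate_admixed_cohort(config, source, rng)


# ---------------------------------------------------------------------------
# Trait association fixtures
# ---------------------------------------------------------------------------

def spaced_indices(snps: SNPTable, n: int, min_gap_bp: int,
                   rng: np.random.Generator, edge_snps: int = 30
                   ) -> np.ndarray:
    """n SNP indices at >= min_gap_bp spacing, away from chromosome edges."""
    candidates = []
    for chrom in snps.chromosomes:
        idx = snps.chrom_slice(chrom)
        if len(idx) > 2 * edge_snps:
            candidates.append(idx[edge_snps:-edge_snps])
    pool = np.concatenate(candidates)
    order = rng.permutation(len(pool))
    chosen: list[int] = []
    for i in order:
        j = pool[i]
        ok = all(snps.chromosome[j] != snps.chromosome[k]
                 or abs(int(snps.position_bp[j]) - int(snps.position_bp[k]))
                 >= min_gap_bp for k in chosen)
        if ok:
            chosen.append(int(j))
            if len(chosen) == n:
                break
    if len(chosen) < n:
        raise ValueError("could not place that many spaced hits")
    return np.array(sorted(chosen))


def simulate_trait_associations(source: SourceFrequencies, n_hits: int,
                                rng: np.random.Generator, *,
                                effect_sd: float = 0.1,
                                correlation: float = 0.0,
                                frac_on_panel: float = 1.0,
                                min_gap_bp: int = 2_000_000,
                                log10p_range: tuple[float, float] = (-30.0, -9.0)
                                ) -> pd.DataFrame:
    """GWAS-style association table over simulated SNPs.

    Effect sizes are N(0, effect_sd) mixed with the standardized signed
    source frequency difference (p_neo - p_mes) by ``correlation`` (0 = null
    trait, 1 = fully aligned with the ancestry-informative axis).  A fraction
    ``1 - frac_on_panel`` of hits is displaced off the SNP panel (their
    positions match no panel site).  Columns: snp, chromosome, position_bp,
    effect_allele, other_allele, beta, p.
    """
    if n_hits == 0:
        return pd.DataFrame(columns=["snp", "chromosome", "position_bp",
                                     "effect_allele", "other_allele", "beta",
                                     "p"])
    snps = source.snps
    hits = spaced_indices(snps, n_hits, min_gap_bp, rng)
    diff = source.p_neo[hits] - source.p_mes[hits]
    z = (diff - diff.mean()) / (diff.std() or 1.0)
    noise = rng.normal(size=n_hits)
    beta = effect_sd * (correlation * z
                        + np.sqrt(max(0.0, 1.0 - correlation ** 2)) * noise)
    pvals = 10.0 ** rng.uniform(*log10p_range, size=n_hits)

    pos = snps.position_bp[hits].astype(np.int64)
    off_panel = rng.random(n_hits) >= frac_on_panel
    pos = np.where(off_panel, pos + 487, pos)   # guaranteed off-grid offset
    return pd.DataFrame({
        "snp": np.where(off_panel,
                        np.array([f"offpanel_{i}" for i in range(n_hits)],
                                 dtype=object),
                        snps.snp_id[hits]),
        "chromosome": snps.chromosome[hits],
        "position_bp": pos,
        "effect_allele": snps.alt_allele[hits],
        "other_allele": snps.ref_allele[hits],
        "beta": beta,
        "p": pvals,
    })


def simulate_polygenic_scenario(config: SimulationConfig, n_hits: int = 30,
                                ancestry_shift: float = 0.15,
                                aligned: bool = True,
                                effect_sd: float = 0.1,
                                min_gap_bp: int = 4_000_000
                                ) -> tuple[SimulationResult, pd.DataFrame]:
    """Cohort plus trait table for polygenic-test calibration and power.

    With ``aligned=True``, each hit SNP becomes a selected locus whose
    ancestry shift (magnitude ``ancestry_shift``) points toward the source
    carrying more of the trait-increasing allele, so local ancestry deviation
    and the ancestry-weighted effect w = beta*(p_neo - p_mes) are coupled.
    With ``aligned=False`` the trait is null: no loci are injected.
    """
    rng = np.random.default_rng(config.seed)
    source = simulate_source_frequencies(config, rng)
    assoc = simulate_trait_associations(source, n_hits, rng,
                                        effect_sd=effect_sd,
                                        min_gap_bp=min_gap_bp)
    loci: list[SelectedLocus] = []
    if aligned and n_hits:
        snp_index = {s: i for i, s in enumerate(source.snps.snp_id)}
        for _, row in assoc.iterrows():
            i = snp_index[row["snp"]]
            w = row["beta"] * (source.p_neo[i] - source.p_mes[i])
            shift = -ancestry_shift * np.sign(w) if w != 0 else 0.0
            loci.append(SelectedLocus(row["chromosome"],
                                      int(row["position_bp"]), float(shift)))
    scenario = replace(config, selected_loci=tuple(loci))
    result = simulate_admixed_cohort(scenario, source, rng)
    return result, assoc


def write_truth(truth: TruthSet, prefix) -> None:
    """Truth sidecars: per-SNP ancestry fraction and selected-locus registry."""
    from pathlib import Path
    prefix = Path(prefix)
    pd.DataFrame({
        "chromosome": truth.snps.chromosome,
        "position_bp": truth.snps.position_bp,
        "true_mesolithic_fraction": truth.true_mesolithic_fraction,
    }).to_csv(prefix.with_suffix(".truth.tsv"), sep="\t", index=False,
              float_format="%.10g")
    pd.DataFrame(
        [(l.chromosome, l.position_bp, l.ancestry_shift, l.frequency_shift)
         for l in truth.selected_loci],
        columns=["chromosome", "position_bp", "ancestry_shift",
                 "frequency_shift"],
    ).to_csv(prefix.with_suffix(".selected.tsv"), sep="\t", index=False,
             float_format="%.10g")
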