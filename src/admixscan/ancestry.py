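"""Two-source hidden Markov model for local ancestry in pseudohaploid data.

The cohort descends from a single admixture pulse between a minority source
(Mesolithic-like, genome-wide proportion ``alpha``) and a majority source
(Neolithic-like), ``t`` generations before sampling.  Along the genetic map,
each haplotype's ancestry is a two-state Markov jump process: recombination
events since the pulse arrive at rate ``t`` per morgan and each event redraws
the ancestry from Bernoulli(alpha), giving the per-interval haplotype switch
probability s = 1 - exp(-t*d) over d morgans.  Hidden states are the diploid
Mesolithic dosage k in {0, 1, 2} (haploid mode: k in {0, 1}), with
Hardy-Weinberg stationary prior (alpha^2, 2*alpha*(1-alpha), (1-alpha)^2 for
k = 2, 1, 0) and transitions from two independent haplotype chains collapsed
to dosage.

Emissions use panel allele frequencies from the two sources: at dosage k the
alternate-allele probability is q_k = (k/ploidy)*p_mes + (1-k/ploidy)*p_neo
(pseudocount-smoothed when built from counts).  A pseudohaploid call is one
Bernoulli(q_k) allele; read counts are Binomial(reads, q_k); missing sites
contribute likelihood 1, preserving chain continuity across gaps.

Posterior decoding is by scaled forward-backward, batched across individuals.
The cohort-level summary is the local-ancestry-deviation (LAD) track: the
window-averaged cohort mean Mesolithic fraction, centered on the mean of a
spaced (approximately independent) null subsample and standardized by its
standard deviation.  Positive LAD means Mesolithic excess.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ALT, REF, FrequencyTable, MESOLITHIC, NEOLITHIC, SNPTable
from .nullfit import MIN_GAP_BP_DEFAULT, NullSample, spaced_subsample, z_scores
from .scan import WINDOW_SNPS_DEFAULT, sliding_windows

logger = logging.getLogger("admixscan")

ALPHA_DEFAULT = 0.3       # genome-wide Mesolithic proportion
T_GENERATIONS_DEFAULT = 35
NE_DEFAULT = 10_000
PSEUDOCOUNT_DEFAULT = 0.5


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

@dataclass
class HmmSpec:
    """Fully specified local-ancestry HMM over a fixed site list.

    States are Mesolithic dosage k = 0..ploidy; ``trans[i]`` is the transition
    matrix over the i-th inter-site interval (stationary rows at chromosome
    boundaries, so chromosomes are independent).
    """

    alpha: float
    t_generations: float
    ne: float
    ploidy: int
    snps: SNPTable
    prior: np.ndarray          # (K,)
    trans: np.ndarray          # (n_sites - 1, K, K)
    emit_alt: np.ndarray       # (n_sites, K): P(alt allele | dosage k)

    @property
    def n_states(self) -> int:
        return self.ploidy + 1

    @property
    def n_sites(self) -> int:
        return len(self.snps)

    @property
    def dosage_values(self) -> np.ndarray:
        return np.arange(self.n_states, dtype=np.float64)


def _haplotype_transition(s: np.ndarray, alpha: float) -> tuple[np.ndarray, ...]:
    """Per-interval haplotype transition entries (Mes->Mes, Mes->Neo, ...)."""
    p_mm = 1.0 - s * (1.0 - alpha)
    p_mn = s * (1.0 - alpha)
    p_nm = s * alpha
    p_nn = 1.0 - s * alpha
    return p_mm, p_mn, p_nm, p_nn


def smoothed_panel_frequencies(freqs: FrequencyTable,
                               pseudocount: float = PSEUDOCOUNT_DEFAULT
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Pseudocount-smoothed source frequencies (p_mes, p_neo).

    Sites where a panel has no observations fall back to the smoothed prior
    0.5 (the pseudocounts alone), i.e. the site is uninformative there.
    """
    out = []
    for pop in (MESOLITHIC, NEOLITHIC):
        alt = freqs.alt(pop).astype(float)
        obs = freqs.obs(pop).astype(float)
        out.append((alt + pseudocount) / (obs + 2.0 * pseudocount))
    return out[0], out[1]


def build_hmm(alpha: float = ALPHA_DEFAULT,
              t_generations: float = T_GENERATIONS_DEFAULT,
              ne: float = NE_DEFAULT,
              snps: SNPTable = None,
              panel_freqs: FrequencyTable | tuple[np.ndarray, np.ndarray] = None,
              mode: str = "diploid",
              pseudocount: float = PSEUDOCOUNT_DEFAULT) -> HmmSpec:
    """Assemble the local-ancestry HMM for a site list and source panels.

    ``panel_freqs`` is either a :class:`FrequencyTable` (counts are
    pseudocount-smoothed) or a pair of already-smoothed probability arrays
    (p_mes, p_neo) used verbatim.  ``ne`` is recorded as the assumed effective
    population size of the admixed cohort; emissions use pseudocount
    smoothing only.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if t_generations < 1:
        raise ValueError("pulse time must be >= 1 generation")
    if mode not in ("diploid", "haploid"):
        raise ValueError("mode must be 'diploid' or 'haploid'")
    if snps is None or panel_freqs is None:
        raise ValueError("snps and panel_freqs are required")
    gpos = snps.genetic_pos
    within = np.diff(gpos)[snps.chromosome[1:] == snps.chromosome[:-1]]
    if len(within) and np.all(within == 0):
        raise ValueError("genetic map is degenerate (zero length on every "
                         "chromosome); interpolate a recombination map first")

    if isinstance(panel_freqs, FrequencyTable):
        p_mes, p_neo = smoothed_panel_frequencies(panel_freqs, pseudocount)
    else:
        p_mes = np.asarray(panel_freqs[0], dtype=np.float64)
        p_neo = np.asarray(panel_freqs[1], dtype=np.float64)
    if len(p_mes) != len(snps) or len(p_neo) != len(snps):
        raise ValueError("panel frequencies do not match SNP table")

    d = np.diff(gpos)
    # chromosome boundaries: infinite map distance -> stationary restart
    boundary = snps.chromosome[1:] != snps.chromosome[:-1]
    s = 1.0 - np.exp(-t_generations * d)
    s[boundary] = 1.0
    p_mm, p_mn, p_nm, p_nn = _haplotype_transition(s, alpha)

    if mode == "haploid":
        ploidy = 1
        prior = np.array([1.0 - alpha, alpha])
        trans = np.empty((len(s), 2, 2))
        trans[:, 0, 0] = p_nn
        trans[:, 0, 1] = p_nm
        trans[:, 1, 0] = p_mn
        trans[:, 1, 1] = p_mm
    else:
        ploidy = 2
        prior = np.array([(1 - alpha) ** 2, 2 * alpha * (1 - alpha), alpha ** 2])
        trans = np.empty((len(s), 3, 3))
        trans[:, 0, 0] = p_nn ** 2
        trans[:, 0, 1] = 2 * p_nn * p_nm
        trans[:, 0, 2] = p_nm ** 2
        trans[:, 1, 0] = p_mn * p_nn
        trans[:, 1, 1] = p_mm * p_nn + p_mn * p_nm
        trans[:, 1, 2] = p_mm * p_nm
        trans[:, 2, 0] = p_mn ** 2
        trans[:, 2, 1] = 2 * p_mm * p_mn
        trans[:, 2, 2] = p_mm ** 2

    k = np.arange(ploidy + 1, dtype=np.float64) / ploidy
    emit_alt = np.clip(k[None, :] * p_mes[:, None]
                       + (1.0 - k[None, :]) * p_neo[:, None], 0.0, 1.0)
    return HmmSpec(alpha, t_generations, ne, ploidy, snps, prior, trans,
                   emit_alt)


# ---------------------------------------------------------------------------
# Posterior decoding
# ---------------------------------------------------------------------------

@dataclass
class PosteriorTrack:
    """Posterior mean Mesolithic dosage per individual per SNP."""

    dosage: np.ndarray          # (n_sites, n_individuals), in [0, ploidy]
    loglik: np.ndarray          # (n_individuals,)
    ploidy: int
    posteriors: np.ndarray | None = None   # (n_sites, n_ind, K) if requested

    @property
    def fraction(self) -> np.ndarray:
        """Posterior Mesolithic fraction in [0, 1]."""
        return self.dosage / self.ploidy


def _site_emissions(hmm: HmmSpec, i: int, calls: np.ndarray | None,
                    ref_reads: np.ndarray | None,
                    alt_reads: np.ndarray | None) -> np.ndarray:
    """Emission likelihood matrix (n_individuals, K) at site i."""
    q = hmm.emit_alt[i]
    if calls is not None:
        row = calls[i]
        e = np.ones((len(row), len(q)))
        e[row == ALT] = q
        e[row == REF] = 1.0 - q
        return e
    a = alt_reads[i][:, None].astype(np.float64)
    r = ref_reads[i][:, None].astype(np.float64)
    # binomial kernel; the coefficient is constant across states
    return q[None, :] ** a * (1.0 - q)[None, :] ** r


def posterior_dosage(hmm: HmmSpec, calls: np.ndarray | None = None, *,
                     ref_reads: np.ndarray | None = None,
                     alt_reads: np.ndarray | None = None,
                     return_posteriors: bool = False) -> PosteriorTrack:
    """Scaled forward-backward posterior decoding, batched over individuals.

    ``calls`` is an (n_sites, n_individuals) pseudohaploid code matrix
    (0/2/9); alternatively pass ``ref_reads``/``alt_reads`` of the same shape
    for read-count emissions.  An all-missing individual decodes to the prior
    everywhere (dosage ploidy*alpha), which is the correct no-data posterior.
    """
    if calls is not None:
        calls = np.asarray(calls)
        if calls.ndim == 1:
            calls = calls[:, None]
        n_sites, n_ind = calls.shape
    else:
        if ref_reads is None or alt_reads is None:
            raise ValueError("provide calls or both read-count matrices")
        ref_reads = np.atleast_2d(np.asarray(ref_reads).T).T
        alt_reads = np.atleast_2d(np.asarray(alt_reads).T).T
        n_sites, n_ind = ref_reads.shape
    if n_sites != hmm.n_sites:
        raise ValueError(f"observations cover {n_sites} sites, "
                         f"HMM has {hmm.n_sites}")

    K = hmm.n_states
    alphas = np.empty((n_sites, n_ind, K))
    scale = np.empty((n_sites, n_ind))

    a = hmm.prior[None, :] * _site_emissions(hmm, 0, calls, ref_reads, alt_reads)
    c = a.sum(axis=1)
    if np.any(c <= 0):
        raise ValueError("zero observation likelihood at site 0")
    alphas[0] = a / c[:, None]
    scale[0] = c
    for i in range(1, n_sites):
        e = _site_emissions(hmm, i, calls, ref_reads, alt_reads)
        a = (alphas[i - 1] @ hmm.trans[i - 1]) * e
        c = a.sum(axis=1)
        if np.any(c <= 0):
            raise ValueError(f"zero observation likelihood at site {i}")
        alphas[i] = a / c[:, None]
        scale[i] = c
    loglik = np.log(scale).sum(axis=0)

    post = alphas            # reuse storage: multiply in place by betas
    beta = np.ones((n_ind, K))
    for i in range(n_sites - 2, -1, -1):
        e = _site_emissions(hmm, i + 1, calls, ref_reads, alt_reads)
        beta = ((beta * e) @ hmm.trans[i].T) / scale[i + 1][:, None]
        post[i] *= beta
    post /= post.sum(axis=2, keepdims=True)

    dosage = post @ hmm.dosage_values
    return PosteriorTrack(dosage, loglik, hmm.ploidy,
                          post if return_posteriors else None)


def _loglik_backward(hmm: HmmSpec, calls: np.ndarray) -> np.ndarray:
    """Observation log-likelihood via the backward recursion (for checks)."""
    calls = np.asarray(calls)
    if calls.ndim == 1:
        calls = calls[:, None]
    n_sites, n_ind = calls.shape
    K = hmm.n_states
    beta = np.ones((n_ind, K))
    logscale = np.zeros(n_ind)
    for i in range(n_sites - 2, -1, -1):
        e = _site_emissions(hmm, i + 1, calls, None, None)
        beta = (beta * e) @ hmm.trans[i].T
        d = beta.sum(axis=1) / K
        beta /= d[:, None]
        logscale += np.log(d)
    e0 = _site_emissions(hmm, 0, calls, None, None)
    return np.log((hmm.prior[None, :] * e0 * beta).sum(axis=1)) + logscale


def enumerate_posteriors(hmm: HmmSpec, calls: np.ndarray) -> np.ndarray:
    """Exact posteriors by exhaustive summation over all state paths.

    Brute-force oracle for small site counts (K^n paths); returns an
    (n_sites, K) posterior matrix for a single observation sequence.
    """
    calls = np.asarray(calls).reshape(-1)
    n = len(calls)
    K = hmm.n_states
    if K ** n > 2_000_000:
        raise ValueError("path enumeration is infeasible at this size")
    e = np.stack([_site_emissions(hmm, i, calls[:, None], None, None)[0]
                  for i in range(n)])
    post = np.zeros((n, K))
    total = 0.0
    for flat in range(K ** n):
        path = []
        rem = flat
        for _ in range(n):
            path.append(rem % K)
            rem //= K
        w = hmm.prior[path[0]] * e[0, path[0]]
        for i in range(1, n):
            w *= hmm.trans[i - 1][path[i - 1], path[i]] * e[i, path[i]]
        total += w
        for i, k in enumerate(path):
            post[i, k] += w
    return post / total


# ---------------------------------------------------------------------------
# Cohort LAD track
# ---------------------------------------------------------------------------

@dataclass
class LADTrack:
    """Windowed cohort-mean Mesolithic fraction with deviation and Z scores.

    ``windows`` columns: chromosome, center_bp, mean_fraction, lad, z,
    n_snps.  LAD is the deviation of the window mean fraction from the
    spaced-null mean; positive = Mesolithic excess, negative = Neolithic
    excess.
    """

    windows: pd.DataFrame
    null: NullSample
    n_individuals: int
    null_mean_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        self.null_mean_fraction = float(np.mean(self.null.values))


def cohort_lad(track: PosteriorTrack, snps: SNPTable,
               window_snps: int = WINDOW_SNPS_DEFAULT,
               min_gap_bp: int = MIN_GAP_BP_DEFAULT) -> LADTrack:
    """Cohort LAD track from per-individual posterior fractions.

    The per-SNP cohort mean Mesolithic fraction is window-averaged exactly as
    the scan statistics, a spaced null subsample supplies the genome-wide
    centering mean and the standard deviation for Z scores.
    """
    if track.dosage.shape[1] < 1:
        raise ValueError("empty cohort")
    mean_fraction = track.fraction.mean(axis=1)
    win = sliding_windows(mean_fraction, snps, window_snps=window_snps)
    if len(win) == 0:
        raise ValueError("no windows; fewer SNPs than the window size")
    null = spaced_subsample(win, min_gap_bp=min_gap_bp)
    out = win[["chromosome", "center_bp", "n_snps"]].copy()
    out.insert(2, "mean_fraction", win["value"].to_numpy())
    out.insert(3, "lad", out["mean_fraction"] - float(np.mean(null.values)))
    null_sd = np.std(null.values, ddof=1) if len(null) >= 2 else 0.0
    if null_sd > 1e-12 * max(1.0, float(np.abs(null.values).max())):
        z = z_scores(null, win["value"].to_numpy())
    elif np.allclose(out["lad"].to_numpy(), 0.0, atol=1e-9):
        z = np.zeros(len(out))    # flat track: no deviation, no variance
    else:
        raise ValueError("degenerate LAD null sample")
    out.insert(4, "z", z)
    return LADTrack(out, null, track.dosage.shape[1])


def region_average(lad: LADTrack, chromosome: str, start_bp: int,
                   end_bp: int) -> tuple[float, float]:
    """Mean LAD over a region and a Z score for that regional mean.

    The region mean is the unweighted mean of LAD over windows whose centers
    fall in [start_bp, end_bp].  Its null distribution is built by centering
    a same-width pseudo-region on every spaced null position and averaging
    the LAD windows inside it; the Z score standardizes the observed region
    mean against those pseudo-region means.
    """
    win = lad.windows
    centers = win["center_bp"].to_numpy()
    chroms = win["chromosome"].to_numpy()
    in_region = (chroms == chromosome) & (centers >= start_bp) & (centers <= end_bp)
    if not in_region.any():
        raise ValueError("region overlaps no window centers")
    obs = float(win.loc[in_region, "lad"].mean())

    half_width = (end_bp - start_bp) / 2.0
    null_means = []
    for _, row in lad.null.windows.iterrows():
        sel = ((chroms == row["chromosome"])
               & (centers >= row["center_bp"] - half_width)
               & (centers <= row["center_bp"] + half_width))
        if sel.any():
            null_means.append(float(win.loc[sel, "lad"].mean()))
    null_means = np.asarray(null_means)
    if len(null_means) < 2 or np.std(null_means, ddof=1) == 0:
        raise ValueError("degenerate null for region averaging")
    z = (obs - null_means.mean()) / np.std(null_means, ddof=1)
    return obs, float(z)


# ---------------------------------------------------------------------------
# Reference-genome bias probe
# ---------------------------------------------------------------------------

@dataclass
class ReferenceProbe:
    track: PosteriorTrack
    fraction_mesolithic_confident: float
    fraction_neolithic_confident: float
    posterior_threshold: float


def reference_bias_probe(hmm: HmmSpec, reference_alleles: np.ndarray,
                         posterior_threshold: float = 0.9) -> ReferenceProbe:
    """Decode a haploid reference-allele sequence against the source panels.

    Probes whether signals could stem from reference-genome mapping bias: if
    the reference itself were uniformly closer to one source, its decoded
    ancestry would be one-sided.  ``reference_alleles`` is a per-site code
    sequence (0 = site carries the ref/panel reference allele, 2 = alt, 9 =
    unknown).  Returns the haploid posterior track and the fraction of sites
    confidently (> threshold) assigned to each ancestry.
    """
    if hmm.ploidy != 1:
        raise ValueError("reference probe requires a haploid-mode HMM")
    track = posterior_dosage(hmm, np.asarray(reference_alleles).reshape(-1, 1),
                             return_posteriors=True)
    p_mes = track.posteriors[:, 0, 1]
    return ReferenceProbe(
        track,
        float(np.mean(p_mes > posterior_threshold)),
        float(np.mean(1.0 - p_mes > posterior_threshold)),
        posterior_threshold,
    )


def write_lad(lad: LADTrack, path) -> None:
    lad.windows.to_csv(path, sep="\t", index=False, float_format="%.10g")
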