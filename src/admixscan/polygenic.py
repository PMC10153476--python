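"""Polygenic adaptive-admixture test.

For a trait with genome-wide significant GWAS associations, the hits are
thinned to approximate independence (keep the smallest p value, drop all
others within 250 kb, repeat), each retained effect size is weighted by the
signed source allele-frequency difference, w = beta * (p_neo - p_mes), and w
is tested for Pearson correlation against the local-ancestry-deviation (LAD)
Z score at the nearest scan window.  Directional inheritance of trait-raising
alleles from one source shows up as a nonzero correlation; the per-trait
genome-wide sum of w is reported as an auxiliary summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ancestry import LADTrack
from .io import MESOLITHIC, NEOLITHIC, FrequencyTable, GenotypeMatrix

logger = logging.getLogger("admixscan")

P_THRESHOLD_DEFAULT = 1e-8
PRUNE_WINDOW_BP_DEFAULT = 250_000
LAD_MATCH_CAP_BP_DEFAULT = 100_000

ASSOC_COLUMNS = ["snp", "chromosome", "position_bp", "effect_allele",
                 "other_allele", "beta", "p"]


@dataclass
class CorrelationResult:
    """Per-trait polygenic test result."""

    trait: str
    r: float
    p: float
    n_snps: int
    weighted_sum: float
    excluded: tuple[str, ...] = ()


def read_associations(path) -> pd.DataFrame:
    """Tab-separated association table (snp, chrom, pos, alleles, beta, p)."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = set(ASSOC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"association table lacks columns {sorted(missing)}")
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        raise ValueError("GWAS p values must lie in (0, 1]")
    return df


def prune_associations(table: pd.DataFrame,
                       p_threshold: float = P_THRESHOLD_DEFAULT,
                       window_bp: int = PRUNE_WINDOW_BP_DEFAULT
                       ) -> pd.DataFrame:
    """Significance-threshold and distance-prune an association table.

    Keeps records with p < ``p_threshold``, then iteratively selects the
    record with the smallest p genome-wide and removes all others within
    ``window_bp`` on the same chromosome.  Ties on p are broken by position,
    then by SNP id (deterministic).  Output records are pairwise >=
    ``window_bp`` apart within each chromosome, sorted by position; pruning
    its own output is a no-op.
    """
    df = table[table["p"] < p_threshold].copy()
    if df.empty:
        return df.reset_index(drop=True)
    df = df.sort_values(["p", "position_bp", "snp"],
                        kind="mergesort").reset_index(drop=True)
    alive = np.ones(len(df), dtype=bool)
    kept: list[int] = []
    chrom = df["chromosome"].to_numpy(dtype=object)
    pos = df["position_bp"].to_numpy(dtype=np.int64)
    for i in range(len(df)):
        if not alive[i]:
            continue
        kept.append(i)
        clash = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) < window_bp)
        alive[clash] = False
    out = df.iloc[sorted(kept)].sort_values(["chromosome", "position_bp"],
                                            kind="mergesort")
    return out.reset_index(drop=True)


def ancestry_weight(pruned: pd.DataFrame, freqs: FrequencyTable,
                    gm_or_snps) -> pd.DataFrame:
    """Weight pruned effect sizes by the signed source frequency difference.

    Each association is matched to a panel SNP by chromosome and position;
    the effect allele is aligned to the panel's alternate allele (flipping
    beta when the effect allele is the reference allele — the weight
    w = beta * (p_neo - p_mes) is invariant under a consistent flip).
    Associations whose SNP is absent or lacks either source frequency are
    dropped with a logged count; an allele pair matching neither orientation
    raises.
    """
    snps = gm_or_snps.snps if isinstance(gm_or_snps, GenotypeMatrix) else gm_or_snps
    key = {(c, int(p)): i for i, (c, p) in
           enumerate(zip(snps.chromosome, snps.position_bp))}
    p_mes = freqs.freq(MESOLITHIC)
    p_neo = freqs.freq(NEOLITHIC)

    rows, n_unmatched, n_nofreq = [], 0, 0
    for _, rec in pruned.iterrows():
        i = key.get((rec["chromosome"], int(rec["position_bp"])))
        if i is None:
            n_unmatched += 1
            continue
        if np.isnan(p_mes[i]) or np.isnan(p_neo[i]):
            n_nofreq += 1
            continue
        ref, alt = snps.ref_allele[i], snps.alt_allele[i]
        if rec["effect_allele"] == alt and rec["other_allele"] == ref:
            beta = float(rec["beta"])
        elif rec["effect_allele"] == ref and rec["other_allele"] == alt:
            beta = -float(rec["beta"])
        else:
            raise ValueError(
                f"alleles {rec['effect_allele']}/{rec['other_allele']} at "
                f"{rec['chromosome']}:{rec['position_bp']} match neither "
                f"orientation of panel {ref}/{alt}")
        rows.append((rec["snp"], rec["chromosome"], int(rec["position_bp"]),
                     beta * (p_neo[i] - p_mes[i])))
    if n_unmatched or n_nofreq:
        logger.info("ancestry_weight: dropped %d unmatched and %d "
                    "frequency-missing associations", n_unmatched, n_nofreq)
    return pd.DataFrame(rows, columns=["snp", "chromosome", "position_bp",
                                       "weight"])


def lad_correlation(weighted: pd.DataFrame, lad: LADTrack,
                    exclude: tuple[str, ...] = (),
                    max_match_bp: int = LAD_MATCH_CAP_BP_DEFAULT,
                    trait: str = "trait") -> CorrelationResult:
    """Pearson correlation of ancestry-weighted effects with LAD Z scores.

    Each weighted SNP is matched to the LAD window whose center is nearest on
    the same chromosome, within ``max_match_bp`` (unmatched SNPs dropped and
    logged).  Excluded SNP ids (leave-out runs) are removed before the
    correlation.  Requires >= 3 matched SNPs.
    """
    df = weighted[~weighted["snp"].isin(exclude)]
    win = lad.windows
    pairs = []
    n_unmatched = 0
    for _, rec in df.iterrows():
        sub = win[win["chromosome"] == rec["chromosome"]]
        if sub.empty:
            n_unmatched += 1
            continue
        dist = np.abs(sub["center_bp"].to_numpy() - rec["position_bp"])
        j = int(np.argmin(dist))
        if dist[j] > max_match_bp:
            n_unmatched += 1
            continue
        pairs.append((float(rec["weight"]), float(sub["z"].iloc[j])))
    if n_unmatched:
        logger.info("lad_correlation: %d SNPs without a window within %d bp",
                    n_unmatched, max_match_bp)
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} matched SNPs; need >= 3")
    w = np.array([p[0] for p in pairs])
    z = np.array([p[1] for p in pairs])
    res = stats.pearsonr(w, z)
    return CorrelationResult(trait, float(res.statistic), float(res.pvalue),
                             len(pairs), float(w.sum()), tuple(exclude))
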