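"""Per-SNP differentiation statistics and their sliding-window summaries.

Two per-SNP statistics are provided:

* ``f2`` — the squared allele-frequency difference between two populations,
  an admixture-unaware measure of differentiation driven by drift or
  selection.
* ``F_adm`` — for an admixed population with genome-wide mixture proportion
  alpha from the first source, the squared deviation of the admixed allele
  frequency from its admixture expectation y = alpha*p1 + (1-alpha)*p2,
  normalized by y(1-y) so the statistic is scale-free across frequencies.

Each statistic is computed per SNP and then averaged in sliding windows of an
odd number of SNPs (51 by default, step 1), reported at the position of the
window's median SNP. Windows never span chromosome boundaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import SNPTable

WINDOW_SNPS_DEFAULT = 51


def f2_statistic(p1, p2) -> np.ndarray:
    """Squared allele-frequency difference (p1 - p2)^2, NaN-propagating."""
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    _check_unit_interval(p1, "p1")
    _check_unit_interval(p2, "p2")
    return (p1 - p2) ** 2


def admixture_expectation(p_mes, p_neo, alpha: float) -> np.ndarray:
    """Expected admixed frequency y = alpha*p_mes + (1-alpha)*p_neo."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha * np.asarray(p_mes, float) + (1.0 - alpha) * np.asarray(p_neo, float)


def _fadm_denominator(y: np.ndarray) -> np.ndarray:
    """Variance normalization y(1-y); isolated so alternatives can be swapped."""
    return y * (1.0 - y)


def fadm_statistic(p_adm, p_mes, p_neo, alpha: float) -> np.ndarray:
    """Adaptive-admixture statistic (p_adm - y)^2 / (y(1-y)).

    Where the expectation y is degenerate (0 or 1) the statistic is 0 if the
    admixed frequency meets it exactly and NaN (flagged missing) otherwise.
    """
    p_adm = np.asarray(p_adm, dtype=np.float64)
    _check_unit_interval(p_adm, "p_adm")
    y = admixture_expectation(p_mes, p_neo, alpha)
    dev2 = (p_adm - y) ** 2
    denom = _fadm_denominator(y)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = dev2 / denom
    degenerate = denom == 0
    if np.ndim(stat) == 0:
        if degenerate:
            return np.float64(0.0) if dev2 == 0 else np.float64(np.nan)
        return np.float64(stat)
    stat = np.where(degenerate, np.where(dev2 == 0, 0.0, np.nan), stat)
    return stat


def _check_unit_interval(p: np.ndarray, name: str) -> None:
    p = np.atleast_1d(p)
    finite = p[np.isfinite(p)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError(f"{name} must lie in [0, 1]")


def sliding_windows(values, snps: SNPTable,
                    window_snps: int = WINDOW_SNPS_DEFAULT,
                    step: int = 1) -> pd.DataFrame:
    """Sliding-window means of a per-SNP statistic.

    Per chromosome with m SNPs, emits ``(m - window_snps) // step + 1``
    windows (none if m < window_snps). The window value is the mean of the
    non-missing per-SNP values; the window is reported at the position of its
    median (center) SNP. Windows with fewer than half their SNPs non-missing
    are flagged.

    Returns a DataFrame with columns chromosome, center_bp, center_index
    (index into ``snps``), value, n_snps, flagged.
    """
    if window_snps % 2 == 0 or window_snps < 1:
        raise ValueError("window_snps must be odd and positive")
    if step < 1:
        raise ValueError("step must be >= 1")
    values = np.asarray(values, dtype=np.float64)
    if len(values) != len(snps):
        raise ValueError("statistic length does not match SNP table")

    half = window_snps // 2
    frames = []
    for chrom in snps.chromosomes:
        idx = snps.chrom_slice(chrom)
        m = len(idx)
        if m < window_snps:
            continue
        v = values[idx]
        ok = np.isfinite(v)
        vsum = np.concatenate(([0.0], np.cumsum(np.where(ok, v, 0.0))))
        vcnt = np.concatenate(([0], np.cumsum(ok.astype(np.int64))))
        starts = np.arange(0, m - window_snps + 1, step)
        counts = vcnt[starts + window_snps] - vcnt[starts]
        sums = vsum[starts + window_snps] - vsum[starts]
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        centers = starts + half
        frames.append(pd.DataFrame({
            "chromosome": chrom,
            "center_bp": snps.position_bp[idx[centers]],
            "center_index": idx[centers],
            "value": means,
            "n_snps": counts,
            "flagged": counts < (window_snps + 1) // 2,
        }))
    if not frames:
        return pd.DataFrame(columns=["chromosome", "center_bp", "center_index",
                                     "value", "n_snps", "flagged"])
    return pd.concat(frames, ignore_index=True)


def annotate_windows(scan: pd.DataFrame, annotations) -> pd.DataFrame:
    """Label windows whose centers fall inside annotation intervals."""
    scan = scan.copy()
    inside = annotations.contains_positions(
        scan["chromosome"].to_numpy(dtype=object),
        scan["center_bp"].to_numpy())
    scan["annotated"] = inside
    return scan


def write_scan(scan: pd.DataFrame, path) -> None:
    scan.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_scan(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chromosome": str})
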