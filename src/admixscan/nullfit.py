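"""Genome-wide null calibration for window scan statistics.

Sliding windows overlap heavily, so the genome-wide distribution of window
values is far from independent. A null sample is built by greedily thinning
the scan to windows separated by at least a minimum gap (5 Mb by default),
treated as approximately independent draws. A gamma distribution is fitted to
this null sample by maximum likelihood and upper-tail probabilities of the
fit convert every window value to a p-value; for signed tracks (local
ancestry deviation) the same null sample supplies the mean and standard
deviation for Z scores.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("admixscan")

MIN_GAP_BP_DEFAULT = 5_000_000
MIN_NULL_SIZE = 30


@dataclass
class NullSample:
    """Spaced, approximately independent window subsample."""

    windows: pd.DataFrame      # chromosome, center_bp, value
    min_gap_bp: int

    @property
    def values(self) -> np.ndarray:
        return self.windows["value"].to_numpy(dtype=np.float64)

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class GammaNull:
    """Maximum-likelihood gamma fit to a null sample (location fixed at 0)."""

    shape: float
    scale: float
    loglik: float
    n_samples: int
    n_zeros_excluded: int = 0

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError("gamma shape and scale must be positive")

    def sf(self, x) -> np.ndarray:
        return stats.gamma.sf(x, a=self.shape, scale=self.scale)

    def to_dict(self) -> dict:
        return {"shape": self.shape, "scale": self.scale,
                "loglik": self.loglik, "n_samples": self.n_samples,
                "n_zeros_excluded": self.n_zeros_excluded}


def spaced_subsample(scan: pd.DataFrame,
                     min_gap_bp: int = MIN_GAP_BP_DEFAULT,
                     rng: np.random.Generator | None = None) -> NullSample:
    """Greedy left-to-right thinning to windows >= min_gap_bp apart.

    Per chromosome: take the first window, then repeatedly the next window at
    least ``min_gap_bp`` beyond the last selected. Chromosomes are
    independent; the selection is deterministic and idempotent on its own
    output. Passing ``rng`` starts each chromosome from a random window within
    the first gap instead of the leftmost one (sensitivity-check mode).
    """
    if len(scan) == 0:
        raise ValueError("empty scan")
    usable = scan[np.isfinite(scan["value"].to_numpy(float))]
    picks = []
    for chrom, grp in usable.groupby("chromosome", sort=False):
        grp = grp.sort_values("center_bp")
        pos = grp["center_bp"].to_numpy()
        if len(pos) == 0:
            continue
        if rng is not None:
            first = int(rng.integers(np.searchsorted(
                pos, pos[0] + min_gap_bp, side="left") or 1))
        else:
            first = 0
        i = first
        while i < len(pos):
            picks.append(grp.index[i])
            i = int(np.searchsorted(pos, pos[i] + min_gap_bp, side="left"))
    sample = usable.loc[picks, ["chromosome", "center_bp", "value"]]
    sample = sample.reset_index(drop=True)
    logger.info("spaced_subsample: %d of %d windows at >= %d bp spacing",
                len(sample), len(scan), min_gap_bp)
    return NullSample(sample, int(min_gap_bp))


def fit_gamma(null: NullSample | np.ndarray) -> GammaNull:
    """Gamma MLE (shape, scale; location 0) on the positive null values.

    Exact zeros are excluded from the fit (gamma support is the positive
    reals) and their count recorded; downstream, zero-valued windows get
    p = 1. Raises on degenerate (constant) samples or fewer than
    ``MIN_NULL_SIZE`` positive values.
    """
    values = null.values if isinstance(null, NullSample) else np.asarray(null, float)
    values = values[np.isfinite(values)]
    if np.any(values < 0):
        raise ValueError("negative values cannot be gamma-distributed")
    n_zero = int((values == 0).sum())
    pos = values[values > 0]
    if len(pos) < MIN_NULL_SIZE:
        raise ValueError(f"need >= {MIN_NULL_SIZE} positive null values, "
                         f"got {len(pos)}")
    if np.ptp(pos) == 0:
        raise ValueError("degenerate null sample (constant values)")
    shape, loc, scale = stats.gamma.fit(pos, floc=0)
    loglik = float(stats.gamma.logpdf(pos, a=shape, scale=scale).sum())
    if not np.isfinite(loglik):
        raise RuntimeError("gamma fit did not converge")
    return GammaNull(float(shape), float(scale), loglik, len(pos), n_zero)


def tail_pvalues(fit: GammaNull, values) -> np.ndarray:
    """Upper-tail gamma probabilities; p in (0, 1], NaN for missing values."""
    values = np.asarray(values, dtype=np.float64)
    p = fit.sf(np.where(np.isfinite(values), values, 0.0))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return np.where(np.isfinite(values), p, np.nan)


def z_scores(null: NullSample | np.ndarray, values) -> np.ndarray:
    """Standardize values against the null sample: (v - mean) / sd, ddof=1."""
    nv = null.values if isinstance(null, NullSample) else np.asarray(null, float)
    nv = nv[np.isfinite(nv)]
    if len(nv) < 2:
        raise ValueError("need >= 2 null values for a Z score")
    sd = float(np.std(nv, ddof=1))
    if sd == 0:
        raise ValueError("zero null variance")
    return (np.asarray(values, dtype=np.float64) - float(np.mean(nv))) / sd


def qq_data(pvalues: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10 p for a quantile-quantile plot."""
    p = np.sort(pvalues[np.isfinite(pvalues)])
    n = len(p)
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    return pd.DataFrame({"expected_neglog10p": expected,
                         "observed_neglog10p": -np.log10(p)})


def save_null(null: NullSample, fit: GammaNull, prefix: str | Path) -> None:
    """Serialize the null sample (TSV) and fit parameters (JSON)."""
    prefix = Path(prefix)
    null.windows.to_csv(prefix.with_suffix(".null.tsv"), sep="\t",
                        index=False, float_format="%.10g")
    payload = fit.to_dict() | {"min_gap_bp": null.min_gap_bp}
    prefix.with_suffix(".fit.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n")
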