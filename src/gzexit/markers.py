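"""Marker labeling indices (Ki67 / p27 / EdU) and proportion comparisons.

A cell is scored positive when its normalized staining intensity lies
strictly above a threshold fraction of maximal intensity (default 0.225,
the midpoint of the published 20-25% cutoff range).  The labeling index is
the percent positive with a Wilson 95% confidence interval.  Conditions
are compared with a pooled two-proportion z-test, or at replicate level by
delegating to Welch's t on per-replicate percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from gzexit.migration import welch_t

DEFAULT_THRESHOLD = 0.225


@dataclass
class LabelingCounts:
    """Positive/total counts with percent and Wilson 95% CI."""

    positive: int
    total: int
    threshold_frac: float
    percent: float
    ci_lo_percent: float
    ci_hi_percent: float


def _wilson_ci(x: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    phat = x / n
    denom = 1 + z**2 / n
    center = (phat + z**2 / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return max(center - half, 0.0), min(center + half, 1.0)


def labeling_index(
    intensities, threshold_frac: float = DEFAULT_THRESHOLD
) -> LabelingCounts:
    """Percent of cells strictly above the intensity threshold.

    Intensities are fractions of maximal staining in [0, 1]; cells exactly
    at the threshold count as negative (ties excluded).
    """
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValueError("at least one intensity required")
    if ((x < 0) | (x > 1)).any():
        raise ValueError("intensities must lie in [0, 1]")
    positive = int((x > threshold_frac).sum())
    lo, hi = _wilson_ci(positive, x.size)
    return LabelingCounts(
        positive=positive,
        total=int(x.size),
        threshold_frac=threshold_frac,
        percent=100.0 * positive / x.size,
        ci_lo_percent=100.0 * lo,
        ci_hi_percent=100.0 * hi,
    )


def compare_proportions(a: LabelingCounts, b: LabelingCounts) -> tuple[float, float]:
    """Pooled two-proportion z-test (two-sided), symmetric in its arguments.

    Returns (z, p).  Degenerate pooled proportions (all positive or all
    negative in both groups combined) give z = 0, p = 1.
    """
    if a.total < 1 or b.total < 1:
        raise ValueError("totals must be >= 1")
    p1, p2 = a.positive / a.total, b.positive / b.total
    pool = (a.positive + b.positive) / (a.total + b.total)
    se = math.sqrt(pool * (1 - pool) * (1 / a.total + 1 / b.total))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return z, float(2 * stats.norm.sf(abs(z)))


def compare_replicate_percentages(percents_a, percents_b) -> tuple[float, float]:
    """Welch's t on per-replicate labeling percentages (replicate mode)."""
    return welch_t(np.asarray(percents_a, float), np.asarray(percents_b, float))
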