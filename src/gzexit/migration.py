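"""Germinal-zone-exit quantification.

Given per-cell planar coordinates (µm) and a polyline tracing the pial
surface of a cerebellar slice, this module measures each cell's distance
to the nearest point of the surface, bins the distances into a fixed
histogram over the 0–450 µm scoring domain, summarises them (mean, sample
SD, n, 99th percentile "migration front"), compares conditions with a
binned two-sample chi-square test and Welch's t, and applies the rescue
decision rule: a perturbation *rescues* germinal-zone exit when its
distance distribution is indistinguishable from control (chi-square
p > 0.8) while its mean distance differs from the phenotype condition
(Welch t, p < 0.01).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

#: Default rescue-rule thresholds: chi-square p vs control must exceed the
#: first, Welch-t p vs phenotype must fall below the second.
RESCUE_CHI2_P = 0.8
RESCUE_T_P = 0.01


class DegenerateSurfaceError(ValueError):
    """All surface segments have zero length."""


@dataclass
class CellCohort:
    """Cells of one condition plus the slice's surface polyline.

    ``cells`` is an (n, 2) array of (x, y) µm coordinates; ``surface`` an
    ordered (m, 2) polyline with m >= 2 vertices.
    """

    cells: np.ndarray
    condition: str
    surface: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        self.surface = np.asarray(self.surface, dtype=float)
        if self.cells.ndim != 2 or self.cells.shape[1] != 2 or len(self.cells) < 1:
            raise ValueError("cells must be a non-empty (n, 2) array")
        if self.surface.ndim != 2 or self.surface.shape[1] != 2 or len(self.surface) < 2:
            raise ValueError("surface must be an (m>=2, 2) polyline")
        if not (np.isfinite(self.cells).all() and np.isfinite(self.surface).all()):
            raise ValueError("coordinates must be finite")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class MigrationProfile:
    """Distance distribution and summary statistics for one condition."""

    distances: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    mean_um: float
    sd_um: float
    n: int
    p99_um: float
    condition: str = ""

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "mean_um": self.mean_um,
            "sd_um": self.sd_um,
            "n": self.n,
            "p99_um": self.p99_um,
            "bin_edges": self.bin_edges.tolist(),
            "counts": self.counts.tolist(),
        }


@dataclass
class RescueVerdict:
    """Outcome of the two-arm rescue rule with the thresholds applied."""

    chi2_p_vs_control: float
    t_p_vs_phenotype: float
    rescued: bool
    chi2_stat: float
    t_stat: float
    thresholds: dict = field(
        default_factory=lambda: {"chi2_p": RESCUE_CHI2_P, "t_p": RESCUE_T_P}
    )


def distance_to_surface(cohort: CellCohort) -> np.ndarray:
    """Euclidean distance from each cell to the nearest point of the surface.

    The minimum is taken over every *segment* of the polyline (closest
    point on the segment, not nearest vertex).  Distances are unsigned:
    cells on either side of the surface get positive values.
    """
    pts = cohort.cells
    verts = cohort.surface
    a = verts[:-1]
    b = verts[1:]
    ab = b - a
    seg_len2 = (ab**2).sum(axis=1)
    usable = seg_len2 > 0
    if not usable.any():
        raise DegenerateSurfaceError("surface polyline has zero total length")

    best = np.full(len(pts), np.inf)
    for ai, abi, l2, ok in zip(a, ab, seg_len2, usable):
        if not ok:
            continue
        t = np.clip(((pts - ai) @ abi) / l2, 0.0, 1.0)
        closest = ai + t[:, None] * abi
        d = np.hypot(*(pts - closest).T)
        np.minimum(best, d, out=best)
    return best


def summarize_cohort(
    distances: np.ndarray,
    bin_width_um: float = 10.0,
    domain_max_um: float = 450.0,
    condition: str = "",
) -> MigrationProfile:
    """Bin distances over [0, domain_max] and compute summary statistics.

    Bins are fixed-width so that profiles from different conditions share
    edges and are directly comparable.  SD is the sample SD (n-1); the
    99th percentile uses linear interpolation (type-7 quantile).
    Distances beyond the domain are clipped into the last bin (logged).
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("at least one distance required")
    n_bins = math.ceil(domain_max_um / bin_width_um)
    edges = np.arange(n_bins + 1) * bin_width_um
    over = d > edges[-1]
    if over.any():
        log.warning("%d distances exceed %.0f µm; clipped into last bin",
                    over.sum(), edges[-1])
        d = np.minimum(d, edges[-1])
    counts, _ = np.histogram(d, bins=edges)
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return MigrationProfile(
        distances=d,
        bin_edges=edges,
        counts=counts,
        mean_um=float(np.mean(d)),
        sd_um=sd,
        n=int(d.size),
        p99_um=float(np.percentile(d, 99)),
        condition=condition,
    )


def _merge_low_expected(ca: np.ndarray, cb: np.ndarray, min_expected: float = 5.0):
    """Merge adjacent histogram bins rightward until every expected count >= 5.

    For a 2 x B contingency table the expected count in (group i, bin j) is
    n_i * c_j / N with c_j the combined bin count, so the binding constraint
    is on the smaller group: a merged bin is closed once its combined count
    reaches ``min_expected * N / min(n_a, n_b)``.  A deficient tail is
    folded into the last closed bin.
    """
    na, nb = ca.sum(), cb.sum()
    if na == 0 or nb == 0:
        raise ValueError("both profiles must contain cells")
    need = min_expected * (na + nb) / min(na, nb)
    ma, mb = [], []
    acc_a = acc_b = 0
    for x, y in zip(ca, cb):
        acc_a += int(x)
        acc_b += int(y)
        if acc_a + acc_b >= need:
            ma.append(acc_a)
            mb.append(acc_b)
            acc_a = acc_b = 0
    if acc_a or acc_b:
        if ma:
            ma[-1] += acc_a
            mb[-1] += acc_b
        else:
            ma, mb = [acc_a], [acc_b]
    return np.array(ma), np.array(mb)


def compare_distributions(
    profile_a: MigrationProfile,
    profile_b: MigrationProfile,
    min_expected: float = 5.0,
) -> tuple[float, float]:
    """Two-sample chi-square test on the binned distance distributions.

    The 2 x B contingency table (bins x conditions) is reduced by merging
    adjacent low-expected bins rightward before testing; p comes from the
    chi-square distribution with (merged bins - 1) degrees of freedom.
    Symmetric in its arguments.
    """
    if not np.array_equal(profile_a.bin_edges, profile_b.bin_edges):
        raise ValueError("profiles must share bin edges")
    ma, mb = _merge_low_expected(profile_a.counts, profile_b.counts, min_expected)
    if len(ma) < 2:
        raise ValueError("fewer than 2 usable bins after merging")
    chi2, p, _, _ = stats.chi2_contingency(np.vstack([ma, mb]), correction=False)
    return float(chi2), float(p)


def _as_summary(x) -> tuple[float, float, int]:
    """Coerce samples, a (mean, sd, n) triple, or a profile to a summary."""
    if isinstance(x, MigrationProfile):
        return x.mean_um, x.sd_um, x.n
    if isinstance(x, (tuple, list)) and len(x) == 3:
        m, s, n = x
        return float(m), float(s), int(n)
    arr = np.asarray(x, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)


def welch_t(a, b) -> tuple[float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Accepts raw samples, ``(mean, sd, n)`` summary triples, or
    :class:`MigrationProfile` objects, so published summary statistics can
    be tested directly.  The Welch-Satterthwaite approximation supplies the
    degrees of freedom.  If both SDs are zero: p = 1 when the means are
    equal (logged convention), otherwise p = 0.
    """
    ma, sa, na = _as_summary(a)
    mb, sb, nb = _as_summary(b)
    if na < 2 or nb < 2:
        raise ValueError("welch_t requires n >= 2 in both groups")
    if sa == 0 and sb == 0:
        if ma == mb:
            log.info("welch_t: both SDs zero and means equal; p=1 by convention")
            return 0.0, 1.0
        return math.copysign(math.inf, ma - mb), 0.0
    t, p = stats.ttest_ind_from_stats(ma, sa, na, mb, sb, nb, equal_var=False)
    return float(t), float(p)


def classify_rescue(
    control: MigrationProfile,
    phenotype: MigrationProfile,
    test: MigrationProfile,
    chi2_p_threshold: float = RESCUE_CHI2_P,
    t_p_threshold: float = RESCUE_T_P,
) -> RescueVerdict:
    """Apply the two-arm rescue rule to a test condition.

    ``rescued`` is True iff the test distribution is chi-square-similar to
    the control (p > 0.8 by default) *and* the test mean differs from the
    phenotype condition by Welch's t (p < 0.01 by default).  Both
    sub-results are reported regardless of the verdict.
    """
    chi2_stat, chi2_p = compare_distributions(test, control)
    t_stat, t_p = welch_t(test, phenotype)
    return RescueVerdict(
        chi2_p_vs_control=chi2_p,
        t_p_vs_phenotype=t_p,
        rescued=bool(chi2_p > chi2_p_threshold and t_p < t_p_threshold),
        chi2_stat=chi2_stat,
        t_stat=t_stat,
        thresholds={"chi2_p": chi2_p_threshold, "t_p": t_p_threshold},
    )


def plot_profile(profile: MigrationProfile, ax=None, cumulative: bool = False):
    """Histogram (or cumulative-fraction curve) of a migration profile."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    centers = 0.5 * (profile.bin_edges[:-1] + profile.bin_edges[1:])
    if cumulative:
        frac = np.cumsum(profile.counts) / profile.n
        ax.step(profile.bin_edges[1:], frac, where="post", label=profile.condition)
        ax.set_ylabel("cumulative fraction of cells")
        ax.axvline(profile.p99_um, ls="--", lw=0.8, color="grey")
    else:
        ax.bar(centers, profile.counts, width=np.diff(profile.bin_edges),
               align="center", alpha=0.6, label=profile.condition)
        ax.set_ylabel("cells per bin")
    ax.set_xlabel("distance from surface (µm)")
    if profile.condition:
        ax.legend()
    return ax
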