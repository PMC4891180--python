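"""Named presets encoding published per-condition summary statistics.

Each slice-migration or neurite-length condition of the source study was
published as a mean ± SD over n cells.  Those printed triples are the
*parameters* of the synthetic cohort generator:
a preset is the study condition, not a tuning knob.  Registry keys follow
a ``figure:condition`` scheme so tests and the CLI can reference conditions
by name.

Labeling presets hold the published marker-positive fractions (EdU
incorporation rates) as binomial probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CohortPreset:
    """Summary-statistic parameters for one measured cell cohort.

    Parameters
    ----------
    name : str
        Registry key, ``figure:condition``.
    mean_um, sd_um : float
        Published mean and sample SD of the per-cell distance (µm).
    n_cells : int
        Published number of cells scored.
    domain_max_um : float
        Upper bound of the measurement domain (the slice assays score
        cells on a 450 µm scale).
    """

    name: str
    mean_um: float
    sd_um: float
    n_cells: int
    domain_max_um: float = 450.0

    def __post_init__(self) -> None:
        if self.sd_um < 0:
            raise ValueError(f"{self.name}: sd_um must be >= 0")
        if self.n_cells < 1:
            raise ValueError(f"{self.name}: n_cells must be >= 1")
        if not 0 < self.mean_um < self.domain_max_um:
            raise ValueError(
                f"{self.name}: mean_um must lie in (0, {self.domain_max_um})"
            )


@dataclass(frozen=True)
class LabelingPreset:
    """Binomial marker-labeling parameters (fraction of positive cells)."""

    name: str
    p_positive: float
    threshold_frac: float = 0.225

    def __post_init__(self) -> None:
        if not 0 <= self.p_positive <= 1:
            raise ValueError(f"{self.name}: p_positive must be in [0, 1]")
        if not 0 < self.threshold_frac < 1:
            raise ValueError(f"{self.name}: threshold_frac must be in (0, 1)")


def _registry(presets):
    return {p.name: p for p in presets}


#: Slice-migration cohorts (distance from the pial surface, µm) and
#: dissociated-culture neurite-length cohorts, keyed "figure:condition".
COHORT_PRESETS: dict[str, CohortPreset] = _registry(
    [
        # 24 h / 48 h slice-migration assays, Zeb1 loss/gain of function.
        CohortPreset("fig2s1:control-24h", 34.2, 10.1, 7358),
        CohortPreset("fig2s1:shZeb1-24h", 67.5, 18.1, 4693),
        CohortPreset("fig2s1:control-48h", 75.2, 3.5, 9744),
        CohortPreset("fig2s1:Zeb1-OE-48h", 40.2, 6.0, 5359),
        # 48 h rescue screen: Zeb1 gain of function plus candidate targets.
        CohortPreset("fig6s1:control-48h", 74.0, 8.3, 13064),
        CohortPreset("fig6s1:Zeb1", 42.4, 7.6, 13424),
        CohortPreset("fig6s1:Pard6a", 79.8, 5.2, 3886),
        CohortPreset("fig6s1:Pard3a", 73.9, 4.5, 8622),
        CohortPreset("fig6s1:JamNec", 71.7, 5.5, 11333),
        CohortPreset("fig6s1:Chl1", 79.4, 6.9, 3006),
        # Ptch1 conditional-deletion assay (constitutive SHH activation).
        CohortPreset("fig8:CreMut", 71.2, 7.8, 9471),
        CohortPreset("fig8:CreWT", 41.4, 5.8, 9872),
        # Neurite lengths in dissociated culture.
        CohortPreset("fig2a:control", 139.8, 13.3, 1045),
        CohortPreset("fig2a:Zeb1", 59.6, 3.0, 1164),
        # Rescue-screen neurite lengths; cell counts were not published,
        # n=1000 is a stand-in of the same order as the other assays.
        CohortPreset("fig5:control", 115.4, 17.7, 1000),
        CohortPreset("fig5:Zeb1", 55.2, 2.6, 1000),
    ]
)

#: Published EdU labeling indices as binomial probabilities.
LABELING_PRESETS: dict[str, LabelingPreset] = _registry(
    [
        LabelingPreset("edu:control-24h", 0.226),
        LabelingPreset("edu:shZeb1-24h", 0.076),
        LabelingPreset("edu:control-48h", 0.033),
        LabelingPreset("edu:Zeb1-48h", 0.109),
    ]
)
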