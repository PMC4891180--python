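"""Synthetic data generators emulating the study's measured distributions.

Every downstream stage can be driven without external data:

* migration / neurite cohorts — truncated-normal draws parameterized by the
  published per-condition mean/SD/n presets (:mod:`gzexit.presets`);
* a one-chromosome genome with planted transcription-factor binding: target
  genes receive a promoter-proximal peak with elevated probability;
* log2 expression matrices with a planted repressed gene block;
* qPCR Ct tables constructed to invert exactly through the delta-delta-Ct
  pipeline;
* binomial marker-labeling cohorts.

Randomness is organised as per-operation streams: each generator derives
its own :class:`numpy.random.Generator` from ``(seed, operation tag)``, so
adding a generator never perturbs another's draws and a fixed seed gives
bit-identical outputs.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gzexit.migration import CellCohort
from gzexit.presets import CohortPreset

log = logging.getLogger(__name__)

#: Retry budget per cell for the truncated-normal rejection sampler.
MAX_REJECTION_ROUNDS = 1000


class InfeasiblePresetError(RuntimeError):
    """Rejection sampling failed to place cells within the domain."""


def rng_stream(seed: int, tag: str) -> np.random.Generator:
    """Per-operation RNG: independent stream keyed by (seed, tag)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(tag.encode())])
    )


# ---------------------------------------------------------------------------
# migration / neurite cohorts
# ---------------------------------------------------------------------------

def truncated_normal_sample(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    n: int,
    lo: float,
    hi: float,
) -> np.ndarray:
    """Normal(mean, sd) draws restricted to [lo, hi] by rejection.

    For the published presets the nearest boundary sits >= 3.3 SD from the
    mean, so the acceptance rate is ~1 and the truncation bias negligible;
    the bias is documented rather than corrected.  Raises
    :class:`InfeasiblePresetError` after ``MAX_REJECTION_ROUNDS`` rounds.
    """
    if sd == 0:
        if not lo <= mean <= hi:
            raise InfeasiblePresetError("degenerate preset mean outside domain")
        return np.full(n, float(mean))
    out = np.empty(n)
    filled = 0
    for _ in range(MAX_REJECTION_ROUNDS):
        draws = rng.normal(mean, sd, size=n - filled)
        keep = draws[(draws >= lo) & (draws <= hi)]
        out[filled : filled + keep.size] = keep
        filled += keep.size
        if filled == n:
            return out
    raise InfeasiblePresetError(
        f"could not place {n} cells in [{lo}, {hi}] after "
        f"{MAX_REJECTION_ROUNDS} rounds (mean={mean}, sd={sd})"
    )


def generate_cohort(preset: CohortPreset, seed: int) -> CellCohort:
    """Synthesize a cell cohort whose surface distances follow the preset.

    Distances are truncated-normal draws on [0, domain_max]; the surface is
    the vertical line x = 0 (the simplest polyline any downstream consumer
    accepts) and cells sit at (distance, jittered y), so recomputing
    distances to the surface returns exactly the drawn values.
    """
    rng = rng_stream(seed, f"cohort:{preset.name}")
    d = truncated_normal_sample(
        rng, preset.mean_um, preset.sd_um, preset.n_cells, 0.0, preset.domain_max_um
    )
    y = rng.uniform(0.0, 100.0, size=preset.n_cells)
    surface = np.array([[0.0, -50.0], [0.0, 150.0]])
    return CellCohort(
        cells=np.column_stack([d, y]), condition=preset.name, surface=surface
    )


# ---------------------------------------------------------------------------
# planted binding association
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedAssociationConfig:
    """Synthetic genome with a planted bound-gene block.

    ``p_bind_target`` / ``p_bind_background`` are the per-gene probabilities
    of receiving one promoter-proximal peak (within +-1 kb of the TSS).
    """

    n_genes: int = 1000
    n_target_genes: int = 100
    p_bind_target: float = 0.8
    p_bind_background: float = 0.1
    chrom_length_bp: int = 100_000_000
    seed: int = 0
    peak_halfwidth_bp: int = 150
    peak_window_bp: int = 1000

    def __post_init__(self) -> None:
        if not 0 <= self.p_bind_background <= self.p_bind_target <= 1:
            raise ValueError("need 0 <= p_bind_background <= p_bind_target <= 1")
        if self.n_target_genes > self.n_genes:
            raise ValueError("n_target_genes must not exceed n_genes")


def generate_genome_and_peaks(
    cfg: PlantedAssociationConfig,
    target_ids=None,
) -> tuple[pd.DataFrame, pd.DataFrame, set[str]]:
    """Place TSSs on one synthetic chromosome and plant binding peaks.

    Returns ``(genes, peaks, target_ids)``.  Genes carry 1-based TSS
    coordinates and random strands; peaks are 0-based half-open intervals
    with a summit and a pseudo p-value.  TSSs are spaced so that +-1 kb
    promoter windows never overlap, keeping peak-to-gene assignment
    unambiguous.  The bound-gene block is a random subset of size
    ``n_target_genes`` unless ``target_ids`` names the genes explicitly
    (e.g. to align binding with a planted expression block).
    """
    rng = rng_stream(cfg.seed, "genome")
    min_gap = 2 * cfg.peak_window_bp + 1
    span = cfg.chrom_length_bp - cfg.n_genes * min_gap - 2 * cfg.peak_window_bp
    if span <= 0:
        raise ValueError("chromosome too short for non-overlapping promoter windows")
    # sorted uniforms plus a fixed stride guarantee pairwise gaps > min_gap
    base = np.sort(rng.uniform(0, span, size=cfg.n_genes))
    tss = (base + min_gap * np.arange(cfg.n_genes) + cfg.peak_window_bp).astype(int) + 1
    width = len(str(cfg.n_genes - 1))
    gene_ids = np.array([f"g{i:0{width}d}" for i in range(cfg.n_genes)])
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": "chrS",
            "tss": tss,
            "strand": rng.choice(["+", "-"], size=cfg.n_genes),
        }
    )
    if target_ids is None:
        target_idx = rng.choice(cfg.n_genes, size=cfg.n_target_genes, replace=False)
        is_target = np.zeros(cfg.n_genes, dtype=bool)
        is_target[target_idx] = True
    else:
        target_ids = set(target_ids)
        unknown = target_ids - set(gene_ids)
        if unknown:
            raise ValueError(f"unknown target gene ids: {sorted(unknown)[:5]}")
        is_target = np.isin(gene_ids, list(target_ids))
    p_bind = np.where(is_target, cfg.p_bind_target, cfg.p_bind_background)
    bound = rng.random(cfg.n_genes) < p_bind

    offsets = rng.integers(-cfg.peak_window_bp, cfg.peak_window_bp + 1,
                           size=cfg.n_genes)
    summits = np.maximum(tss - 1 + offsets, cfg.peak_halfwidth_bp)  # 0-based
    pvals = 10.0 ** (-rng.uniform(2.0, 10.0, size=cfg.n_genes))
    peaks = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": summits - cfg.peak_halfwidth_bp,
            "end": summits + cfg.peak_halfwidth_bp + 1,
            "name": [f"peak_{g}" for g in gene_ids],
            "summit": summits,
            "p_value": pvals,
        }
    )[bound].reset_index(drop=True)
    return genes, peaks, set(gene_ids[is_target])


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionSimConfig:
    """Log2 expression matrix with a planted repressed gene block.

    The first ``repressed_block_size`` genes are shifted by ``-log2_effect``
    in ``perturbed_condition`` (the last condition when unset), emulating a
    repressor gain-of-function experiment against its control.
    """

    n_genes: int = 1000
    conditions: tuple[str, ...] = ("control", "zeb1")
    repressed_block_size: int = 100
    log2_effect: float = 2.0
    noise_sd: float = 0.25
    replicates: int = 4
    seed: int = 0
    perturbed_condition: str | None = None

    def __post_init__(self) -> None:
        if self.repressed_block_size > self.n_genes:
            raise ValueError("repressed_block_size must not exceed n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if (self.perturbed_condition is not None
                and self.perturbed_condition not in self.conditions):
            raise ValueError("perturbed_condition must be one of conditions")


def generate_expression(cfg: ExpressionSimConfig):
    """Simulate a genes x (conditions x replicates) log2 intensity matrix."""
    from gzexit.expression import ExpressionMatrix

    rng = rng_stream(cfg.seed, "expression")
    perturbed = cfg.perturbed_condition or cfg.conditions[-1]
    width = len(str(cfg.n_genes - 1))
    gene_ids = [f"g{i:0{width}d}" for i in range(cfg.n_genes)]
    baseline = rng.uniform(6.0, 12.0, size=cfg.n_genes)

    cols, design, data = [], {}, []
    for cond in cfg.conditions:
        shift = np.zeros(cfg.n_genes)
        if cond == perturbed:
            shift[: cfg.repressed_block_size] = -cfg.log2_effect
        for rep in range(1, cfg.replicates + 1):
            sample = f"{cond}::r{rep}"
            cols.append(sample)
            design[sample] = cond
            data.append(baseline + shift
                        + rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes))
    values = pd.DataFrame(np.column_stack(data), index=gene_ids, columns=cols)
    values.index.name = "gene_id"
    return ExpressionMatrix(values=values, design=pd.Series(design))


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def generate_ct_table(
    true_folds: dict[str, float],
    reference_ct: float = 12.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    replicates: int = 3,
    conditions: tuple[str, str] = ("control", "treated"),
    reference_gene: str = "18S",
    base_ct: float = 25.0,
) -> pd.DataFrame:
    """Construct Ct values that invert exactly through delta-delta-Ct.

    ``true_folds`` maps each target gene to its fold change in
    ``conditions[1]`` relative to ``conditions[0]``: the target's Ct is
    lowered by log2(fold) cycles in the treated condition while the
    reference gene stays at ``reference_ct`` in every sample.  Optional
    Gaussian Ct noise can be added on top.
    """
    for gene, fold in true_folds.items():
        if fold <= 0:
            raise ValueError(f"fold for {gene} must be > 0 (got {fold})")
    rng = rng_stream(seed, "ct")
    ref_cond, alt_cond = conditions
    rows = []
    for rep in range(1, replicates + 1):
        for cond in conditions:
            rows.append((reference_gene, cond, rep, reference_ct))
            for gene, fold in true_folds.items():
                ct = base_ct - (np.log2(fold) if cond == alt_cond else 0.0)
                rows.append((gene, cond, rep, ct))
    table = pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])
    if noise_sd > 0:
        table["ct"] = table["ct"] + rng.normal(0.0, noise_sd, size=len(table))
    return table


# ---------------------------------------------------------------------------
# marker labeling
# ---------------------------------------------------------------------------

def generate_labeling(
    n_cells: int,
    p_positive: float,
    threshold: float = 0.225,
    seed: int = 0,
    condition: str = "",
) -> pd.DataFrame:
    """Per-cell marker intensities with a binomial positive fraction.

    Each cell is positive with probability ``p_positive``; positive cells
    get an intensity strictly above ``threshold``, negative cells at or
    below it, so the labeling index recovers the binomial draw exactly.
    """
    if not 0 <= p_positive <= 1:
        raise ValueError("p_positive must be in [0, 1]")
    rng = rng_stream(seed, "labeling")
    positive = rng.random(n_cells) < p_positive
    lo = np.nextafter(threshold, 1.0)
    intensity = np.where(
        positive,
        rng.uniform(lo, 1.0, size=n_cells),
        rng.uniform(0.0, threshold, size=n_cells),
    )
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n_cells)],
            "condition": condition,
            "intensity_frac": intensity,
        }
    )
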