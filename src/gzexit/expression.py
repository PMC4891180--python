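"""Expression quantification: deregulated-gene selection, BH FDR, qPCR.

The selector applies a per-gene Welch t-test between two conditions of a
log2 intensity matrix with Benjamini-Hochberg FDR control, keeping genes
at |fold change| >= 1.5 and q <= 0.05 (the published cutoffs).  The
per-gene Welch t is a deliberately simple test for matrices with known
planted truth; it is not a moderated-statistics replacement for array
pipelines.  qPCR arithmetic covers delta-delta-Ct relative quantification
against a reference gene (18S by default) and ChIP-qPCR fold enrichment
against an IgG control fixed at 1.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

FC_CUTOFF = 1.5
Q_CUTOFF = 0.05


@dataclass
class ExpressionMatrix:
    """Log2 intensities, genes x samples, with a sample -> condition design."""

    values: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix must have no missing values")
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples without design entry: {sorted(missing)}")

    def samples_of(self, condition: str) -> list[str]:
        cols = [s for s in self.values.columns if self.design[s] == condition]
        if len(cols) < 2:
            raise ValueError(f"condition {condition!r} needs >= 2 replicates")
        return cols


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1, returned in the
    original order.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def select_deregulated(
    matrix: ExpressionMatrix,
    condition_a: str,
    condition_b: str,
    fc_cutoff: float = FC_CUTOFF,
    q_cutoff: float = Q_CUTOFF,
) -> pd.DataFrame:
    """Per-gene Welch t + BH selection of deregulated genes.

    ``log2fc`` is mean(condition_a) - mean(condition_b), i.e. condition_b
    is the baseline.  A gene is selected when |fold change| >= ``fc_cutoff``
    on the linear scale (|log2fc| >= log2 fc_cutoff) and q <= ``q_cutoff``;
    ``direction`` is up/down by the sign of log2fc.  Genes with zero
    variance in both groups get p = 1 and are flagged ``degenerate``.
    """
    a = matrix.values[matrix.samples_of(condition_a)].to_numpy()
    b = matrix.values[matrix.samples_of(condition_b)].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    if degenerate.any():
        log.warning("%d genes with zero variance in both groups; p set to 1",
                    degenerate.sum())
    p = np.where(degenerate | np.isnan(p), 1.0, p)
    q = bh_fdr(p)
    selected = (np.abs(log2fc) >= np.log2(fc_cutoff)) & (q <= q_cutoff)
    return pd.DataFrame(
        {
            "gene_id": matrix.values.index,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "direction": np.where(log2fc >= 0, "up", "down"),
            "selected": selected,
            "degenerate": degenerate,
        }
    ).set_index("gene_id")


def ddct_relative_expression(
    ct_table: pd.DataFrame,
    reference_gene: str = "18S",
    reference_condition: str = "control",
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Delta-delta-Ct relative quantification.

    Per sample (condition, replicate): dCt = Ct_target - Ct_reference_gene;
    per gene and condition: ddCt = mean dCt(condition) - mean
    dCt(reference_condition); fold = efficiency ** (-ddCt).  Every gene's
    fold in the reference condition is 1 by construction.  Amplification
    efficiency is fixed at 2 (plain SYBR ddCt, no efficiency correction).

    ``ct_table`` needs columns gene, condition, replicate, ct; the
    reference gene must be present in every (condition, replicate) sample.
    """
    required = {"gene", "condition", "replicate", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    ref = ct_table[ct_table["gene"] == reference_gene].set_index(
        ["condition", "replicate"]
    )["ct"]
    targets = ct_table[ct_table["gene"] != reference_gene].copy()
    sample_idx = pd.MultiIndex.from_frame(targets[["condition", "replicate"]])
    missing = sample_idx.unique().difference(ref.index)
    if len(missing) or ref.index.duplicated().any():
        raise ValueError(
            f"reference gene {reference_gene!r} missing or duplicated in "
            f"samples: {list(missing)}"
        )
    targets["dct"] = targets["ct"].to_numpy() - ref.reindex(sample_idx).to_numpy()
    mean_dct = targets.groupby(["gene", "condition"])["dct"].mean().unstack()
    if reference_condition not in mean_dct.columns:
        raise ValueError(f"reference condition {reference_condition!r} not found")
    ddct = mean_dct.sub(mean_dct[reference_condition], axis=0)
    folds = float(efficiency) ** (-ddct)
    folds.columns.name = "condition"
    return folds


def chip_fold_enrichment(sample_pct_input, igg_pct_input):
    """ChIP-qPCR fold enrichment over the IgG control.

    ``fold = sample %input / IgG %input``; the IgG channel is by definition
    exactly 1.0.  Accepts scalars or aligned array-likes; returns a
    DataFrame with ``fold`` and ``igg_fold`` columns (or floats for
    scalars).
    """
    sample = np.asarray(sample_pct_input, dtype=float)
    igg = np.asarray(igg_pct_input, dtype=float)
    if (igg <= 0).any():
        raise ValueError("IgG %input must be > 0")
    if (sample < 0).any():
        raise ValueError("sample %input must be >= 0")
    fold = sample / igg
    if fold.ndim == 0:
        return float(fold)
    return pd.DataFrame({"fold": fold, "igg_fold": np.ones_like(fold)})
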