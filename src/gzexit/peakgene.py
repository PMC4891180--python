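"""ChIP-peak-to-gene assignment and gene-set association statistics.

Peaks (0-based half-open intervals with a summit) are assigned to the gene
with the closest annotated TSS on the same chromosome.  Association between
binding events and a gene set (e.g. the genes down-regulated by a
transcription factor) is tested against a resampling null: the binding-event
count of the observed set is compared with counts over random gene sets of
equal size drawn from the array universe, with a normal approximation to
the null giving z and p.  A cumulative-fraction map relates deregulation
strength (fold-change bins) to binding significance thresholds, with a
label-permuted control.  A motif-density profile counts E-box occurrences
around peak summits.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


class DegenerateNullError(ValueError):
    """The resampling null has zero variance (e.g. gene_set == universe)."""


# ---------------------------------------------------------------------------
# peak -> gene assignment
# ---------------------------------------------------------------------------

def _validate_genes(genes: pd.DataFrame) -> None:
    required = {"gene_id", "chrom", "tss", "strand"}
    if not required.issubset(genes.columns):
        raise ValueError(f"gene table needs columns {sorted(required)}")
    if genes["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in gene table")


def assign_peaks_to_genes(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_window: tuple[int, int] = (2000, 500),
    proximal_bp: int = 10_000,
) -> pd.DataFrame:
    """Assign each peak to the gene with the nearest TSS.

    Nearness is ``|summit - tss|`` on the peak's chromosome; ties (two TSSs
    exactly equidistant, or several genes sharing a TSS) go to the
    lexicographically smallest gene_id, making the assignment deterministic
    and independent of input ordering.  The signed distance is strand-aware
    (negative = upstream of the TSS).  Feature classes: ``promoter`` when
    the summit lies within ``-upstream..+downstream`` of the TSS,
    ``gene-proximal`` within ``proximal_bp``, else ``distal``.  Peaks on a
    chromosome without genes yield an unassigned record (gene_id NaN),
    logged.

    Gene TSSs are 1-based (as stored in gene tables); summits 0-based (BED
    convention).  The conversion happens here, once.
    """
    _validate_genes(genes)
    up_bp, down_bp = promoter_window
    records = []
    by_chrom = {
        chrom: grp.sort_values(["tss", "gene_id"], kind="mergesort")
        for chrom, grp in genes.groupby("chrom")
    }
    for idx, peak in peaks.iterrows():
        grp = by_chrom.get(peak["chrom"])
        if grp is None:
            log.warning("peak %s on %s has no genes; left unassigned",
                        idx, peak["chrom"])
            records.append((idx, peak["chrom"], int(peak["summit"]),
                            None, np.nan, "unassigned"))
            continue
        tss0 = grp["tss"].to_numpy() - 1  # 0-based TSS positions, sorted
        summit = int(peak["summit"])
        j = np.searchsorted(tss0, summit)
        cand = [k for k in (j - 1, j) if 0 <= k < len(tss0)]
        dmin = min(abs(summit - tss0[k]) for k in cand)
        # all genes achieving the minimum distance (handles shared TSSs
        # and exact left/right ties); smallest gene_id wins
        tied = abs(summit - tss0) == dmin
        sub = grp[tied]
        row = sub.loc[sub["gene_id"].idxmin()]
        gene_tss0 = int(row["tss"]) - 1
        signed = summit - gene_tss0 if row["strand"] == "+" else gene_tss0 - summit
        if -up_bp <= signed <= down_bp:
            feat = "promoter"
        elif abs(signed) <= proximal_bp:
            feat = "gene-proximal"
        else:
            feat = "distal"
        records.append((idx, peak["chrom"], summit, row["gene_id"], signed, feat))
    out = pd.DataFrame(
        records,
        columns=["peak_index", "chrom", "summit", "gene_id",
                 "signed_distance", "feature_class"],
    )
    if "p_value" in peaks.columns:
        out["p_value"] = peaks["p_value"].to_numpy()
    return out


def count_binding_events(assignments: pd.DataFrame, gene_set) -> int:
    """Number of peaks assigned to a gene in ``gene_set`` (peaks, not genes)."""
    gene_set = set(gene_set)
    if not gene_set:
        log.warning("count_binding_events: empty gene set")
        return 0
    return int(assignments["gene_id"].isin(gene_set).sum())


# ---------------------------------------------------------------------------
# resampling association null
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    """Observed binding count against a size-matched resampling null."""

    observed: int
    null_mean: float
    null_sd: float
    z: float
    p: float
    null_draws: int
    boxplot: dict
    tail: str = "greater"


def _null_counts(
    per_gene_counts: np.ndarray,
    k: int,
    n_resample: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binding-event counts of ``n_resample`` random size-k gene subsets."""
    u = per_gene_counts.size
    # one argpartition per draw, vectorized: k smallest of u uniforms
    # is a uniform without-replacement subset
    keys = rng.random((n_resample, u))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    return per_gene_counts[idx].sum(axis=1)


def resample_association(
    assignments: pd.DataFrame,
    gene_set,
    universe,
    n_resample: int = 1000,
    seed: int = 0,
    tail: str = "greater",
) -> AssociationResult:
    """Test binding-event enrichment in a gene set by resampling.

    Draws ``n_resample`` random subsets of size ``|gene_set|`` from the
    array universe without replacement, counts binding events for each,
    and converts the observed count to z = (obs - mean)/sd with a normal
    approximation for p (upper tail by default, since the hypothesis is
    enrichment).  Boxplot statistics of the null (median, quartiles,
    1.5 x IQR whiskers clipped to the observed null range) are reported
    for plotting.
    """
    from gzexit.synthetic import rng_stream

    universe = pd.Index(sorted(set(universe)))
    gene_set = set(gene_set)
    if not gene_set <= set(universe):
        raise ValueError("gene_set must be a subset of the universe")
    if tail not in ("greater", "less", "two-sided"):
        raise ValueError("tail must be greater, less or two-sided")

    counts_by_gene = assignments["gene_id"].value_counts()
    per_gene = counts_by_gene.reindex(universe, fill_value=0).to_numpy(dtype=np.int64)
    observed = int(per_gene[universe.isin(gene_set)].sum())

    rng = rng_stream(seed, "resample_association")
    null = _null_counts(per_gene, len(gene_set), n_resample, rng)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    if null_sd == 0:
        raise DegenerateNullError(
            "resampling null has zero variance (every draw yields "
            f"{null_mean:g} events); is gene_set the whole universe?"
        )
    z = (observed - null_mean) / null_sd
    if tail == "greater":
        p = stats.norm.sf(z)
    elif tail == "less":
        p = stats.norm.cdf(z)
    else:
        p = 2 * stats.norm.sf(abs(z))

    q1, med, q3 = np.percentile(null, [25, 50, 75])
    iqr = q3 - q1
    boxplot = {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_lo": float(max(q1 - 1.5 * iqr, null.min())),
        "whisker_hi": float(min(q3 + 1.5 * iqr, null.max())),
    }
    return AssociationResult(
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=float(z),
        p=float(p),
        null_draws=n_resample,
        boxplot=boxplot,
        tail=tail,
    )


# ---------------------------------------------------------------------------
# cumulative-fraction enrichment map
# ---------------------------------------------------------------------------

DEFAULT_P_THRESHOLDS = tuple(10.0 ** np.arange(-5.0, -1.0, 0.5)) + (0.05,)


@dataclass
class CumulativeFractionMap:
    """Fraction of top-deregulated genes bound at increasing p cutoffs."""

    fc_bin_edges: list
    p_thresholds: np.ndarray
    fractions: np.ndarray  # (n_fc_bins, n_thresholds)
    control_mean: np.ndarray
    direction: str = ""


def cumulative_fraction_map(
    fold_changes: pd.Series,
    bound_gene_pvalues: pd.Series,
    direction: str = "down",
    n_fc_bins: int = 20,
    p_thresholds=None,
    n_random: int = 100,
    seed: int = 0,
) -> CumulativeFractionMap:
    """Map deregulation strength against binding significance.

    ``fold_changes`` is per-gene log2 fold change over the whole universe;
    ``bound_gene_pvalues`` the best binding p-value per bound gene.  Genes
    of the requested direction are sorted by decreasing |fold change| and
    split into ``n_fc_bins`` equal-size bins; entry (i, j) is the fraction
    of genes in cumulative bins 1..i bound at p <= threshold_j, so rows are
    non-decreasing along the threshold axis.  ``control_mean`` repeats the
    computation with the observed binding p-values reassigned to uniformly
    random same-size gene sets, averaged over ``n_random`` draws.
    """
    from gzexit.synthetic import rng_stream

    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    thresholds = np.asarray(
        DEFAULT_P_THRESHOLDS if p_thresholds is None else p_thresholds, dtype=float
    )
    sel = fold_changes[fold_changes > 0] if direction == "up" else \
        fold_changes[fold_changes < 0]
    if n_fc_bins > len(sel):
        raise ValueError("n_fc_bins exceeds gene count for this direction")
    order = sel.abs().sort_values(ascending=False, kind="mergesort").index
    bins = np.array_split(np.arange(len(order)), n_fc_bins)
    cut_sizes = np.cumsum([len(b) for b in bins])

    def one_map(pvals: pd.Series) -> np.ndarray:
        gene_p = pvals.reindex(order).to_numpy(dtype=float)  # NaN = unbound
        out = np.empty((n_fc_bins, thresholds.size))
        for j, thr in enumerate(thresholds):
            bound = np.nan_to_num(gene_p, nan=np.inf) <= thr
            cum = np.cumsum(bound)
            out[:, j] = cum[cut_sizes - 1] / cut_sizes
        return out

    fractions = one_map(bound_gene_pvalues)

    rng = rng_stream(seed, "cumulative_fraction_control")
    universe = fold_changes.index.to_numpy()
    pv = bound_gene_pvalues.to_numpy(dtype=float)
    acc = np.zeros_like(fractions)
    for _ in range(n_random):
        random_genes = rng.choice(universe, size=pv.size, replace=False)
        acc += one_map(pd.Series(pv, index=random_genes))
    return CumulativeFractionMap(
        fc_bin_edges=[int(s) for s in cut_sizes],
        p_thresholds=thresholds,
        fractions=fractions,
        control_mean=acc / n_random,
        direction=direction,
    )


# ---------------------------------------------------------------------------
# E-box motif density
# ---------------------------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _iupac_regex(motif: str) -> re.Pattern:
    try:
        body = "".join(_IUPAC[c] for c in motif.upper())
    except KeyError as e:
        raise ValueError(f"invalid IUPAC code in motif: {e}") from None
    return re.compile(f"(?=({body}))")


def _revcomp_iupac(motif: str) -> str:
    return motif.upper().translate(_COMPLEMENT)[::-1]


def _fetch(seqs, chrom: str, start: int, end: int) -> str:
    """Window from a dict of strings or a pyfaidx-style Fasta object."""
    record = seqs[chrom]
    piece = record[start:end]
    return str(piece).upper()


def ebox_density(
    peaks: pd.DataFrame,
    seqs,
    motif: str = "CACCTG",
    window: int = 2000,
) -> pd.DataFrame:
    """Per-offset motif occurrence frequency around peak summits.

    For each offset in [-window, +window) the value is the fraction of
    peaks whose +-window sequence contains a motif match *starting* at that
    offset on either strand (forward motif or its reverse complement on the
    forward sequence).  Windows truncated at contig ends are dropped and
    logged.  The motif is an IUPAC string; the default CACCTG is the
    Zeb-class E-box core, CANNTG matches the looser consensus.
    """
    fwd = _iupac_regex(motif)
    rev = _iupac_regex(_revcomp_iupac(motif))
    offsets = np.arange(-window, window)
    hits = np.zeros(offsets.size)
    used = 0
    for _, peak in peaks.iterrows():
        summit = int(peak["summit"])
        chrom = peak["chrom"]
        contig_len = len(seqs[chrom]) if hasattr(seqs[chrom], "__len__") else None
        lo, hi = summit - window, summit + window
        if lo < 0 or (contig_len is not None and hi > contig_len):
            log.warning("window around summit %d on %s truncated; dropped",
                        summit, chrom)
            continue
        s = _fetch(seqs, chrom, lo, hi)
        if len(s) < 2 * window:
            log.warning("window around summit %d on %s truncated; dropped",
                        summit, chrom)
            continue
        row = np.zeros(offsets.size, dtype=bool)
        for m in fwd.finditer(s):
            if m.start() < offsets.size:
                row[m.start()] = True
        for m in rev.finditer(s):
            if m.start() < offsets.size:
                row[m.start()] = True
        hits += row
        used += 1
    if used == 0:
        raise ValueError("no usable windows (all truncated or no peaks)")
    return pd.DataFrame({"offset": offsets, "frequency": hits / used})
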