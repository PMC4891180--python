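"""Peak assignment, binding-event counting, resampling null, map, motif density."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gzexit import (
    assign_peaks_to_genes,
    count_binding_events,
    cumulative_fraction_map,
    ebox_density,
    resample_association,
)
from gzexit.peakgene import DegenerateNullError

from conftest import make_peaks


def brute_force_assign(peaks, genes):
    """O(n*m) all-pairs nearest-TSS scan (independent oracle)."""
    out = []
    for _, pk in peaks.iterrows():
        cand = genes[genes["chrom"] == pk["chrom"]]
        if cand.empty:
            out.append(None)
            continue
        dist = (pk["summit"] - (cand["tss"] - 1)).abs()
        best = dist.min()
        out.append(cand.loc[dist == best, "gene_id"].min())
    return out


class TestAssign:
    def test_summit_at_tss_is_promoter_distance_zero(self, toy_genes):
        peaks = make_peaks([1000])  # 0-based summit of 1-based TSS 1001
        a = assign_peaks_to_genes(peaks, toy_genes)
        assert a.loc[0, "gene_id"] == "geneA"
        assert a.loc[0, "signed_distance"] == 0
        assert a.loc[0, "feature_class"] == "promoter"

    def test_signed_distance_is_strand_aware(self, toy_genes):
        # 100 bp left of geneA(+) TSS -> upstream (negative);
        # 100 bp left of geneB(-) TSS -> downstream (positive)
        a = assign_peaks_to_genes(make_peaks([900, 4900]), toy_genes)
        assert a.loc[0, "signed_distance"] == -100
        assert a.loc[1, "signed_distance"] == 100

    def test_equidistant_tie_goes_to_smaller_gene_id(self, toy_genes):
        a = assign_peaks_to_genes(make_peaks([3000]), toy_genes)  # 2000 bp each
        assert a.loc[0, "gene_id"] == "geneA"

    def test_chromosome_without_genes_left_unassigned(self, toy_genes):
        a = assign_peaks_to_genes(make_peaks([500], chrom="chrX"), toy_genes)
        assert a.loc[0, "feature_class"] == "unassigned"
        assert pd.isna(a.loc[0, "gene_id"])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(21)
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i:02d}" for i in range(20)],
                "chrom": rng.choice(["chr1", "chr2"], 20),
                "tss": rng.integers(1, 100_000, 20),
                "strand": rng.choice(["+", "-"], 20),
            }
        )
        peaks = make_peaks(rng.integers(200, 100_000, 50), chrom="chr1")
        peaks.loc[25:, "chrom"] = "chr2"
        a = assign_peaks_to_genes(peaks, genes)
        assert list(a["gene_id"]) == brute_force_assign(peaks, genes)

    def test_order_independent(self, toy_genes):
        rng = np.random.default_rng(22)
        peaks = make_peaks(rng.integers(200, 10_000, 30))
        a = assign_peaks_to_genes(peaks, toy_genes)
        shuffled = peaks.sample(frac=1, random_state=1)
        b = assign_peaks_to_genes(shuffled, toy_genes)
        merged = a.merge(b, on="peak_index", suffixes=("_a", "_b"))
        assert (merged["gene_id_a"] == merged["gene_id_b"]).all()
        assert (merged["signed_distance_a"] == merged["signed_distance_b"]).all()


class TestCounting:
    def test_empty_set_is_zero(self, toy_genes):
        a = assign_peaks_to_genes(make_peaks([1000]), toy_genes)
        assert count_binding_events(a, set()) == 0

    def test_counts_peaks_not_genes(self, toy_genes):
        a = assign_peaks_to_genes(make_peaks([990, 1000, 1010, 5000]), toy_genes)
        assert count_binding_events(a, {"geneA"}) == 3
        assert count_binding_events(a, {"geneB"}) == 1

    def test_matches_filter_and_count(self, planted_instance):
        genes, _, targets, assignments = planted_instance
        oracle = sum(1 for g in assignments["gene_id"] if g in targets)
        assert count_binding_events(assignments, targets) == oracle


class TestResampling:
    def test_gene_set_equal_universe_degenerate(self, planted_instance):
        genes, _, _, assignments = planted_instance
        with pytest.raises(DegenerateNullError):
            resample_association(assignments, set(genes["gene_id"]),
                                 genes["gene_id"])

    def test_null_mean_matches_exhaustive_enumeration(self, toy_genes):
        rng = np.random.default_rng(30)
        universe = [f"u{i}" for i in range(10)]
        genes = pd.DataFrame(
            {
                "gene_id": universe,
                "chrom": "chr1",
                "tss": np.arange(10) * 10_000 + 1,
                "strand": "+",
            }
        )
        peaks = make_peaks(rng.choice(np.arange(10) * 10_000, size=25))
        assignments = assign_peaks_to_genes(peaks, genes)
        counts = assignments["gene_id"].value_counts().reindex(
            universe, fill_value=0
        )
        exact = np.mean(
            [counts[list(s)].sum()
             for s in itertools.combinations(universe, 3)]
        )
        exact_sd = np.std(
            [counts[list(s)].sum()
             for s in itertools.combinations(universe, 3)], ddof=1
        )
        res = resample_association(assignments, set(universe[:3]), universe,
                                   n_resample=10_000, seed=1)
        assert abs(res.null_mean - exact) < 3 * exact_sd / np.sqrt(10_000)

    def test_z_invariant_under_gene_relabeling(self, planted_instance):
        genes, peaks, targets, assignments = planted_instance
        relabel = {g: f"x{g}" for g in genes["gene_id"]}
        assignments2 = assignments.assign(
            gene_id=assignments["gene_id"].map(relabel)
        )
        r1 = resample_association(assignments, targets, genes["gene_id"], seed=7)
        r2 = resample_association(
            assignments2, {relabel[g] for g in targets},
            [relabel[g] for g in genes["gene_id"]], seed=7,
        )
        assert r1.observed == r2.observed
        assert r1.z == pytest.approx(r2.z)

    def test_boxplot_whiskers_are_iqr_rule_clipped_to_range(self, planted_instance):
        genes, _, targets, assignments = planted_instance
        res = resample_association(assignments, targets, genes["gene_id"], seed=3)
        b = res.boxplot
        iqr = b["q3"] - b["q1"]
        assert b["whisker_lo"] >= b["q1"] - 1.5 * iqr - 1e-12
        assert b["whisker_hi"] <= b["q3"] + 1.5 * iqr + 1e-12
        assert b["whisker_lo"] <= b["q1"] <= b["median"] <= b["q3"] <= b["whisker_hi"]

    def test_set_outside_universe_rejected(self, planted_instance):
        genes, _, _, assignments = planted_instance
        with pytest.raises(ValueError, match="subset"):
            resample_association(assignments, {"nope"}, genes["gene_id"])


class TestCumulativeMap:
    universe = pd.Series(
        {"a": -3.0, "b": -2.0, "c": -1.0, "d": -0.5, "e": -0.4, "f": -0.1,
         "g": 1.0, "h": 2.0}
    )

    def test_no_gene_bound_all_zero(self):
        m = cumulative_fraction_map(self.universe, pd.Series(dtype=float),
                                    direction="down", n_fc_bins=3, n_random=5)
        assert (m.fractions == 0).all()
        assert (m.control_mean == 0).all()

    def test_every_gene_bound_all_ones(self):
        bound = pd.Series(1e-9, index=self.universe.index)
        m = cumulative_fraction_map(self.universe, bound, direction="down",
                                    n_fc_bins=3, n_random=5)
        assert (m.fractions == 1).all()

    def test_toy_map_matches_hand_enumeration(self):
        # down genes sorted by |fc|: a, b, c, d, e, f -> bins (a,b,c), (d,e,f)
        fc = self.universe
        bound = pd.Series({"a": 1e-6, "d": 0.01})
        m = cumulative_fraction_map(
            fc, bound, direction="down", n_fc_bins=2,
            p_thresholds=[1e-4, 0.05], n_random=5,
        )
        # thr 1e-4: only a bound -> 1/3 then 1/6; thr 0.05: a and d -> 1/3, 2/6
        np.testing.assert_allclose(
            m.fractions, [[1 / 3, 1 / 3], [1 / 6, 2 / 6]]
        )

    def test_rows_non_decreasing_along_threshold_axis(self, planted_instance):
        genes, _, targets, assignments = planted_instance
        rng = np.random.default_rng(0)
        fc = pd.Series(rng.normal(0, 2, len(genes)),
                       index=genes["gene_id"])
        bound = assignments.dropna(subset=["gene_id"]).groupby(
            "gene_id")["p_value"].min()
        m = cumulative_fraction_map(fc, bound, direction="down",
                                    n_fc_bins=10, n_random=10)
        assert (np.diff(m.fractions, axis=1) >= -1e-12).all()
        assert (np.diff(m.control_mean, axis=1) >= -1e-12).all()

    def test_too_many_bins_rejected(self):
        with pytest.raises(ValueError, match="n_fc_bins"):
            cumulative_fraction_map(self.universe, pd.Series(dtype=float),
                                    direction="up", n_fc_bins=5)


class TestEboxDensity:
    @staticmethod
    def random_seq(rng, n):
        return "".join(rng.choice(list("ACGT"), size=n))

    def test_motif_free_sequence_gives_zero_profile(self):
        seq = "A" * 10_000
        peaks = make_peaks([5000], chrom="chrS")
        prof = ebox_density(peaks, {"chrS": seq}, window=1000)
        assert (prof["frequency"] == 0).all()
        assert len(prof) == 2000

    def test_planted_motif_peaks_at_offset_zero(self):
        rng = np.random.default_rng(31)
        seq = list(self.random_seq(rng, 50_000))
        summits = rng.integers(3000, 47_000, size=25)
        for s in summits:
            seq[s : s + 6] = "CACCTG"
        prof = ebox_density(make_peaks(summits, chrom="chrS"),
                            {"chrS": "".join(seq)}, window=2000)
        assert prof.loc[prof["frequency"].idxmax(), "offset"] == 0
        assert prof["frequency"].max() == 1.0

    def test_uniform_sequence_matches_closed_form(self):
        rng = np.random.default_rng(32)
        seqs = {"chrS": self.random_seq(rng, 300_000)}
        summits = rng.integers(2000, 298_000, size=40)
        prof = ebox_density(make_peaks(summits, chrom="chrS"), seqs,
                            window=1000)
        # either-strand match probability per position under uniform bases
        p = 2 * 0.25**6 - 0.25**12
        se = np.sqrt(p * (1 - p) / 40 / len(prof))
        assert abs(prof["frequency"].mean() - p) < 3 * se

    def test_truncated_windows_dropped(self):
        seqs = {"chrS": "ACGT" * 1000}
        peaks = make_peaks([100, 2500], chrom="chrS")  # first window truncated
        prof = ebox_density(peaks, seqs, window=1500)
        assert prof["frequency"].isin([0.0, 1.0]).all()  # single usable peak
        with pytest.raises(ValueError, match="no usable"):
            ebox_density(make_peaks([100], chrom="chrS"), seqs, window=1500)

    def test_degenerate_iupac_motif_supported(self):
        seq = "T" * 3000 + "CAGGTG" + "T" * 3000  # revcomp of CACCTG
        prof = ebox_density(make_peaks([3000], chrom="chrS"), {"chrS": seq},
                            window=500)
        assert prof.loc[prof["offset"] == 0, "frequency"].item() == 1.0
        loose = ebox_density(make_peaks([3000], chrom="chrS"), {"chrS": seq},
                             motif="CANNTG", window=500)
        assert loose["frequency"].sum() >= prof["frequency"].sum()
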