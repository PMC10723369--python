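"""Transcription coupling: binning, DE scores, gene mapping, group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import trace3d as t3
from trace3d import coupling as cpl

from conftest import make_panel


class TestRadialActivityFractions:
    def test_anti_monotone_activity_concentrates_curves(self):
        ids = [f"l{i}" for i in range(40)]
        radial = pd.Series(np.linspace(0.05, 0.95, 40), index=ids)
        track = pd.Series(np.linspace(1.0, 0.0, 40), index=ids)  # active = interior
        out = cpl.radial_activity_fractions(radial, track, n_bins=4)
        # high-activity mass concentrates in the innermost bins, low in outer
        assert out["frac_high"].iloc[:2].sum() == pytest.approx(1.0)
        assert out["frac_low"].iloc[2:].sum() == pytest.approx(1.0)
        assert out["frac_high"].iloc[0] >= 0.9
        assert out["frac_low"].iloc[-1] >= 0.9

    def test_uniform_activity_equal_curves(self):
        ids = [f"l{i}" for i in range(20)]
        radial = pd.Series(np.linspace(0, 1, 20), index=ids)
        track = pd.Series(1.0, index=ids)
        out = cpl.radial_activity_fractions(radial, track, n_bins=5)
        np.testing.assert_allclose(out["frac_high"], out["frac_low"])

    def test_curves_sum_to_one(self):
        rng = np.random.default_rng(0)
        ids = [f"l{i}" for i in range(57)]
        radial = pd.Series(rng.random(57), index=ids)
        track = pd.Series(rng.random(57), index=ids)
        out = cpl.radial_activity_fractions(radial, track, n_bins=10)
        assert out["frac_high"].sum() == pytest.approx(1.0, abs=1e-12)
        assert out["frac_low"].sum() == pytest.approx(1.0, abs=1e-12)


class TestRadialTrackCorrelation:
    def test_perfect_correlations(self):
        ids = [f"l{i}" for i in range(15)]
        radial = pd.Series(np.linspace(0, 1, 15), index=ids)
        assert cpl.radial_track_correlation(radial, radial)["spearman_r"] == pytest.approx(1.0)
        assert cpl.radial_track_correlation(radial, -radial)["spearman_r"] == pytest.approx(-1.0)

    def test_matches_rank_oracle(self):
        rng = np.random.default_rng(1)
        ids = [f"l{i}" for i in range(20)]
        radial = pd.Series(rng.random(20), index=ids)
        track = pd.Series(rng.random(20), index=ids)
        got = cpl.radial_track_correlation(radial, track)["spearman_r"]
        # hand rank computation: Pearson on ranks
        rr = pd.Series(radial).rank().to_numpy()
        tr = pd.Series(track).rank().to_numpy()
        expected = stats.pearsonr(rr, tr).statistic
        assert got == pytest.approx(expected, abs=1e-12)

    def test_constant_track_absent(self):
        ids = [f"l{i}" for i in range(12)]
        radial = pd.Series(np.linspace(0, 1, 12), index=ids)
        out = cpl.radial_track_correlation(radial, pd.Series(2.0, index=ids))
        assert out["spearman_r"] is None


class TestMapGenesToLoci:
    def test_tie_goes_to_lower_coordinate(self):
        panel = make_panel(1, 2)  # midpoints at 1,025,000 and 2,025,000
        genes = pd.DataFrame({"gene_id": ["g"], "tss_chrom": ["chr1"],
                              "tss_bp": [1_525_000]})  # equidistant
        m = cpl.map_genes_to_loci(genes, panel)
        assert m["locus_id"].iloc[0] == "chr1_L000"

    def test_exact_midpoint_distance_zero(self):
        panel = make_panel(1, 2)
        genes = pd.DataFrame({"gene_id": ["g"], "tss_chrom": ["chr1"],
                              "tss_bp": [1_025_000]})
        m = cpl.map_genes_to_loci(genes, panel)
        assert m["mapping_distance_bp"].iloc[0] == 0

    def test_max_distance_unmaps(self):
        panel = make_panel(1, 2)
        genes = pd.DataFrame({"gene_id": ["g"], "tss_chrom": ["chr1"],
                              "tss_bp": [1_175_000]})  # 150 kb from nearest
        m = cpl.map_genes_to_loci(genes, panel, max_distance_bp=100_000)
        assert pd.isna(m["locus_id"].iloc[0])

    def test_absent_chromosome_unmapped(self):
        panel = make_panel(1, 2)
        genes = pd.DataFrame({"gene_id": ["g"], "tss_chrom": ["chrX"], "tss_bp": [5]})
        m = cpl.map_genes_to_loci(genes, panel)
        assert pd.isna(m["locus_id"].iloc[0])


class TestDeScore:
    def test_hand_welch_value(self):
        # {0,1,2} vs {1,2,3}: means 1 vs 2, each variance 1, n=3 -> 1/sqrt(2/3)
        assert cpl.welch_t(np.array([0, 1, 2]), np.array([1, 2, 3])) == pytest.approx(
            1.2247448, abs=1e-6)

    def test_antisymmetry(self):
        a, b = np.array([0.0, 1, 2, 5]), np.array([1.0, 2, 3, 3])
        assert cpl.welch_t(a, b) == pytest.approx(-cpl.welch_t(b, a))

    def test_identical_groups_zero(self):
        assert cpl.welch_t(np.array([1.0, 2, 3]), np.array([1.0, 2, 3])) == 0.0

    def test_both_constant_absent(self):
        assert np.isnan(cpl.welch_t(np.array([2.0, 2.0]), np.array([2.0, 2.0])))

    def test_de_score_normalization_pipeline(self, small_sim):
        expr = small_sim["expr"]
        cells = list(expr.counts.columns)
        ga, gb = cells[:10], cells[10:20]
        gene = expr.genes["gene_id"].iloc[0]
        t = cpl.de_score(expr, gene, ga, gb)
        norm = cpl.normalize_counts(expr.counts)
        expected = cpl.welch_t(norm.loc[gene, ga].to_numpy(), norm.loc[gene, gb].to_numpy())
        assert t == pytest.approx(expected) or (np.isnan(t) and np.isnan(expected))


class TestBinnedProfile:
    def test_two_equal_count_bins(self):
        y = np.arange(1.0, 11.0)
        bp = cpl.binned_profile(y, y, 2)
        assert bp.table["mean"].tolist() == [3.0, 8.0]

    def test_constant_y_zero_ci(self):
        bp = cpl.binned_profile(np.arange(10.0), np.full(10, 2.0), 5)
        assert (bp.table["mean"] == 2.0).all()
        assert (bp.table["ci95"] == 0.0).all()

    def test_eleven_items_two_bins_sizes(self):
        bp = cpl.binned_profile(np.arange(11.0), np.arange(11.0), 2)
        assert bp.table["n"].tolist() == [6, 5]

    def test_fewer_items_than_bins_rejected(self):
        with pytest.raises(ValueError):
            cpl.binned_profile(np.arange(3.0), np.arange(3.0), 5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_permutation_invariance_of_bin_means(self, seed):
        """Shuffling tied-free input leaves equal-count bin means unchanged."""
        rng = np.random.default_rng(seed)
        x = rng.permutation(np.linspace(0, 1, 23))  # distinct values, no ties
        y = x * 2 + 1
        perm = rng.permutation(23)
        a = cpl.binned_profile(x, y, 4).table["mean"]
        b = cpl.binned_profile(x[perm], y[perm], 4).table["mean"]
        np.testing.assert_allclose(a, b)


class TestGenotypeDelta:
    def test_identity_and_shift(self):
        wt = pd.Series([0.2, 0.5, 0.8], index=["a", "b", "c"])
        assert (cpl.genotype_delta(wt, wt) == 0).all()
        np.testing.assert_allclose(cpl.genotype_delta(wt, wt + 0.1), 0.1)

    def test_missing_locus_absent(self):
        wt = pd.Series([0.2, 0.5], index=["a", "b"])
        ko = pd.Series([0.3], index=["a"])
        delta = cpl.genotype_delta(wt, ko)
        assert list(delta.index) == ["a"]


class TestGroupComparison:
    def test_mwu_exact_small_sample(self):
        # C(6,3)=20 arrangements; extreme split -> two-sided p = 2/20 = 0.1
        out = cpl.group_comparison({"a": np.array([1, 2, 3]),
                                    "b": np.array([4, 5, 6])}, "mwu_bh")
        res = out["results"]["a vs b"]
        assert res["statistic"] in (0.0, 9.0)
        assert res["p_raw"] == pytest.approx(0.1)

    def test_identical_groups_ttest(self):
        out = cpl.group_comparison({"a": np.array([1.0, 2, 3]),
                                    "b": np.array([1.0, 2, 3])}, "ttest_bonferroni")
        res = out["results"]["a vs b"]
        assert res["statistic"] == 0.0
        assert res["p_adjusted"] == pytest.approx(1.0)

    def test_bonferroni_is_min_one_mp(self):
        rng = np.random.default_rng(3)
        groups = {k: rng.normal(size=6) for k in "abc"}
        out = cpl.group_comparison(groups, "ttest_bonferroni")
        raw = [v["p_raw"] for v in out["results"].values()]
        adj = [v["p_adjusted"] for v in out["results"].values()]
        for p, q in zip(raw, adj):
            assert q == pytest.approx(min(1.0, 3 * p))

    def test_bh_matches_definitional_oracle(self):
        rng = np.random.default_rng(4)
        groups = {k: rng.normal(loc=i, size=8) for i, k in enumerate("abcd")}
        out = cpl.group_comparison(groups, "mwu_bh")
        raw = np.array([v["p_raw"] for v in out["results"].values()])
        adj = np.array([v["p_adjusted"] for v in out["results"].values()])
        # definitional BH: sort, p*(m/rank), cumulative min from the largest
        m = len(raw)
        order = np.argsort(raw)
        stepped = raw[order] * m / np.arange(1, m + 1)
        expected_sorted = np.minimum.accumulate(stepped[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(expected_sorted, 1.0)
        np.testing.assert_allclose(adj, expected, atol=1e-12)

    def test_anova_tukey_route(self):
        out = cpl.group_comparison({"a": np.array([0.0, 0, 0.1]),
                                    "b": np.array([1.0, 1, 1.1]),
                                    "c": np.array([0.0, 0.1, 0])}, "anova_tukey")
        assert out["anova_p"] < 0.01
        assert out["tukey"]["a vs b"] < 0.05
        assert out["tukey"]["a vs c"] > 0.5

    def test_small_groups_skipped(self):
        out = cpl.group_comparison({"a": np.array([1.0]), "b": np.array([1.0, 2.0]),
                                    "c": np.array([3.0, 4.0])}, "mwu_bh")
        assert out["skipped"] == ["a"]
        assert "b vs c" in out["results"]


class TestOneSampleShift:
    def test_shift_detected_with_bonferroni(self):
        rng = np.random.default_rng(5)
        res = cpl.one_sample_shift_tests({"up": rng.normal(1.0, 0.5, 30),
                                          "null": rng.normal(0.0, 0.5, 30)})
        assert res["up"]["p_adjusted"] < 1e-6
        assert res["null"]["p_adjusted"] > 0.05
        assert res["up"]["p_adjusted"] == pytest.approx(min(1.0, 2 * res["up"]["p_raw"]))
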