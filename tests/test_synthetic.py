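"""Synthetic generator: planted structure, determinism, null behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import trace3d as t3
from trace3d import synthetic as syn
from trace3d import matrices as mat


def null_type(name="T", **kw):
    defaults = dict(nucleus_radius_um=4.0, segregation_strength=0.0, radial_bias=0.0,
                    megadomain_strength=0.0, territory_confinement_radius_um=1.8)
    defaults.update(kw)
    return syn.CellTypeParams(name=name, **defaults)


class TestGeneratePanel:
    def test_counts_and_spacing(self):
        p = t3.SimParams(n_chrom=2, loci_per_chrom=3, spacing_bp=2_500_000,
                         n_cells_per_type=1)
        panel = t3.generate_panel(p)
        assert len(panel) == 6
        sub = panel.loci_for_chrom("chr1")
        mids = (sub["start_bp"] + sub["end_bp"]) // 2
        assert set(np.diff(mids)) == {2_500_000}

    def test_single_locus(self):
        p = t3.SimParams(n_chrom=1, loci_per_chrom=1, n_cells_per_type=1)
        assert len(t3.generate_panel(p)) == 1

    def test_deterministic(self):
        p = t3.SimParams(n_chrom=2, loci_per_chrom=5, n_cells_per_type=1,
                         n_se_per_type=2, seed=42)
        pd.testing.assert_frame_equal(t3.generate_panel(p).df, t3.generate_panel(p).df)


class TestPlantCompartments:
    @pytest.mark.parametrize("frac,check", [
        (0.0, "identical"), (1.0, "complementary")])
    def test_extreme_switch_fractions(self, frac, check):
        p = t3.SimParams(n_chrom=2, loci_per_chrom=10, n_cells_per_type=1)
        panel = t3.generate_panel(p)
        truth = t3.plant_compartments(panel, ["x", "y"], block_len_loci=5,
                                      switch_fraction=frac, seed=3)
        lx, ly = truth.labels_for("x"), truth.labels_for("y")
        if check == "identical":
            assert (lx == ly.reindex(lx.index)).all()
        else:
            assert (lx != ly.reindex(lx.index)).all()

    def test_realized_fraction_within_binomial_band(self):
        # 600 loci at p=0.15: binomial 95% band is 0.15 +/- 1.96*sqrt(.15*.85/600)
        p = t3.SimParams(n_chrom=10, loci_per_chrom=60, n_cells_per_type=1)
        panel = t3.generate_panel(p)
        truth = t3.plant_compartments(panel, ["x", "y"], switch_fraction=0.15, seed=3)
        realized = truth.switch_fractions[("x", "y")]
        band = 1.96 * np.sqrt(0.15 * 0.85 / 600)
        assert abs(realized - 0.15) < band + 1e-12
        assert band < 0.03

    def test_block_longer_than_chromosome_rejected(self):
        p = t3.SimParams(n_chrom=1, loci_per_chrom=4, n_cells_per_type=1)
        panel = t3.generate_panel(p)
        with pytest.raises(ValueError):
            t3.plant_compartments(panel, ["x"], block_len_loci=10)

    def test_reference_type_alternating_blocks(self):
        p = t3.SimParams(n_chrom=1, loci_per_chrom=20, n_cells_per_type=1)
        panel = t3.generate_panel(p)
        truth = t3.plant_compartments(panel, ["x"], block_len_loci=10)
        labels = truth.labels_for("x").reindex(panel.df["locus_id"]).to_numpy()
        assert (labels[:10] == "A").all() and (labels[10:] == "B").all()


class TestSimulateCells:
    def test_full_detection_has_every_observation(self):
        p = t3.SimParams(n_chrom=1, loci_per_chrom=5, n_cells_per_type=3,
                         detection_rate=1.0, cell_types=(null_type(),), seed=0)
        _, _, ds, _, _ = t3.simulate(p, with_expression=False)
        assert len(ds.observations) == 3 * 5 * 2

    def test_same_seed_identical_dataset(self):
        p = t3.SimParams(n_chrom=2, loci_per_chrom=8, n_cells_per_type=5, seed=9)
        _, _, ds1, _, _ = t3.simulate(p, with_expression=False)
        _, _, ds2, _, _ = t3.simulate(p, with_expression=False)
        pd.testing.assert_frame_equal(ds1.observations, ds2.observations)
        pd.testing.assert_frame_equal(ds1.cells, ds2.cells)

    def test_null_simulation_is_radially_unbiased(self):
        """lambda=rho=mu=0: A and B loci have equal mean radial position."""
        p = t3.SimParams(n_chrom=2, loci_per_chrom=15, n_cells_per_type=500,
                         cell_types=(null_type(),), seed=21,
                         localization_sigma_um=0.0, detection_rate=1.0)
        panel, truth, ds, _, _ = t3.simulate(p, with_expression=False)
        block = truth.cell_state[("T", "WT")]
        radial = np.linalg.norm(block.positions, axis=-1) / block.nucleus_radius
        mean_a = radial[:, block.labels_a].mean()
        mean_b = radial[:, ~block.labels_a].mean()
        assert abs(mean_a - mean_b) < 0.02

    def test_distance_decay_without_relaxation(self):
        """Backbone chain alone: close genomic pairs are spatially closer."""
        p = t3.SimParams(n_chrom=1, loci_per_chrom=30, n_cells_per_type=200,
                         cell_types=(null_type(),), seed=22)
        panel, truth, ds, _, _ = t3.simulate(p, with_expression=False)
        m = mat.median_distance_matrix(ds, "T", "chr1").matrix.to_numpy()
        g = panel.genomic_distance_matrix("chr1").to_numpy()
        s = p.spacing_bp
        near = np.nanmedian(m[(g >= s) & (g <= 5 * s)])
        far = np.nanmedian(m[g >= 10 * s])
        assert near < far

    def test_radial_bias_orders_a_and_b_monotonically(self):
        """rho > 0 pushes B outward; the A-B radial gap grows with rho."""
        gaps = []
        for rho in (0.0, 0.3, 0.6):
            ct = null_type(radial_bias=rho)
            p = t3.SimParams(n_chrom=2, loci_per_chrom=15, n_cells_per_type=150,
                             cell_types=(ct,), seed=23)
            _, truth, _, _, _ = t3.simulate(p, with_expression=False)
            block = truth.cell_state[("T", "WT")]
            radial = np.linalg.norm(block.positions, axis=-1) / block.nucleus_radius
            gaps.append(radial[:, ~block.labels_a].mean() - radial[:, block.labels_a].mean())
        assert gaps[0] < gaps[1] < gaps[2]
        assert gaps[1] > 0

    def test_ko_attenuation_reduces_segregation(self):
        """delta > 0 shrinks the A-vs-B local-ratio separation vs matched WT."""
        ct = null_type(segregation_strength=0.8, radial_bias=0.3, ko_attenuation=0.8)
        p = t3.SimParams(n_chrom=2, loci_per_chrom=15, n_cells_per_type=80,
                         n_ko_cells_per_type=80, cell_types=(ct,), seed=24)
        panel, truth, ds, _, _ = t3.simulate(p, with_expression=False)
        from trace3d import localenv as env
        labels = {"T": truth.labels_for("T")}
        gaps = {}
        for gt in ("WT", "KO"):
            prof = env.local_env_profile(ds, labels, genotype=gt, min_cells=5)
            v = prof.values.merge(truth.compartment_labels, on=["cell_type", "locus_id"])
            gaps[gt] = (v.loc[v.label == "A", "median_ratio"].median()
                        - v.loc[v.label == "B", "median_ratio"].median())
        assert gaps["KO"] < gaps["WT"]


class TestSimulateExpression:
    def test_no_coupling_equalizes_a_and_b_means(self):
        """beta_AB = beta_R = 0: per-gene mean counts equal across A and B loci."""
        ct = null_type(segregation_strength=0.8, radial_bias=0.3,
                       coupling_ab=0.0, coupling_radial=0.0,
                       base_expression_rate=5.0)
        p = t3.SimParams(n_chrom=2, loci_per_chrom=15, n_cells_per_type=150,
                         cell_types=(ct,), seed=30)
        panel, truth, ds, expr, _ = t3.simulate(p)
        labels = truth.labels_for("T")
        gene_means = expr.counts.mean(axis=1)
        lab = labels.reindex([g[2:] for g in gene_means.index]).to_numpy()
        mean_a = gene_means.to_numpy()[lab == "A"].mean()
        mean_b = gene_means.to_numpy()[lab == "B"].mean()
        # each class mean pools ~15 Poisson(5) genes x 150 cells:
        # sd(diff) ~= sqrt(2 * 5 / 2250) ~= 0.067; allow 3 sigma
        assert abs(mean_a - mean_b) < 0.2

    def test_doubling_base_rate_doubles_totals(self):
        common = dict(segregation_strength=0.0, radial_bias=0.0,
                      coupling_ab=0.0, coupling_radial=0.0)
        totals = []
        for rate in (4.0, 8.0):
            ct = null_type(base_expression_rate=rate, **common)
            p = t3.SimParams(n_chrom=1, loci_per_chrom=20, n_cells_per_type=100,
                             cell_types=(ct,), seed=31)
            _, _, _, expr, _ = t3.simulate(p)
            totals.append(expr.total_umis_per_cell().mean())
        assert totals[1] / totals[0] == pytest.approx(2.0, rel=0.05)

    def test_same_seed_identical_counts(self):
        p = t3.SimParams(n_chrom=1, loci_per_chrom=10, n_cells_per_type=20, seed=32)
        _, _, _, e1, _ = t3.simulate(p)
        _, _, _, e2, _ = t3.simulate(p)
        pd.testing.assert_frame_equal(e1.counts, e2.counts)


class TestGroundTruthSidecar:
    def test_round_trip(self, tmp_path, small_sim):
        truth = small_sim["truth"]
        t3.write_ground_truth(truth, tmp_path)
        back = t3.read_ground_truth(tmp_path)
        pd.testing.assert_frame_equal(truth.compartment_labels, back.compartment_labels)
        assert back.params == truth.params
        assert back.switch_fractions == pytest.approx(truth.switch_fractions)


class TestCrossTypeStructure:
    def test_larger_nucleus_larger_long_range_distances(self):
        """With segregation and megadomain strengths fixed, the cell type with
        the larger nucleus/territory shows larger median distances for
        locus pairs separated by more than 10 Mb."""
        common = dict(segregation_strength=0.4, radial_bias=0.2,
                      megadomain_strength=0.0)
        cts = (syn.CellTypeParams(name="big", nucleus_radius_um=5.0,
                                  territory_confinement_radius_um=2.0, **common),
               syn.CellTypeParams(name="small", nucleus_radius_um=3.5,
                                  territory_confinement_radius_um=1.5, **common))
        p = t3.SimParams(n_chrom=2, loci_per_chrom=20, n_cells_per_type=80,
                         cell_types=cts, seed=40)
        panel, truth, ds, _, _ = t3.simulate(p, with_expression=False)
        g = panel.genomic_distance_matrix("chr1").to_numpy()
        far = g >= 10_000_000
        med = {}
        for name in ("big", "small"):
            m = mat.median_distance_matrix(ds, name, "chr1").matrix.to_numpy()
            med[name] = np.nanmedian(m[far])
        assert med["big"] > med["small"]

    def test_planted_se_effect_shows_in_specific_heatmap(self):
        """Super-enhancer loci are planted active (A) only in their origin
        type, so the specific association heatmap has negative off-diagonal
        entries for every reference type (the ratio drops elsewhere)."""
        from trace3d import localenv as env
        p = t3.SimParams(n_chrom=2, loci_per_chrom=20, n_cells_per_type=60,
                         n_se_per_type=6, seed=41)
        panel, truth, ds, _, _ = t3.simulate(p, with_expression=False)
        labels = {ct: truth.labels_for(ct) for ct in ("neuron", "glia")}
        prof = env.local_env_profile(ds, labels, min_cells=5, genotype="WT")
        spec_hm, _ = env.se_association(prof, panel, seed=1)
        for ref in spec_hm.matrix.index:
            for tgt in spec_hm.matrix.columns:
                if ref != tgt:
                    assert spec_hm.matrix.loc[ref, tgt] < 0
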