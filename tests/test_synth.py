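"""Ground-truth generator: determinism, calibration, geometry, spillover."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from domemap.synth import (
    SimConfig,
    apply_spillover,
    default_spillover,
    default_zone_geometry,
    simulate_coloc_raster,
    simulate_imc_roi,
    simulate_spot_sample,
    simulate_suspension_pair,
)
from domemap.synth.geometry import exclusive_zone_polygons, zone_of_points


class TestDeterminism:
    def test_suspension_identical_for_same_seed(self, small_suspension_config):
        ev1, tr1 = simulate_suspension_pair(small_suspension_config, 2)
        ev2, tr2 = simulate_suspension_pair(small_suspension_config, 2)
        pd.testing.assert_frame_equal(ev1, ev2)
        pd.testing.assert_frame_equal(tr1, tr2)

    def test_imc_identical_for_same_seed(self, sim_config):
        c1, _, t1 = simulate_imc_roi(sim_config)
        c2, _, t2 = simulate_imc_roi(sim_config)
        pd.testing.assert_frame_equal(c1, c2)

    def test_spots_identical_for_same_seed(self, sim_config):
        t1, _ = simulate_spot_sample(sim_config)
        t2, _ = simulate_spot_sample(sim_config)
        np.testing.assert_array_equal(t1.counts, t2.counts)

    def test_different_seeds_differ(self):
        t1, _ = simulate_spot_sample(SimConfig(seed=1))
        t2, _ = simulate_spot_sample(SimConfig(seed=2))
        assert (t1.counts != t2.counts).any()


class TestSuspension:
    def test_no_donors_gives_empty_tables(self, sim_config):
        ev, tr = simulate_suspension_pair(sim_config, 0)
        assert ev.empty and tr.empty

    def test_bad_proportions_rejected(self, sim_config):
        sim_config.suspension.galt_proportions = {"Naive": 0.5, "Mem": 0.2}
        with pytest.raises(ValueError, match="sum"):
            simulate_suspension_pair(sim_config, 1)

    def test_realized_fractions_concentrate(self):
        cfg = SimConfig(seed=3)
        cfg.suspension.n_events_per_sample = 50_000
        cfg.suspension.donor_concentration = 1e9  # isolate multinomial noise
        ev, tr = simulate_suspension_pair(cfg, 1)
        galt = tr[tr.compartment == "GALT"]
        frac = (galt.true_subset == "DN2/3").mean()
        assert frac == pytest.approx(
            cfg.suspension.galt_proportions["DN2/3"], abs=0.01)

    def test_galt_enriched_in_configured_subsets(self, small_suspension_config):
        ev, tr = simulate_suspension_pair(small_suspension_config, 5)
        frac = (tr.groupby(["compartment"])["true_subset"]
                .value_counts(normalize=True).unstack())
        for subset in ("DN2/3", "GC", "PB/PC"):
            assert frac.loc["GALT", subset] > frac.loc["PBMC", subset]


class TestGeometry:
    def test_cells_inside_their_zone_polygon(self, imc_rois):
        cells, zones, truth = imc_rois
        assigned = zone_of_points(cells[["x", "y"]].to_numpy(), zones)
        np.testing.assert_array_equal(assigned, truth["true_zone"].to_numpy())

    def test_fae_cells_within_fae_polygon(self, imc_rois):
        cells, zones, truth = imc_rois
        fae = cells[(truth["true_zone"] == "FAE").to_numpy()]
        for _, row in fae.head(50).iterrows():
            assert zones["FAE"].covers(Point(row.x, row.y))

    def test_exclusive_polygons_carve_out_nested_zones(self):
        zones = default_zone_geometry()
        excl = exclusive_zone_polygons(zones)
        # the mantle becomes an annulus: GC centre no longer covered
        gc_centre = zones["GC"].centroid
        assert zones["mantle"].covers(gc_centre)
        assert not excl["mantle"].covers(gc_centre)

    def test_dn2_shallower_than_naive_by_construction(self, imc_rois):
        cells, zones, truth = imc_rois
        epi_y = cells[(truth["true_type"] == "Epithelial").to_numpy()]["y"]
        depth = cells["y"] - epi_y.max()
        dn2 = depth[(truth["true_type"] == "DN2").to_numpy()]
        naive = depth[(truth["true_type"] == "Naive").to_numpy()]
        assert dn2.median() < naive.median()


class TestSpillover:
    def test_identity_matrix_is_noop(self):
        X = np.random.default_rng(0).uniform(0, 50, (20, 4))
        np.testing.assert_array_equal(apply_spillover(X, np.eye(4)), X)

    def test_two_channel_leak(self):
        S = np.array([[1.0, 0.1], [0.0, 1.0]])
        np.testing.assert_allclose(apply_spillover(np.array([10.0, 0.0]), S),
                                   [10.0, 1.0])

    def test_zero_in_zero_out(self):
        S = default_spillover().to_numpy()
        out = apply_spillover(np.zeros(S.shape[0]), S)
        np.testing.assert_array_equal(out, 0.0)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            apply_spillover(np.ones(2), np.array([[2.0, 0], [0, 1.0]]))
        with pytest.raises(ValueError):
            apply_spillover(np.ones(3), np.eye(2))


class TestSpots:
    def test_lattice_covers_all_regions(self, spot_sample):
        table, truth = spot_sample
        regions = set(table.spots["region"])
        assert {"SED", "Follicle", "none"} <= regions

    def test_dnase1l3_fold_change_recovered(self, spot_sample):
        table, _ = spot_sample
        gi = table.gene_index("DNASE1L3")
        reg = table.spots["region"].to_numpy()
        ratio = (table.counts[reg == "SED", gi].mean()
                 / table.counts[reg == "Follicle", gi].mean())
        assert 3.2 <= ratio <= 4.8

    def test_null_gene_flat_across_regions(self, spot_sample):
        table, _ = spot_sample
        reg = table.spots["region"].to_numpy()
        ratios = []
        for g in [g for g in table.genes if g.startswith("NULL")][:50]:
            gi = table.gene_index(g)
            a = table.counts[reg == "SED", gi].mean()
            b = table.counts[reg == "Follicle", gi].mean()
            if a > 0 and b > 0:
                ratios.append(np.log2(a / b))
        assert abs(np.median(ratios)) < 0.3

    def test_truth_records_every_spot_once(self, spot_sample):
        table, truth = spot_sample
        assert len(truth) == table.n_spots
        assert truth["spot_id"].is_unique


class TestColocRaster:
    @pytest.mark.parametrize("requested", [0.0, 0.3, 1.0])
    def test_ground_truth_matches_request(self, sim_config, requested):
        raster, truth = simulate_coloc_raster(sim_config, requested)
        assert truth["overlap_fraction"] == pytest.approx(requested, abs=0.02)

    def test_disjoint_at_zero(self, sim_config):
        _, truth = simulate_coloc_raster(sim_config, 0.0)
        assert not (truth["signal_mask"] & truth["reference_mask"]).any()

    def test_fully_contained_at_one(self, sim_config):
        _, truth = simulate_coloc_raster(sim_config, 1.0)
        assert (truth["signal_mask"] <= truth["reference_mask"]).all()

    def test_out_of_range_request_rejected(self, sim_config):
        with pytest.raises(ValueError):
            simulate_coloc_raster(sim_config, 1.5)


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path, sim_config):
        path = tmp_path / "sim.yaml"
        sim_config.raster.shape = (128, 128)
        sim_config.to_yaml(path)
        loaded = SimConfig.from_yaml(path)
        assert loaded == sim_config

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            SimConfig.from_dict({"seed": 1, "bogus": {}})
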