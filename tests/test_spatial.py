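"""Spatial statistics: distances, zones, positivity, contrasts, rasters."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from domemap.spatial import (
    coloc_fraction,
    distance_ordering_report,
    expression_contrast,
    nearest_epithelial_distance,
    positivity_classify,
    segment_objects,
    zone_assign,
)
from domemap.synth import SimConfig, simulate_coloc_raster
from domemap.synth.raster import ColocRaster


def cells_frame(coords, lineage, roi="R1", **extra):
    df = pd.DataFrame(coords, columns=["x", "y"])
    df["lineage"] = lineage
    df["roi"] = roi
    for k, v in extra.items():
        df[k] = v
    return df


class TestNearestEpithelialDistance:
    def test_three_four_five_triangle(self):
        cells = cells_frame([(0, 0), (3, 4)], ["Epithelial", "B"])
        d = nearest_epithelial_distance(cells)
        assert d.iloc[1] == pytest.approx(5.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 500, size=(1000, 2))
        lineage = np.where(rng.random(1000) < 0.1, "Epithelial", "B")
        cells = cells_frame(coords, lineage)
        d = nearest_epithelial_distance(cells).to_numpy()
        epi = coords[lineage == "Epithelial"]
        for i in rng.choice(1000, 200, replace=False):
            dists = np.linalg.norm(epi - coords[i], axis=1)
            if lineage[i] == "Epithelial":
                expected = np.sort(dists)[1]
            else:
                expected = dists.min()
            assert d[i] == expected

    def test_extra_epithelial_cell_never_increases_distance(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 100, size=(50, 2))
        lineage = ["Epithelial"] * 5 + ["B"] * 45
        cells = cells_frame(coords, lineage)
        before = nearest_epithelial_distance(cells)
        extra = pd.concat([cells, cells_frame([(50, 50)], ["Epithelial"])],
                          ignore_index=True)
        after = nearest_epithelial_distance(extra).iloc[:50]
        assert (after.to_numpy() <= before.to_numpy() + 1e-12).all()

    def test_roi_without_epithelium_is_nan(self):
        cells = cells_frame([(0, 0), (1, 1)], ["B", "T"])
        with pytest.warns(UserWarning, match="no epithelial"):
            d = nearest_epithelial_distance(cells)
        assert d.isna().all()

    def test_distances_do_not_cross_rois(self):
        cells = pd.concat([
            cells_frame([(0, 0), (0, 10)], ["Epithelial", "B"], roi="R1"),
            cells_frame([(0, 1000), (0, 990)], ["Epithelial", "B"], roi="R2"),
        ], ignore_index=True)
        d = nearest_epithelial_distance(cells)
        assert d.iloc[1] == pytest.approx(10.0)
        assert d.iloc[3] == pytest.approx(10.0)


class TestZoneAssign:
    zones = {"outer": box(0, 0, 100, 100), "inner": box(40, 40, 60, 60)}

    def test_smallest_containing_polygon_wins(self):
        cells = cells_frame([(50, 50), (10, 10), (200, 200)], ["B"] * 3)
        z = zone_assign(cells, self.zones)
        assert list(z) == ["inner", "outer", "other"]

    def test_boundary_inclusive(self):
        cells = cells_frame([(0, 0)], ["B"])
        assert zone_assign(cells, self.zones).iloc[0] == "outer"

    def test_translation_equivariance(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(-20, 120, size=(100, 2))
        cells = cells_frame(coords, ["B"] * 100)
        base = zone_assign(cells, self.zones)
        shift = np.array([37.5, -12.25])
        moved = cells_frame(coords + shift, ["B"] * 100)
        zones_moved = {
            name: box(*(np.array(poly.bounds) + np.tile(shift, 2)))
            for name, poly in self.zones.items()}
        np.testing.assert_array_equal(base.to_numpy(),
                                      zone_assign(moved, zones_moved).to_numpy())


class TestPositivity:
    def test_bimodal_recovery(self):
        rng = np.random.default_rng(3)
        truth = rng.random(2000) < 0.3
        intensity = np.where(truth, rng.normal(3.2, 0.4, 2000),
                             rng.normal(0.2, 0.4, 2000))
        cells = cells_frame(np.zeros((2000, 2)), ["B"] * 2000,
                            marker=intensity)
        flags = positivity_classify(cells, "marker", method="mixture")
        assert (flags.to_numpy() != truth).mean() < 0.02

    def test_all_zero_channel_negative(self):
        cells = cells_frame(np.zeros((10, 2)), ["B"] * 10, marker=0.0)
        assert not positivity_classify(cells, "marker", "mixture").any()

    def test_fixed_threshold_boundary_positive(self):
        cells = cells_frame(np.zeros((3, 2)), ["B"] * 3,
                            marker=[0.5, 1.0, 1.5])
        flags = positivity_classify(cells, "marker", "fixed", threshold=1.0)
        assert list(flags) == [False, True, True]


class TestExpressionContrast:
    def test_roi_level_paired_detection(self):
        rng = np.random.default_rng(4)
        frames = []
        for r in range(14):
            for grp, mean in (("SED", 4.0), ("non-SED", 1.0)):
                n = 20
                frames.append(cells_frame(
                    np.zeros((n, 2)), ["MacDC"] * n, roi=f"R{r}",
                    group=grp, value=rng.normal(mean, 0.5, n)))
        cells = pd.concat(frames, ignore_index=True)
        rep = expression_contrast(cells, "group", "value", unit="ROI")
        assert rep.test.p_value < 0.05
        assert rep.group_means["SED"] > rep.group_means["non-SED"]
        assert rep.unit == "ROI"

    def test_identical_groups_degenerate(self):
        cells = pd.concat([
            cells_frame(np.zeros((5, 2)), ["B"] * 5, group="a", value=1.0),
            cells_frame(np.zeros((5, 2)), ["B"] * 5, group="b", value=1.0),
        ], ignore_index=True)
        rep = expression_contrast(cells, "group", "value", unit="cell")
        assert rep.test.degenerate and rep.test.p_value == 1.0

    def test_units_agree_on_balanced_data(self):
        frames = []
        for r in range(4):
            for grp, val in (("a", 2.0), ("b", 5.0)):
                frames.append(cells_frame(np.zeros((10, 2)), ["B"] * 10,
                                          roi=f"R{r}", group=grp, value=val))
        cells = pd.concat(frames, ignore_index=True)
        roi = expression_contrast(cells, "group", "value", unit="ROI")
        cell = expression_contrast(cells, "group", "value", unit="cell")
        assert roi.group_means == cell.group_means

    def test_more_than_two_levels_rejected(self):
        cells = cells_frame(np.zeros((6, 2)), ["B"] * 6,
                            group=["a", "b", "c"] * 2, value=1.0)
        with pytest.raises(ValueError, match="2 levels"):
            expression_contrast(cells, "group", "value")


class TestDistanceOrdering:
    def test_focus_subset_ranked_and_tested(self, imc_rois):
        cells, zones, truth = imc_rois
        cells = cells.assign(
            lineage=truth["true_lineage"].to_numpy(),
            b_subset=truth["true_type"].to_numpy())
        cells["dist_epithelium_um"] = nearest_epithelial_distance(cells)
        b = cells[cells["lineage"] == "B"]
        med, tests = distance_ordering_report(b)
        assert (med.idxmin(axis=1) == "DN2").all()
        assert (tests["p_value"] < 0.05).all()
        assert "IEDN" not in med.columns


class TestSegmentation:
    def make_raster(self, arr):
        return ColocRaster(channels={"c": np.asarray(arr, dtype=float)})

    def test_two_disjoint_blobs(self):
        img = np.zeros((20, 20))
        img[2:5, 2:5] = 10
        img[10:14, 10:14] = 10
        labels, table = segment_objects(self.make_raster(img), "c")
        assert len(table) == 2

    def test_corner_touching_connectivity(self):
        img = np.zeros((6, 6))
        img[1:3, 1:3] = 10
        img[3:5, 3:5] = 10   # touches at one corner (2,2)-(3,3)
        _, t8 = segment_objects(self.make_raster(img), "c", connectivity=8)
        _, t4 = segment_objects(self.make_raster(img), "c", connectivity=4)
        assert len(t8) == 1 and len(t4) == 2

    def test_empty_raster_zero_objects(self):
        labels, table = segment_objects(self.make_raster(np.zeros((8, 8))), "c")
        assert table.empty and labels.max() == 0

    def test_min_diameter_filter(self):
        img = np.zeros((20, 20))
        img[1, 1] = 10                  # single pixel
        img[10:16, 10:16] = 10          # 6x6 block
        _, table = segment_objects(self.make_raster(img), "c",
                                   min_diameter_px=3)
        assert len(table) == 1


class TestColocFraction:
    def test_generator_round_trip(self, sim_config):
        raster, truth = simulate_coloc_raster(sim_config, 0.3)
        # recompute from raw pixels (ignore the stored masks)
        bare = ColocRaster(channels=dict(raster.channels))
        frac = coloc_fraction(bare, "signal", "reference")
        assert frac == pytest.approx(truth["overlap_fraction"], abs=0.02)

    def test_disjoint_and_contained_extremes(self, sim_config):
        for requested, expected in ((0.0, 0.0), (1.0, 1.0)):
            raster, _ = simulate_coloc_raster(sim_config, requested)
            frac = coloc_fraction(raster, "signal", "reference")
            assert frac == pytest.approx(expected, abs=0.02)

    def test_no_signal_yields_nan(self):
        raster = ColocRaster(channels={"s": np.zeros((10, 10)),
                                       "r": np.ones((10, 10))})
        with pytest.warns(UserWarning, match="undefined"):
            frac = coloc_fraction(raster, "s", np.ones((10, 10), bool),
                                  signal_threshold=0.5)
        assert np.isnan(frac)

    def test_invariant_to_signal_free_channels(self, sim_config):
        raster, _ = simulate_coloc_raster(sim_config, 0.3)
        frac = coloc_fraction(raster, "signal", "reference")
        raster.channels["empty"] = np.zeros(raster.shape)
        assert coloc_fraction(raster, "signal", "reference") == frac
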