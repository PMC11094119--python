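"""Segmented-image stage: QC, compensation, gating, propagation, batches."""

import numpy as np
import pandas as pd
import pytest

from domemap.imc import (
    GatingScheme,
    compensate_spillover,
    cluster_and_classify_b_cells,
    gate_cells,
    integrate_batches,
    propagate_labels,
    qc_filter,
    run_imc_stage,
)
from domemap.stats import arcsinh_transform
from domemap.synth import apply_spillover, default_spillover
from domemap.synth.phenotypes import IMC_MARKERS


def toy_cells(areas, dna=10.0):
    df = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(len(areas))],
        "roi": "R1",
        "area_px": areas,
        "DNA1": dna, "DNA2": dna,
    })
    return df


class TestQcFilter:
    def test_size_threshold_inclusive(self):
        kept, log = qc_filter(toy_cells([5, 11, 20]), min_area_px=11,
                              dna_percentile=0.0, dna_floor=0.0)
        assert list(kept["area_px"]) == [11, 20]

    def test_disabled_qc_is_identity(self):
        cells = toy_cells([1, 2, 3])
        kept, _ = qc_filter(cells, min_area_px=0, dna_percentile=0.0,
                            dna_floor=0.0)
        assert len(kept) == 3

    def test_zero_dna_removed_despite_size(self):
        cells = toy_cells([50, 50])
        cells.loc[1, ["DNA1", "DNA2"]] = 0.0
        kept, log = qc_filter(cells, min_area_px=11)
        assert list(kept["cell_id"]) == ["c0"]
        assert int(log["low_dna"].sum()) == 1


class TestCompensation:
    def test_identity_matrix_noop(self):
        X = np.random.default_rng(0).uniform(0, 100, (50, 3))
        np.testing.assert_allclose(compensate_spillover(X, np.eye(3)), X)

    def test_exact_two_channel_solve(self):
        S = np.array([[1.0, 0.1], [0.0, 1.0]])
        out = compensate_spillover(np.array([[10.0, 1.0]]), S)
        np.testing.assert_allclose(out, [[10.0, 0.0]], atol=1e-12)

    def test_never_negative_under_noise(self):
        S = np.array([[1.0, 0.2], [0.0, 1.0]])
        obs = np.array([[10.0, 1.0], [5.0, 0.5 ]])
        obs[:, 1] -= 0.9  # drive the pure-spillover channel negative-going
        out = compensate_spillover(obs, S)
        assert (out >= 0).all()

    def test_round_trip_with_forward_model(self):
        rng = np.random.default_rng(3)
        S = default_spillover().to_numpy()
        X = rng.uniform(0, 200, (100, S.shape[0]))
        back = compensate_spillover(apply_spillover(X, S), S)
        np.testing.assert_allclose(back, X, atol=1e-8)

    def test_ill_conditioned_rejected(self):
        S = np.ones((3, 3))
        np.fill_diagonal(S, 1.0)
        with pytest.raises(ValueError, match="ill-conditioned"):
            compensate_spillover(np.ones((2, 3)), S)


class TestGating:
    @pytest.fixture
    def gated_setup(self, imc_rois):
        cells, zones, truth = imc_rois
        comp = compensate_spillover(cells[list(IMC_MARKERS)],
                                    default_spillover())
        transformed = pd.DataFrame(
            arcsinh_transform(comp.to_numpy(), 5.0),
            index=cells.index, columns=list(IMC_MARKERS))
        labels = gate_cells(cells, transformed, seed=0)
        return cells, truth, transformed, labels

    def test_pure_b_profile_gated_b(self, gated_setup):
        cells, truth, transformed, labels = gated_setup
        scheme = GatingScheme()
        gate_ch = list(scheme.channels)
        naive = (truth["true_type"] == "Naive").to_numpy()
        clean = naive & (transformed["CD20"] > 1.5).to_numpy()
        for ch in gate_ch:
            if ch != "CD20":
                clean &= (transformed[ch] < 0.8).to_numpy()
        assert clean.sum() > 50
        assert (labels[clean] == "B").all()

    def test_bt_doublets_never_gate_labelled(self, gated_setup):
        cells, truth, transformed, labels = gated_setup
        bt = ((transformed["CD20"] > 1.5) & (transformed["CD3"] > 1.5)).to_numpy()
        assert bt.sum() > 10
        assert (labels[bt] == "unassigned").all()

    def test_all_below_threshold_unassigned(self, gated_setup):
        cells, truth, transformed, labels = gated_setup
        dim = (transformed[list(GatingScheme().channels)] < 0.5).all(axis=1)
        assert (labels[dim.to_numpy()] == "unassigned").all()

    def test_gate_order_irrelevant(self, gated_setup):
        cells, truth, transformed, labels = gated_setup
        scheme = GatingScheme()
        reordered = GatingScheme(gates=tuple(reversed(scheme.gates)))
        again = gate_cells(cells, transformed, scheme=reordered, seed=0)
        pd.testing.assert_series_equal(labels, again)

    def test_missing_channel_rejected(self, gated_setup):
        cells, truth, transformed, _ = gated_setup
        with pytest.raises(ValueError, match="missing"):
            gate_cells(cells, transformed.drop(columns=["CD3"]), seed=0)


class TestPropagation:
    def test_gated_labels_never_overwritten_and_split_respected(self, imc_rois):
        cells, zones, truth = imc_rois
        comp = compensate_spillover(cells[list(IMC_MARKERS)],
                                    default_spillover())
        transformed = pd.DataFrame(
            arcsinh_transform(comp.to_numpy(), 5.0),
            index=cells.index, columns=list(IMC_MARKERS))
        gated = gate_cells(cells, transformed, seed=0)
        out, report = propagate_labels(transformed, gated, split=0.7, seed=0)
        keep = gated != "unassigned"
        pd.testing.assert_series_equal(out[keep], gated[keep])
        assert report.split == 0.7
        assert (out != "unassigned").all()
        assert report.accuracy >= 0.99

    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        tf = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        gated = pd.Series(["X"] * 40 + ["unassigned"] * 10)
        with pytest.raises(ValueError, match=">= 2"):
            propagate_labels(tf, gated)

    def test_centroid_profile_recovers_class(self):
        rng = np.random.default_rng(1)
        centres = {"A": np.zeros(4), "B": np.full(4, 3.0)}
        frames, labels = [], []
        for name, c in centres.items():
            frames.append(c + rng.normal(0, 0.3, size=(200, 4)))
            labels += [name] * 200
        X = pd.DataFrame(np.vstack(frames), columns=list("wxyz"))
        gated = pd.Series(labels + ["unassigned"],
                          index=range(401))
        X.loc[400] = centres["B"]
        out, _ = propagate_labels(X, gated, seed=0)
        assert out.iloc[400] == "B"


class TestBatchIntegration:
    def test_duplicated_batches_uncorrected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(150, 6))
        XX = np.vstack([X, X])
        batches = np.array(["a"] * 150 + ["b"] * 150)
        Z = integrate_batches(XX, batches, seed=0)
        assert np.abs(Z[:150] - Z[150:]).max() < 1e-6

    def test_constant_offset_removed(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(1)
        base = np.vstack([rng.normal(0, 1, size=(150, 6)),
                          rng.normal(4, 1, size=(150, 6))])
        delta = 2.0
        X = np.vstack([base, base + delta])
        batches = np.array(["a"] * 300 + ["b"] * 300)
        Z = integrate_batches(X, batches, seed=0)
        gap = np.linalg.norm(Z[:300].mean(axis=0) - Z[300:].mean(axis=0))
        mu, sd = X.mean(0), X.std(0)
        Z0 = PCA(6, random_state=0).fit_transform((X - mu) / sd)
        gap0 = np.linalg.norm(Z0[:300].mean(axis=0) - Z0[300:].mean(axis=0))
        assert gap < 0.1 * gap0

    def test_large_disjoint_offset_never_made_worse(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(1)
        base = np.vstack([rng.normal(0, 1, size=(150, 6)),
                          rng.normal(4, 1, size=(150, 6))])
        X = np.vstack([base, base + 3.0])   # batches fully separated
        batches = np.array(["a"] * 300 + ["b"] * 300)
        Z = integrate_batches(X, batches, seed=0)
        gap = np.linalg.norm(Z[:300].mean(axis=0) - Z[300:].mean(axis=0))
        mu, sd = X.mean(0), X.std(0)
        Z0 = PCA(6, random_state=0).fit_transform((X - mu) / sd)
        gap0 = np.linalg.norm(Z0[:300].mean(axis=0) - Z0[300:].mean(axis=0))
        assert gap <= gap0 * 1.06

    def test_distinct_populations_stay_separable(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(2)
        shared_a = rng.normal(0, 0.5, size=(150, 6))
        shared_b = rng.normal(0, 0.5, size=(150, 6)) + 0.5
        only_a = rng.normal(5, 0.5, size=(100, 6))
        only_b = rng.normal(-5, 0.5, size=(100, 6))
        X = np.vstack([shared_a, only_a, shared_b, only_b])
        batches = np.array(["a"] * 250 + ["b"] * 250)
        subsets = np.array(["shared"] * 150 + ["ua"] * 100
                           + ["shared"] * 150 + ["ub"] * 100)
        Z = integrate_batches(X, batches, seed=0)
        assert silhouette_score(Z, subsets) > 0.4

    def test_single_batch_notice(self):
        X = np.random.default_rng(0).normal(size=(60, 4))
        with pytest.warns(UserWarning, match="single batch"):
            integrate_batches(X, np.array(["a"] * 60), seed=0)


class TestEndToEnd:
    def test_lineage_and_subset_recovery(self, imc_rois):
        cells, zones, truth = imc_rois
        res = run_imc_stage(cells, default_spillover(), IMC_MARKERS, seed=7)
        lineage_truth = truth.loc[res.cells["cell_id"],
                                  "true_lineage"].to_numpy()
        assert (res.lineage.to_numpy() == lineage_truth).mean() >= 0.95
        subset_truth = truth.loc[
            res.cells.loc[res.b_subset.index, "cell_id"],
            "true_type"].to_numpy()
        assert (res.b_subset.to_numpy() == subset_truth).mean() >= 0.85

    def test_k1_single_label(self, imc_rois):
        cells, zones, truth = imc_rois
        res = run_imc_stage(cells, default_spillover(), IMC_MARKERS, seed=7)
        b_t = res.transformed.loc[res.b_subset.index]
        labels, coords, med = cluster_and_classify_b_cells(
            res.b_embedding, b_t, k=1, seed=0)
        assert labels.nunique() == 1
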