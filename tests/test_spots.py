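"""Spot transcriptomics: preprocessing, graph, Potts sampler, DE, correlations."""

import numpy as np
import pandas as pd
import pytest

from domemap.spots import (
    build_spot_graph,
    gene_correlation_matrix,
    log_normalise,
    potts_cluster,
    preprocess_spots,
    region_de,
    select_hvgs,
    select_lymphoid_cluster,
    subcluster_lymphoid,
    tune_q,
    _elbow,
)
from domemap.synth import (
    SimConfig,
    simulate_feature_lattice,
    simulate_program_lattice,
    simulate_spot_sample,
)


class TestPreprocess:
    def test_constant_gene_never_hvg(self):
        rng = np.random.default_rng(0)
        ln = rng.normal(1, 0.3, size=(50, 10))
        ln[:, 3] = 2.0
        hvg = select_hvgs(ln, 5)
        assert 3 not in hvg

    def test_pc_variances_non_increasing(self, spot_sample):
        table, _ = spot_sample
        pre = preprocess_spots(table, n_hvg=2000, n_pcs=15)
        variances = pre.pcs.var(axis=0)
        assert np.all(np.diff(variances) <= 1e-9)

    def test_zero_count_spot_removed(self, spot_sample):
        table, _ = spot_sample
        table2 = table.subset(np.ones(table.n_spots, dtype=bool))
        table2.counts[5] = 0
        with pytest.warns(UserWarning, match="zero-count"):
            pre = preprocess_spots(table2)
        assert 5 not in pre.kept_spots


class TestSpotGraph:
    def test_hex_interior_degree_six(self, spot_sample):
        table, _ = spot_sample
        g = build_spot_graph(table.spots, "hex")
        degs = g.degrees
        assert degs.max() == 6
        interior = degs == 6
        assert interior.mean() > 0.7

    def test_square_corner_degree_two(self):
        spots = pd.DataFrame([(r, c) for r in range(4) for c in range(4)],
                             columns=["row", "col"])
        g = build_spot_graph(spots, "square")
        corner = spots.index[(spots.row == 0) & (spots.col == 0)][0]
        assert len(g.neighbours[corner]) == 2

    def test_symmetric_adjacency(self, spot_sample):
        table, _ = spot_sample
        g = build_spot_graph(table.spots, "hex")
        for i, nb in enumerate(g.neighbours):
            for j in nb:
                assert i in g.neighbours[j]

    def test_duplicate_coordinates_rejected(self):
        spots = pd.DataFrame({"row": [0, 0], "col": [1, 1]})
        with pytest.raises(ValueError, match="duplicate"):
            build_spot_graph(spots, "square")


class TestPottsCluster:
    def test_q1_trivial(self):
        X, z, spots = simulate_feature_lattice(seed=0, n_rows=10, n_cols=10)
        g = build_spot_graph(spots, "hex")
        st = potts_cluster(X, g, q=1, seed=0)
        assert (st.labels == 0).all()

    def test_q_larger_than_spots_rejected(self):
        X, z, spots = simulate_feature_lattice(seed=0, n_rows=4, n_cols=4)
        g = build_spot_graph(spots, "hex")
        with pytest.raises(ValueError):
            potts_cluster(X, g, q=100, seed=0)

    def test_deterministic_given_seed(self):
        X, z, spots = simulate_feature_lattice(seed=1, n_rows=12, n_cols=12)
        g = build_spot_graph(spots, "hex")
        a = potts_cluster(X, g, 3, iterations=80, burn_in=40, seed=5)
        b = potts_cluster(X, g, 3, iterations=80, burn_in=40, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_smoothing_never_reduces_neighbour_agreement(self):
        X, z, spots = simulate_feature_lattice(seed=2, n_rows=20, n_cols=20,
                                               separation=1.5)
        g = build_spot_graph(spots, "hex")
        agreements = []
        for gamma in (0.0, 1.0, 2.0, 4.0):
            st = potts_cluster(X, g, 3, gamma=gamma, iterations=200,
                               burn_in=100, seed=2)
            agree = np.mean([
                np.mean(st.labels[nb] == st.labels[i])
                for i, nb in enumerate(g.neighbours) if len(nb)])
            agreements.append(agree)
        assert np.all(np.diff(agreements) >= -0.02)


class TestTuneQ:
    def test_flat_or_rising_curve_suggests_smallest_q(self):
        qs = np.arange(2, 10)
        rising = np.linspace(100.0, 140.0, len(qs))
        assert _elbow(qs, rising) == 2
        flat = np.full(len(qs), 50.0)
        assert _elbow(qs, flat) == 2

    def test_sharp_elbow_detected(self):
        qs = np.arange(2, 10)
        curve = np.array([100.0, 80, 60, 40, 39, 38.5, 38, 37.8])
        assert _elbow(qs, curve) == 5

    def test_requires_three_qs(self, spot_sample):
        table, _ = spot_sample
        pre = preprocess_spots(table)
        g = build_spot_graph(table.spots, "hex")
        with pytest.raises(ValueError):
            tune_q(pre.pcs, g, q_range=[2, 3])


class TestLymphoidSelection:
    def test_follicle_cluster_selected(self, spot_sample):
        table, _ = spot_sample
        pre = preprocess_spots(table)
        labels = (table.spots["region"].to_numpy() == "Follicle").astype(int)
        cid, mask, score = select_lymphoid_cluster(labels, pre.lognorm,
                                                   pre.genes)
        assert cid == 1

    def test_tie_flagged(self):
        rng = np.random.default_rng(0)
        ln = rng.normal(1, 0.01, size=(60, 4))
        labels = np.repeat([0, 1, 2], 20)
        with pytest.raises(ValueError, match="ambiguous"):
            select_lymphoid_cluster(labels, ln, ["MS4A1", "IGHD", "IGHM",
                                                 "CD19"])

    def test_missing_marker_is_config_error(self):
        ln = np.ones((30, 2))
        with pytest.raises(ValueError, match="marker"):
            select_lymphoid_cluster(np.zeros(30, int), ln, ["g1", "g2"])


class TestSubcluster:
    def test_batch_corrected_zone_recovery(self):
        from sklearn.metrics import adjusted_rand_score as ari

        ta, za = simulate_program_lattice(seed=3, n_zones=5, layout_seed=3)
        tb, zb = simulate_program_lattice(seed=103, n_zones=5, layout_seed=3,
                                          batch_sdlog=0.4, sample="M")
        labels, corrected, batch = subcluster_lymphoid(
            {"A": log_normalise(ta.counts), "B": log_normalise(tb.counts)},
            ta.genes, n_subclusters=5, seed=3)
        zones = np.concatenate([za, zb])
        assert ari(zones, labels) >= 0.8
        assert abs(ari(batch, labels)) <= 0.1

    def test_single_sample_notice(self):
        ta, _ = simulate_program_lattice(seed=4, n_zones=3, n_rows=12,
                                         n_cols=12)
        with pytest.warns(UserWarning, match="single sample"):
            subcluster_lymphoid({"A": log_normalise(ta.counts)}, ta.genes,
                                n_subclusters=3, seed=0)


class TestRegionDE:
    def test_paper_thresholds_and_top_gene(self, spot_sample):
        table, _ = spot_sample
        de = region_de(table, logfc_min=0.25, min_fraction=0.10)
        sed_up = de[de["passed_filters"] & (de["logfc"] > 0)]
        assert sed_up.iloc[0]["gene"] == "DNASE1L3"
        flagged = de[~de["passed_filters"]]
        assert flagged["p_value"].isna().all()   # flagged, not dropped
        assert len(de) == len(table.genes)

    def test_swapping_regions_negates_logfc(self, spot_sample):
        table, _ = spot_sample
        ab = region_de(table, "SED", "Follicle")
        ba = region_de(table, "Follicle", "SED")
        merged = ab.set_index("gene").join(ba.set_index("gene"),
                                           lsuffix="_ab", rsuffix="_ba")
        np.testing.assert_allclose(merged["logfc_ab"], -merged["logfc_ba"],
                                   atol=1e-12)
        tested = merged["p_value_ab"].notna()
        np.testing.assert_allclose(merged.loc[tested, "p_value_ab"],
                                   merged.loc[tested, "p_value_ba"])

    def test_too_few_spots_rejected(self, spot_sample):
        table, _ = spot_sample
        small = table.subset(np.arange(table.n_spots) < 30)
        with pytest.raises(ValueError, match="spots per region"):
            region_de(small)


class TestGeneCorrelation:
    def test_matrix_properties(self, spot_sample):
        table, _ = spot_sample
        pre = preprocess_spots(table)
        rho, padj = gene_correlation_matrix(
            pre.lognorm, pre.genes,
            ("DNASE1L3", "C1QB", "C1QA", "NULL_001"))
        np.testing.assert_allclose(np.diag(rho), 1.0)
        np.testing.assert_allclose(rho.to_numpy(), rho.to_numpy().T)
        np.testing.assert_allclose(padj.to_numpy(), padj.to_numpy().T)

    def test_two_genes_holm_equals_raw(self, spot_sample):
        from domemap.stats import spearman_correlation

        table, _ = spot_sample
        pre = preprocess_spots(table)
        rho, padj = gene_correlation_matrix(pre.lognorm, pre.genes,
                                            ("DNASE1L3", "C1QB"))
        i = pre.genes.index("DNASE1L3")
        j = pre.genes.index("C1QB")
        _, p_raw = spearman_correlation(pre.lognorm[:, i], pre.lognorm[:, j])
        assert padj.loc["DNASE1L3", "C1QB"] == pytest.approx(p_raw)

    def test_missing_gene_warned_not_fatal(self, spot_sample):
        table, _ = spot_sample
        pre = preprocess_spots(table)
        with pytest.warns(UserWarning, match="absent"):
            rho, _ = gene_correlation_matrix(
                pre.lognorm, pre.genes, ("DNASE1L3", "C1QB", "NOT_A_GENE"))
        assert list(rho.columns) == ["DNASE1L3", "C1QB"]
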