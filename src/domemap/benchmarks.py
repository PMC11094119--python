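"""Synthetic benchmark suite: every headline behaviour, recomputed from scratch.

Each function simulates its own inputs with known ground truth, runs the
relevant pipeline stage, and returns the measured quantities. The same
functions back the acceptance test suite and the standalone benchmark
script, so the numbers reported anywhere are always produced by running the
package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synth import SimConfig, rng_for


def spillover_roundtrip(seed: int, n_cases: int = 100,
                        cell_area_px: int = 40) -> dict:
    """Compensate(apply(X, S), S) must return X; with Poisson shot noise the
    median relative error at mean counts >= 20 must stay small.

    Shot noise acts on the integrated ion counts over a cell's pixels; the
    tables carry mean pixel intensities, so the noisy observation is a
    Poisson draw of ``mean * area`` divided back by the area (the default
    area is the simulator's median cell size).
    """
    from .imc import compensate_spillover
    from .synth import apply_spillover

    rng = rng_for(seed, "bench/spillover")
    max_err = 0.0
    rel_errors = []
    for _ in range(n_cases):
        p = int(rng.integers(4, 17))
        S = np.eye(p)
        off = rng.uniform(0.0, 0.08, size=(p, p))
        S += off * (1 - np.eye(p))
        X = rng.uniform(0.0, 300.0, size=(50, p))
        clean = compensate_spillover(apply_spillover(X, S), S)
        max_err = max(max_err, float(np.abs(clean - X).max()))
        noisy_obs = rng.poisson(
            apply_spillover(X, S) * cell_area_px) / cell_area_px
        noisy = compensate_spillover(noisy_obs, S)
        mask = X >= 20
        rel_errors.append(np.abs(noisy[mask] - X[mask]) / X[mask])
    median_rel = float(np.median(np.concatenate(rel_errors)))
    return {"max_abs_error": max_err, "poisson_median_rel_error": median_rel,
            "n_cases": n_cases}


def distance_oracle(seed: int, n_rois: int = 50, n_cells: int = 1000) -> dict:
    """KD-tree distances must equal the exhaustive O(n^2) minimum exactly."""
    from .spatial import nearest_epithelial_distance

    rng = rng_for(seed, "bench/distance")
    mismatches = 0
    for r in range(n_rois):
        coords = rng.uniform(0, 1000, size=(n_cells, 2))
        lineage = np.where(rng.random(n_cells) < 0.1, "Epithelial", "B")
        if (lineage == "Epithelial").sum() < 2:
            lineage[:2] = "Epithelial"
        cells = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1],
                              "lineage": lineage, "roi": f"R{r}"})
        fast = nearest_epithelial_distance(cells).to_numpy()
        epi = coords[lineage == "Epithelial"]
        d_all = np.linalg.norm(coords[:, None, :] - epi[None, :, :], axis=2)
        is_epi = lineage == "Epithelial"
        d_all[is_epi, :] = np.where(
            d_all[is_epi] == 0.0, np.inf, d_all[is_epi])
        brute = d_all.min(axis=1)
        mismatches += int((fast != brute).sum())
    return {"mismatches": mismatches, "n_rois": n_rois, "n_cells": n_cells}


def dn2_distance_ordering(seed: int, n_rois: int = 16) -> dict:
    """DN2 cells must sit closest to the epithelium across simulated ROIs."""
    from .spatial import distance_ordering_report, nearest_epithelial_distance
    from .synth import simulate_imc_rois

    cfg = SimConfig(seed=seed)
    cells, zones, truth = simulate_imc_rois(cfg, n_rois=n_rois)
    cells = cells.assign(lineage=truth["true_lineage"].to_numpy(),
                         b_subset=truth["true_type"].to_numpy())
    cells["dist_epithelium_um"] = nearest_epithelial_distance(cells)
    b = cells[cells["lineage"] == "B"]
    medians, tests = distance_ordering_report(b)
    dn2_closest = int((medians.idxmin(axis=1) == "DN2").sum())
    return {
        "dn2_closest_rois": dn2_closest,
        "n_rois": int(len(medians)),
        "max_p_vs_other_subsets": float(tests["p_value"].max()),
        "n_subsets_tested": int(len(tests)),
        "dn2_median_um": float(medians["DN2"].median()),
    }


def cytof_replicates(seed: int, n_replicates: int = 100,
                     n_events: int = 2500, n_per_sample: int = 1500,
                     k_nodes: int = 60) -> dict:
    """Paired tissue/blood detection of the configured DN2/3 enrichment,
    with DN1 (no configured effect) as the type-I control, across seeds."""
    from .cytof import run_cytof_stage
    from .synth import simulate_suspension_pair

    rng = rng_for(seed, "bench/cytof")
    dn2_hits = 0
    dn1_null = 0
    for rep in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        cfg = SimConfig(seed=rep_seed)
        cfg.suspension.n_events_per_sample = n_events
        events, _ = simulate_suspension_pair(cfg, n_donors=5)
        res = run_cytof_stage(events.reset_index(),
                              n_per_sample=n_per_sample,
                              k_nodes=k_nodes, seed=rep_seed)
        tests = res.tests.set_index("subset")
        if ("DN2/3" in tests.index
                and tests.loc["DN2/3", "p_value"] < 0.05
                and tests.loc["DN2/3", "galt_mean"]
                > tests.loc["DN2/3", "pbmc_mean"]):
            dn2_hits += 1
        if "DN1" in tests.index and tests.loc["DN1", "p_value"] > 0.05:
            dn1_null += 1
    return {"dn2_detection_rate": dn2_hits / n_replicates,
            "dn1_null_rate": dn1_null / n_replicates,
            "n_replicates": n_replicates}


def gating_propagation(seed: int, n_rois: int = 2) -> dict:
    """Lineage recovery, mutual-exclusion property, held-out accuracy."""
    from .imc import (compensate_spillover, gate_cells, propagate_labels,
                      qc_filter)
    from .stats import arcsinh_transform
    from .synth import default_spillover, simulate_imc_rois
    from .synth.phenotypes import IMC_MARKERS

    cfg = SimConfig(seed=seed)
    cells, zones, truth = simulate_imc_rois(cfg, n_rois=n_rois)
    truth = truth.set_index("cell_id")
    kept, _ = qc_filter(cells)
    comp = compensate_spillover(kept[list(IMC_MARKERS)], default_spillover())
    transformed = pd.DataFrame(arcsinh_transform(comp.to_numpy(), 5.0),
                               index=kept.index, columns=list(IMC_MARKERS))
    gated = gate_cells(kept, transformed, seed=seed)
    bt = ((transformed["CD20"] > 1.5) & (transformed["CD3"] > 1.5)).to_numpy()
    bt_gate_labelled = int((gated[bt] != "unassigned").sum())
    lineage, report = propagate_labels(transformed, gated, split=0.7,
                                       seed=seed)
    lineage_truth = truth.loc[kept["cell_id"], "true_lineage"].to_numpy()
    return {
        "n_cells": int(len(kept)),
        "lineage_accuracy": float((lineage.to_numpy() == lineage_truth).mean()),
        "heldout_accuracy": float(report.accuracy),
        "bt_profiles_gate_labelled": bt_gate_labelled,
        "n_bt_profiles": int(bt.sum()),
    }


def potts_benchmark(seed: int) -> dict:
    """Spatial clustering at 2-sigma separation, and the gamma=0 reduction
    to a non-spatial Gaussian mixture at 5-sigma."""
    from sklearn.metrics import adjusted_rand_score as ari
    from sklearn.mixture import GaussianMixture

    from .spots import build_spot_graph, potts_cluster
    from .synth import simulate_feature_lattice

    X, zones, spots = simulate_feature_lattice(seed=seed, n_rows=40,
                                               n_cols=40, n_zones=3,
                                               separation=2.0)
    graph = build_spot_graph(spots, "hex")
    spatial = potts_cluster(X, graph, q=3, iterations=600, burn_in=200,
                            seed=seed)
    flat = potts_cluster(X, graph, q=3, gamma=0.0, iterations=300,
                         burn_in=150, seed=seed)
    X5, z5, spots5 = simulate_feature_lattice(seed=seed + 1, n_rows=40,
                                              n_cols=40, n_zones=3,
                                              separation=5.0)
    graph5 = build_spot_graph(spots5, "hex")
    flat5 = potts_cluster(X5, graph5, q=3, gamma=0.0, iterations=300,
                          burn_in=150, seed=seed)
    gmm = GaussianMixture(3, covariance_type="spherical",
                          random_state=seed % (2**31)).fit(X5)
    return {
        "ari_spatial": float(ari(zones, spatial.labels)),
        "ari_gamma0": float(ari(zones, flat.labels)),
        "ari_gamma0_vs_gmm_5sigma": float(ari(gmm.predict(X5), flat5.labels)),
        "n_spots": int(len(X)),
    }


def qtune_benchmark(seed: int, n_seeds: int = 20, n_zones: int = 7) -> dict:
    """Advisory elbow recovery of the simulated program count."""
    from .spots import build_spot_graph, preprocess_spots, tune_q
    from .synth import simulate_program_lattice

    rng = rng_for(seed, "bench/qtune")
    hits = 0
    for _ in range(n_seeds):
        s = int(rng.integers(0, 2**31 - 1))
        table, _ = simulate_program_lattice(seed=s, n_zones=n_zones)
        pre = preprocess_spots(table, n_hvg=2000, n_pcs=15)
        graph = build_spot_graph(table.spots, "hex")
        _, suggested = tune_q(pre.pcs, graph, q_range=range(2, 13), seed=s)
        hits += int(suggested == n_zones)
    return {"hit_rate": hits / n_seeds, "n_seeds": n_seeds,
            "true_q": n_zones}


def region_de_benchmark(seed: int, n_null_replicates: int = 200) -> dict:
    """DNASE1L3 must top the SED-enriched ranking; family-wise error over
    the null genes must stay controlled across replicates."""
    from .spots import region_de
    from .synth import simulate_spot_sample

    cfg = SimConfig(seed=seed)
    table, _ = simulate_spot_sample(cfg)
    de = region_de(table)
    sed_up = de[de["passed_filters"] & (de["logfc"] > 0)]
    top_gene = str(sed_up.iloc[0]["gene"]) if len(sed_up) else ""

    rng = rng_for(seed, "bench/de_null")
    false_positive_reps = 0
    for _ in range(n_null_replicates):
        s = int(rng.integers(0, 2**31 - 1))
        null_cfg = SimConfig(seed=s)
        null_cfg.spots.n_rows, null_cfg.spots.n_cols = 17, 18
        t, _ = simulate_spot_sample(null_cfg)
        d = region_de(t)
        nulls = d[d["gene"].str.startswith("NULL")]
        if (nulls["p_adjusted"] < 0.05).any():
            false_positive_reps += 1
    return {"top_sed_gene": top_gene,
            "top_is_dnase1l3": int(top_gene == "DNASE1L3"),
            "null_fwer": false_positive_reps / n_null_replicates,
            "n_null_replicates": n_null_replicates}


def correlation_benchmark(seed: int) -> dict:
    """Co-programmed complement genes correlate strongly over lymphoid
    spots; independent null genes do not."""
    from .spots import gene_correlation_matrix, preprocess_spots
    from .synth import simulate_spot_sample

    cfg = SimConfig(seed=seed)
    table, _ = simulate_spot_sample(cfg)
    pre = preprocess_spots(table)
    lymph = np.isin(table.spots["region"].to_numpy(),
                    ["SED", "Follicle"])[pre.kept_spots]
    program = ("DNASE1L3", "C1QB", "C1QA")
    nulls = ("NULL_001", "NULL_002", "NULL_003", "NULL_004", "NULL_005")
    rho, padj = gene_correlation_matrix(pre.lognorm, pre.genes,
                                        program + nulls, spot_mask=lymph)
    prog_rhos = [rho.loc[a, b] for i, a in enumerate(program)
                 for b in program[i + 1:]]
    prog_padj = [padj.loc[a, b] for i, a in enumerate(program)
                 for b in program[i + 1:]]
    null_rhos = [abs(rho.loc[a, b]) for i, a in enumerate(nulls)
                 for b in nulls[i + 1:]]
    null_padj = [padj.loc[a, b] for i, a in enumerate(nulls)
                 for b in nulls[i + 1:]]
    return {
        "min_program_rho": float(min(prog_rhos)),
        "max_program_holm_p": float(max(prog_padj)),
        "max_null_abs_rho": float(max(null_rhos)),
        "min_null_holm_p": float(min(null_padj)),
        "n_spots": int(lymph.sum()),
    }


def coloc_benchmark(seed: int,
                    overlaps: tuple[float, ...] = (0.0, 0.3, 1.0)) -> dict:
    """Requested overlap fractions recovered through the threshold pipeline."""
    from .spatial import coloc_fraction
    from .synth import simulate_coloc_raster
    from .synth.raster import ColocRaster

    cfg = SimConfig(seed=seed)
    errors = {}
    for overlap in overlaps:
        raster, truth = simulate_coloc_raster(cfg, overlap)
        bare = ColocRaster(channels=dict(raster.channels),
                           um_per_px=raster.um_per_px)
        computed = coloc_fraction(bare, "signal", "reference")
        errors[overlap] = abs(computed - overlap)
    return {"max_abs_error": float(max(errors.values())),
            "per_overlap_error": {str(k): float(v)
                                  for k, v in errors.items()},
            "n_overlaps": len(overlaps)}
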