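"""End-to-end orchestration: simulate inputs, run every stage, bundle reports.

The pipeline runs the stages in dependency order — simulate, then the
suspension-cytometry stage, the segmented-image stage with its spatial
quantifications, the spot-transcriptomics stage, and the colocalization
quantification — collecting per-stage outputs, warnings and timings into a
single report. All randomness flows from the config seed; re-running the
same config reproduces the same report.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synth import (SimConfig, default_spillover, simulate_coloc_raster,
                    simulate_imc_rois, simulate_spot_pair,
                    simulate_suspension_pair)
from .synth.phenotypes import IMC_MARKERS


@dataclass
class PipelineConfig:
    """All stage parameters with their defaults, plus stage toggles."""

    seed: int = 0
    out_dir: str = "domemap_out"
    simulate: bool = True
    stages: tuple[str, ...] = ("cytof", "imc", "spatial", "spots", "coloc")
    # suspension stage
    n_donors: int = 5
    n_per_sample: int = 9214
    k_nodes: int = 100
    # segmented-image stage
    min_area_px: int = 11
    split: float = 0.7
    k_b_clusters: int = 20
    # spot stage
    n_hvg: int = 2000
    n_pcs: int = 15
    gamma: float = 4.0
    q: int | None = None              # None: advisory elbow from tune_q
    q_range: tuple[int, int] = (2, 12)
    mcmc_iterations: int = 400
    mcmc_burn_in: int = 150
    n_subclusters: int = 5
    logfc_min: float = 0.25
    min_fraction: float = 0.10
    # colocalization stage
    overlaps: tuple[float, ...] = (0.0, 0.3, 1.0)
    sim: SimConfig = field(default_factory=SimConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        if "sim" in raw and isinstance(raw["sim"], dict):
            raw["sim"] = SimConfig.from_dict(raw["sim"])
        for key in ("stages", "overlaps", "q_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.sim.seed = cfg.seed
        return cfg


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the enabled stages and return (and write) the report bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "warnings": [],
    }

    def _run(stage: str, fn) -> None:
        if stage not in config.stages:
            return
        t0 = time.time()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                report["stages"][stage] = fn()
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        report["warnings"] += [f"{stage}: {w.message}" for w in caught]
        report["stages"][stage]["elapsed_s"] = round(time.time() - t0, 2)

    _run("cytof", lambda: _cytof_stage(config, out_dir))
    imc_ctx: dict[str, Any] = {}
    _run("imc", lambda: _imc_stage(config, out_dir, imc_ctx))
    _run("spatial", lambda: _spatial_stage(config, out_dir, imc_ctx))
    _run("spots", lambda: _spot_stage(config, out_dir))
    _run("coloc", lambda: _coloc_stage(config))

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonify)
    return report


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _cytof_stage(config: PipelineConfig, out_dir: Path) -> dict[str, Any]:
    from .cytof import run_cytof_stage

    events, truth = simulate_suspension_pair(config.sim, config.n_donors)
    res = run_cytof_stage(events.reset_index(),
                          n_per_sample=config.n_per_sample,
                          k_nodes=config.k_nodes, seed=config.seed)
    res.proportions.to_csv(out_dir / "cytof_proportions.csv", index=False)
    res.tests.to_csv(out_dir / "cytof_tests.csv", index=False)
    tests = res.tests.set_index("subset")
    return {
        "n_events": int(len(res.events)),
        "n_nodes": int(res.tree.n_nodes),
        "subset_tests": {
            s: {"galt_mean": float(r["galt_mean"]),
                "pbmc_mean": float(r["pbmc_mean"]),
                "p_value": float(r["p_value"])}
            for s, r in tests.iterrows()},
    }


def _imc_stage(config: PipelineConfig, out_dir: Path,
               ctx: dict[str, Any]) -> dict[str, Any]:
    from .imc import run_imc_stage

    cells, zones, truth = simulate_imc_rois(config.sim)
    res = run_imc_stage(cells, default_spillover(), IMC_MARKERS,
                        min_area_px=config.min_area_px, split=config.split,
                        k_b_clusters=config.k_b_clusters, seed=config.seed)
    ctx.update(cells=cells, zones=zones, truth=truth, result=res)
    labelled = res.cells.assign(lineage=res.lineage)
    labelled.loc[res.b_subset.index, "b_subset"] = res.b_subset
    labelled.to_csv(out_dir / "imc_cells.csv", index=False)
    res.qc_log.to_csv(out_dir / "imc_qc_log.csv", index=False)
    return {
        "n_cells_in": int(len(cells)),
        "n_cells_qc": int(len(res.cells)),
        "propagation_accuracy": res.propagation.accuracy,
        "lineage_counts": res.lineage.value_counts().to_dict(),
        "b_subset_counts": res.b_subset.value_counts().to_dict(),
    }


def _spatial_stage(config: PipelineConfig, out_dir: Path,
                   ctx: dict[str, Any]) -> dict[str, Any]:
    from .spatial import (distance_ordering_report,
                          nearest_epithelial_distance, zone_assign)

    if not ctx:
        raise ValueError("spatial stage requires the imc stage")
    res = ctx["result"]
    cells = res.cells.assign(lineage=res.lineage.to_numpy())
    cells["b_subset"] = "none"
    cells.loc[res.b_subset.index, "b_subset"] = res.b_subset
    cells["dist_epithelium_um"] = nearest_epithelial_distance(cells)
    cells["zone"] = zone_assign(cells, ctx["zones"])
    b = cells[cells["lineage"] == "B"]
    medians, tests = distance_ordering_report(b)
    medians.to_csv(out_dir / "spatial_subset_distances.csv")
    tests.to_csv(out_dir / "spatial_distance_tests.csv", index=False)
    med_overall = medians.median()
    return {
        "subset_median_distance_um": {k: float(v)
                                      for k, v in med_overall.items()},
        "dn2_closest_in_rois": int(
            (medians.idxmin(axis=1) == "DN2").sum()),
        "n_rois": int(len(medians)),
        "tests": tests.to_dict("records"),
    }


def _spot_stage(config: PipelineConfig, out_dir: Path) -> dict[str, Any]:
    from .spots import (build_spot_graph, gene_correlation_matrix,
                        potts_cluster, preprocess_spots, region_de,
                        select_lymphoid_cluster, tune_q)

    sta, stb, truth = simulate_spot_pair(config.sim)
    pre = preprocess_spots(sta, n_hvg=config.n_hvg, n_pcs=config.n_pcs,
                           seed=config.seed)
    graph = build_spot_graph(sta.spots.iloc[pre.kept_spots], sta.lattice)
    if config.q is None:
        curve, q = tune_q(pre.pcs, graph,
                          q_range=range(config.q_range[0],
                                        config.q_range[1] + 1),
                          gamma=config.gamma, seed=config.seed)
        curve.to_csv(out_dir / "spots_qtune.csv", index=False)
    else:
        q = config.q
    state = potts_cluster(pre.pcs, graph, q, gamma=config.gamma,
                          iterations=config.mcmc_iterations,
                          burn_in=config.mcmc_burn_in, seed=config.seed)
    cluster_id, lymph_mask, score = select_lymphoid_cluster(
        state.labels, pre.lognorm, pre.genes)
    de = region_de(sta, logfc_min=config.logfc_min,
                   min_fraction=config.min_fraction)
    de.to_csv(out_dir / "spots_region_de.csv", index=False)
    rho, padj = gene_correlation_matrix(pre.lognorm, pre.genes,
                                        spot_mask=lymph_mask)
    rho.to_csv(out_dir / "spots_sle_rho.csv")
    padj.to_csv(out_dir / "spots_sle_padj.csv")
    sed_up = de[de["passed_filters"] & (de["logfc"] > 0)]
    return {
        "q": int(q),
        "lymphoid_cluster": int(cluster_id),
        "n_lymphoid_spots": int(lymph_mask.sum()),
        "top_sed_gene": (str(sed_up.iloc[0]["gene"]) if len(sed_up)
                         else None),
        "n_de_genes": int((de["p_adjusted"] < 0.05).sum()),
    }


def _coloc_stage(config: PipelineConfig) -> dict[str, Any]:
    from .spatial import coloc_fraction

    out = {}
    for overlap in config.overlaps:
        raster, truth = simulate_coloc_raster(config.sim, overlap)
        frac = coloc_fraction(raster, "signal", "reference")
        out[str(overlap)] = {"requested": overlap,
                             "ground_truth": truth["overlap_fraction"],
                             "computed": frac}
    return {"overlap_fractions": out}
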