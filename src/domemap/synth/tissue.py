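"""Simulated imaging-mass-cytometry ROIs: segmented cells with zones.

Each ROI is a stylised GALT section (see :mod:`.geometry`): cells are placed
by a zone-weighted point process — DN2 B cells concentrated just beneath the
FAE in the SED, IEDN inside the FAE itself, naive/MZ cells in the mantle,
germinal-centre subsets in the GC — so the expected ordering of
distance-to-epithelium across B subsets holds by construction. Observed raw
intensities are the inverse-arcsinh of (true transformed + per-ROI batch
shift), mixed through the spillover matrix. A configurable fraction of cells
falls below the size-QC threshold or carries no DNA signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from ..stats import arcsinh_transform, inverse_arcsinh
from .config import SimConfig, rng_for
from .geometry import (default_zone_geometry, exclusive_zone_polygons,
                       sample_points_in_polygon)
from .phenotypes import IMC_MARKERS, LINEAGE_OF_TYPE, default_imc_model


@dataclass(frozen=True)
class CellPlacement:
    """How many cells of one type to place, and where."""

    name: str
    count: int
    zone_weights: dict[str, float]
    depth_scale: float | None = None  # exponential depth decay within zone


def default_cell_layout() -> tuple[CellPlacement, ...]:
    return (
        CellPlacement("Epithelial", 350, {"FAE": 1.0}),
        CellPlacement("Endothelial", 200, {"lamina_propria": 0.9, "T_zone": 0.1}),
        CellPlacement("T", 700, {"T_zone": 0.7, "lamina_propria": 0.2, "GC": 0.1}),
        CellPlacement("MacDC", 350, {"SED": 0.6, "lamina_propria": 0.4}),
        CellPlacement("Naive", 500, {"mantle": 0.8, "lamina_propria": 0.2}),
        CellPlacement("MZP", 80, {"mantle": 0.5, "SED": 0.5}),
        CellPlacement("MZB", 150, {"SED": 0.4, "mantle": 0.6}),
        CellPlacement("Mem", 250, {"lamina_propria": 0.6, "SED": 0.2, "mantle": 0.2}),
        CellPlacement("DN1", 120, {"lamina_propria": 0.7, "mantle": 0.3}),
        CellPlacement("DN2", 150, {"SED": 0.9, "FAE": 0.1}, depth_scale=40.0),
        CellPlacement("IEDN", 60, {"FAE": 1.0}),
        CellPlacement("GC LZ", 300, {"GC": 1.0}),
        CellPlacement("GC DZ", 300, {"GC": 1.0}),
        CellPlacement("PB/PC", 150, {"lamina_propria": 0.8, "SED": 0.2}),
    )


def default_spillover(n_channels: int | None = None,
                      strength: float = 0.04) -> pd.DataFrame:
    """Banded spillover matrix: each channel leaks into its two successors."""
    channels = list(IMC_MARKERS) if n_channels is None else [
        f"ch{i}" for i in range(n_channels)]
    n = len(channels)
    S = np.eye(n)
    for i in range(n - 1):
        S[i, i + 1] = strength
    for i in range(n - 2):
        S[i, i + 2] = strength / 2
    return pd.DataFrame(S, index=channels, columns=channels)


def apply_spillover(true_intensities: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Forward spillover mixing: ``observed = true @ S``.

    Row ``i`` of ``S`` says how source channel ``i`` distributes its signal
    across receiving channels; the diagonal must be 1 and entries
    nonnegative.
    """
    S = np.asarray(S, dtype=float)
    true_intensities = np.asarray(true_intensities, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("spillover matrix must be square")
    if not np.allclose(np.diag(S), 1.0):
        raise ValueError("spillover diagonal must be 1")
    if np.any(S < 0):
        raise ValueError("spillover entries must be nonnegative")
    if true_intensities.shape[-1] != S.shape[0]:
        raise ValueError(
            f"channel mismatch: {true_intensities.shape[-1]} vs {S.shape[0]}")
    return true_intensities @ S


def simulate_imc_roi(
    config: SimConfig,
    roi: str = "ROI01",
    layout: tuple[CellPlacement, ...] | None = None,
    zones: dict[str, Polygon] | None = None,
) -> tuple[pd.DataFrame, dict[str, Polygon], pd.DataFrame]:
    """Simulate one ROI.

    Returns ``(cells, zones, truth)``. ``cells`` holds observed raw
    intensities (post batch shift and spillover) in the marker columns plus
    ``cell_id, roi, x, y, area_px``. ``truth`` holds the true type, lineage,
    zone and the pre-spillover transformed intensities (``asinh_`` columns).
    """
    imc = config.imc
    layout = default_cell_layout() if layout is None else layout
    zones = default_zone_geometry() if zones is None else zones
    model = default_imc_model()
    markers = list(model.markers)
    S = default_spillover(strength=imc.spillover_strength).to_numpy()

    for placement in layout:
        missing = set(placement.zone_weights) - set(zones)
        if placement.count > 0 and missing:
            raise ValueError(
                f"{placement.name}: zones {sorted(missing)} not in geometry")

    sampling_polys = exclusive_zone_polygons(zones)
    rng = rng_for(config.seed, f"imc/{roi}")
    batch_shift = rng_for(config.seed, f"imc/{roi}/batch").normal(
        0.0, imc.batch_sd, size=len(markers))

    rows = []
    truth_rows = []
    for placement in layout:
        if placement.count == 0:
            continue
        names = list(placement.zone_weights)
        w = np.array([placement.zone_weights[z] for z in names], dtype=float)
        w = w / w.sum()
        per_zone = rng.multinomial(placement.count, w)
        for zone_name, k in zip(names, per_zone):
            if k == 0:
                continue
            pts = sample_points_in_polygon(
                sampling_polys[zone_name], int(k), rng,
                depth_scale=placement.depth_scale)
            raw_true = model.sample_raw(placement.name, int(k), rng)
            rows.append((placement.name, zone_name, pts, raw_true))

    n_total = sum(r[2].shape[0] for r in rows)
    order = rng.permutation(n_total)

    types = np.concatenate([[r[0]] * r[2].shape[0] for r in rows])[order]
    zone_labels = np.concatenate([[r[1]] * r[2].shape[0] for r in rows])[order]
    xy = np.vstack([r[2] for r in rows])[order]
    raw_true = np.vstack([r[3] for r in rows])[order]

    true_transformed = arcsinh_transform(raw_true, imc.cofactor)
    shifted = np.clip(true_transformed + batch_shift, 0.0, None)
    raw_shifted = inverse_arcsinh(shifted, imc.cofactor)

    # a fraction of cells with essentially no DNA signal (segmentation noise)
    low_dna = rng.random(n_total) < imc.low_dna_fraction
    dna_idx = [markers.index("DNA1"), markers.index("DNA2")]
    raw_shifted[np.ix_(low_dna, dna_idx)] = rng.uniform(
        0.0, 0.5, size=(int(low_dna.sum()), 2))

    # B-T adjacency doublets: B cells that also carry T-cell signal
    bt = (rng.random(n_total) < imc.bt_doublet_fraction) & (
        np.isin(types, ["Naive", "Mem", "MZB"]))
    cd3_idx = markers.index("CD3")
    raw_shifted[bt, cd3_idx] = np.exp(rng.normal(
        model.neg_meanlog + model.separation, model.pos_sdlog,
        size=int(bt.sum())))

    observed = apply_spillover(raw_shifted, S)

    area = np.round(np.exp(rng.normal(np.log(40.0), 0.35, size=n_total)))
    small = rng.random(n_total) < imc.small_cell_fraction
    area[small] = rng.integers(3, 11, size=int(small.sum()))
    area = np.clip(area, 1, None).astype(int)

    cells = pd.DataFrame(observed, columns=markers)
    cells.insert(0, "area_px", area)
    cells.insert(0, "y", xy[:, 1])
    cells.insert(0, "x", xy[:, 0])
    cells.insert(0, "roi", roi)
    cells.insert(0, "cell_id", [f"{roi}_c{i:05d}" for i in range(n_total)])

    truth = pd.DataFrame(
        arcsinh_transform(raw_true, imc.cofactor),
        columns=[f"asinh_{m}" for m in markers])
    truth.insert(0, "low_dna", low_dna)
    truth.insert(0, "bt_doublet", bt)
    truth.insert(0, "true_zone", zone_labels)
    truth.insert(0, "true_lineage", [LINEAGE_OF_TYPE[t] for t in types])
    truth.insert(0, "true_type", types)
    truth.insert(0, "cell_id", cells["cell_id"].to_numpy())
    return cells, zones, truth


def simulate_imc_rois(
    config: SimConfig,
    n_rois: int | None = None,
) -> tuple[pd.DataFrame, dict[str, Polygon], pd.DataFrame]:
    """Concatenate ``n_rois`` simulated ROIs (default from config)."""
    n = config.imc.n_rois if n_rois is None else n_rois
    cell_frames, truth_frames = [], []
    zones: dict[str, Polygon] = {}
    for i in range(n):
        cells, zones, truth = simulate_imc_roi(config, roi=f"ROI{i + 1:02d}")
        cell_frames.append(cells)
        truth_frames.append(truth)
    return (pd.concat(cell_frames, ignore_index=True), zones,
            pd.concat(truth_frames, ignore_index=True))
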