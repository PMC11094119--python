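"""Spatial quantifications on labelled cells and rasters.

Distance-to-epithelium statistics (the B-subset distance ordering), polygon
zone assignment, per-ROI positivity classification, grouped expression
contrasts with ROI-level paired tests, blob segmentation of raster channels,
and pixel colocalization fractions.

Coordinates are µm, origin top-left, y increasing downward; zone polygons
are boundary-inclusive and nested polygons resolve to the smallest
containing one. Distances are centroid-to-centroid and never cross ROI
boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from .stats import TestResult, t_test
from .synth.geometry import zone_of_points
from .synth.raster import ColocRaster


@dataclass
class ContrastReport:
    """Two-group expression contrast with explicit unit of analysis."""

    group_by: str
    value: str
    unit: str                        # "cell" or "ROI"
    group_means: dict[str, float]
    group_n: dict[str, int]
    per_roi: pd.DataFrame | None
    test: TestResult


def nearest_epithelial_distance(
    cells: pd.DataFrame,
    lineage_col: str = "lineage",
    epithelium_label: str = "Epithelial",
    roi_col: str = "roi",
    x_col: str = "x",
    y_col: str = "y",
) -> pd.Series:
    """Per-cell Euclidean distance (µm) to the nearest epithelial cell.

    Computed independently within each ROI with a KD-tree (exact, the index
    is an optimisation only). Epithelial cells report the distance to the
    nearest *other* epithelial cell. ROIs without epithelial cells yield NaN
    with a warning.
    """
    out = pd.Series(np.nan, index=cells.index, name="dist_epithelium_um")
    for roi, idx in cells.groupby(roi_col).indices.items():
        idx = cells.index[idx]
        block = cells.loc[idx]
        epi = block[block[lineage_col] == epithelium_label]
        if epi.empty:
            warnings.warn(f"ROI {roi}: no epithelial cells; distances NaN",
                          stacklevel=2)
            continue
        tree = cKDTree(epi[[x_col, y_col]].to_numpy(dtype=float))
        pts = block[[x_col, y_col]].to_numpy(dtype=float)
        is_epi = (block[lineage_col] == epithelium_label).to_numpy()
        if len(epi) > 1:
            d2, _ = tree.query(pts, k=2)
            d = np.where(is_epi, d2[:, 1], d2[:, 0])
        else:
            d, _ = tree.query(pts, k=1)
            d = np.where(is_epi, np.nan, d)
        out.loc[idx] = d
    return out


def zone_assign(
    cells: pd.DataFrame,
    zones: dict[str, Polygon],
    x_col: str = "x",
    y_col: str = "y",
    fallback: str = "other",
) -> pd.Series:
    """Zone label per cell: smallest containing polygon, boundary-inclusive."""
    for name, poly in zones.items():
        if not poly.is_valid:
            raise ValueError(f"zone {name!r}: invalid polygon")
    labels = zone_of_points(cells[[x_col, y_col]].to_numpy(dtype=float),
                            zones, fallback=fallback)
    return pd.Series(labels, index=cells.index, name="zone")


def positivity_classify(
    cells: pd.DataFrame,
    channel: str,
    method: str = "mixture",
    threshold: float | None = None,
    roi_col: str = "roi",
) -> pd.Series:
    """Positive/negative flag per cell on a transformed intensity channel.

    Thresholds are per-ROI: a two-component mixture midpoint (falling back
    to a quantile rule on effectively unimodal channels, with a warning),
    Otsu's threshold, or a fixed value. The boundary is inclusive
    (intensity >= threshold is positive).
    """
    if channel not in cells.columns:
        raise ValueError(f"channel {channel!r} not present")
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold value")
        return (cells[channel] >= threshold).rename(f"{channel}_pos")
    from .rules import fit_marker_thresholds

    flags = pd.Series(False, index=cells.index, name=f"{channel}_pos")
    for roi, idx in cells.groupby(roi_col).indices.items():
        idx = cells.index[idx]
        x = cells.loc[idx, channel].to_numpy(dtype=float)
        if np.ptp(x) < 1e-12:
            flags.loc[idx] = False
            continue
        if method == "otsu":
            thr = float(threshold_otsu(x))
        elif method == "mixture":
            thr = fit_marker_thresholds(
                pd.DataFrame({channel: x}))[channel]
            if thr > x.max():       # degenerate unimodal fallback
                warnings.warn(
                    f"ROI {roi}: unimodal {channel}; quantile fallback",
                    stacklevel=2)
                thr = float(np.quantile(x, 0.99))
        else:
            raise ValueError(f"unknown method {method!r}")
        flags.loc[idx] = x >= thr
    return flags


def expression_contrast(
    cells: pd.DataFrame,
    group_by: str,
    value: str,
    unit: str = "ROI",
    roi_col: str = "roi",
) -> ContrastReport:
    """Compare a value between the two levels of a grouping variable.

    ``unit="ROI"`` (default): group means are computed per ROI and compared
    with a paired t test across ROIs (ROIs missing a group are dropped with
    a warning), matching analyses whose n is the number of imaged regions.
    ``unit="cell"``: pooled two-sample (Welch) t test over cells.
    """
    levels = [lv for lv in pd.unique(cells[group_by]) if pd.notna(lv)]
    if len(levels) != 2:
        raise ValueError(f"{group_by} must have exactly 2 levels, got {levels}")
    a_lv, b_lv = sorted(levels, key=str)
    vals = cells[[roi_col, group_by, value]].dropna(subset=[value])
    means = {str(lv): float(vals.loc[vals[group_by] == lv, value].mean())
             for lv in (a_lv, b_lv)}
    ns = {str(lv): int((vals[group_by] == lv).sum()) for lv in (a_lv, b_lv)}
    if unit == "ROI":
        per_roi = (vals.pivot_table(index=roi_col, columns=group_by,
                                    values=value, aggfunc="mean"))
        complete = per_roi.dropna()
        dropped = set(per_roi.index) - set(complete.index)
        if dropped:
            warnings.warn(f"ROIs missing a group dropped: {sorted(dropped)}",
                          stacklevel=2)
        if len(complete) < 2:
            raise ValueError("need >= 2 complete ROIs for the paired test")
        test = t_test(complete[a_lv], complete[b_lv], mode="paired")
        per_roi_out = complete.reset_index()
    elif unit == "cell":
        test = t_test(vals.loc[vals[group_by] == a_lv, value],
                      vals.loc[vals[group_by] == b_lv, value],
                      mode="unpaired")
        per_roi_out = None
    else:
        raise ValueError(f"unknown unit {unit!r}")
    return ContrastReport(group_by=group_by, value=value, unit=unit,
                          group_means=means, group_n=ns,
                          per_roi=per_roi_out, test=test)


def distance_ordering_report(
    cells: pd.DataFrame,
    subset_col: str = "b_subset",
    focus: str = "DN2",
    exclude: tuple[str, ...] = ("IEDN", "none"),
    distance_col: str = "dist_epithelium_um",
    roi_col: str = "roi",
    min_cells: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distance-to-epithelium ordering of B subsets across ROIs.

    Returns ``(per_roi_medians, tests)``: median distance per subset per
    ROI, and for every non-focus subset a paired t test of the focus
    subset's per-ROI medians against it. Intraepithelial subsets are
    excluded by default — sitting among the epithelial cells themselves,
    their near-zero distances say nothing about positioning within the
    tissue stroma.
    """
    df = cells.dropna(subset=[distance_col])
    df = df[~df[subset_col].isin(exclude)]
    counts = df.groupby([roi_col, subset_col]).size()
    med = (df.groupby([roi_col, subset_col])[distance_col].median()
           .unstack())
    # mask subset/ROI combinations with too few cells for a stable median
    small = counts.unstack() < min_cells
    med = med.mask(small)
    if focus not in med.columns:
        raise ValueError(f"focus subset {focus!r} absent")
    rows = []
    for subset in med.columns:
        if subset == focus:
            continue
        pair = med[[focus, subset]].dropna()
        if len(pair) < 2:
            continue
        res = t_test(pair[focus], pair[subset], mode="paired")
        rows.append({
            "subset": subset,
            "n_rois": len(pair),
            "focus_median_mean": float(pair[focus].mean()),
            "subset_median_mean": float(pair[subset].mean()),
            "statistic": res.statistic,
            "p_value": res.p_value,
            "focus_closer_in": int((pair[focus] < pair[subset]).sum()),
        })
    return med, pd.DataFrame(rows)


def segment_objects(
    raster: ColocRaster,
    channel: str,
    min_diameter_px: float = 0.0,
    connectivity: int = 8,
    threshold: float | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Threshold a channel and extract connected objects.

    Otsu threshold by default, binary mask, connected components (4- or
    8-connectivity), objects below ``min_diameter_px`` equivalent diameter
    discarded. Returns the label image and an object table (centroid, area,
    equivalent diameter).
    """
    if channel not in raster.channels:
        raise ValueError(f"channel {channel!r} not in raster")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    img = raster.channels[channel]
    cols = ["object", "centroid_y", "centroid_x", "area_px", "equiv_diameter"]
    if img.size == 0 or np.ptp(img) < 1e-12:
        return np.zeros(img.shape, dtype=int), pd.DataFrame(columns=cols)
    thr = float(threshold_otsu(img)) if threshold is None else threshold
    mask = img > thr
    labels = cc_label(mask, connectivity=1 if connectivity == 4 else 2)
    rows = []
    keep = np.zeros(labels.max() + 1, dtype=int)
    nxt = 1
    for prop in regionprops(labels):
        if prop.equivalent_diameter_area >= min_diameter_px:
            keep[prop.label] = nxt
            rows.append({"object": nxt,
                         "centroid_y": prop.centroid[0],
                         "centroid_x": prop.centroid[1],
                         "area_px": int(prop.area),
                         "equiv_diameter": float(prop.equivalent_diameter_area)})
            nxt += 1
    return keep[labels], pd.DataFrame(rows, columns=cols)


def binarize_channel(raster: ColocRaster, channel: str,
                     threshold: float | None = None) -> np.ndarray:
    """Otsu (or fixed) binary mask of one channel, using a precomputed mask
    if the raster carries one."""
    if threshold is None and channel in raster.masks:
        return raster.masks[channel].astype(bool)
    img = raster.channels[channel]
    thr = float(threshold_otsu(img)) if threshold is None else threshold
    return img > thr


def coloc_fraction(
    raster: ColocRaster,
    signal_channel: str,
    reference: str | np.ndarray,
    signal_threshold: float | None = None,
) -> float:
    """Fraction of signal-positive pixels lying inside the reference mask.

    ``reference`` is a channel name (thresholded like the signal) or a
    boolean mask of the same shape. Zero signal-positive pixels yield NaN
    with a warning rather than a division error.
    """
    img = raster.channels[signal_channel]
    thr = (float(threshold_otsu(img)) if signal_threshold is None
           else signal_threshold)
    sig = img > thr
    if isinstance(reference, str):
        ref = binarize_channel(raster, reference)
    else:
        ref = np.asarray(reference, dtype=bool)
    if ref.shape != sig.shape:
        raise ValueError("reference mask shape mismatch")
    total = int(sig.sum())
    if total == 0:
        warnings.warn("no signal-positive pixels; fraction undefined",
                      stacklevel=2)
        return float("nan")
    return float((sig & ref).sum() / total)
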