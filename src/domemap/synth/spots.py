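"""Hex-grid spot transcriptomes with zone-specific gene programs.

The default sample lays spots on an odd-row-offset hexagonal lattice over the
zone geometry and draws negative-binomial counts whose means combine a
per-gene baseline, a zone-specific fold change (the "program"), and a
spot-specific library-size factor. The SED program is anchored on DNASE1L3
(largest fold change) with the complement genes C1QB/C1QA/C1R/C3 and the
myeloid markers CCL20/ITGAX; the follicle program carries MS4A1/IGHD/IGHM/
TCL1A/CD19; BCL6 marks the germinal centre; a T-zone program and >= 200 null
genes complete the panel.

Two auxiliary generators produce controlled lattices for clustering tests:
:func:`simulate_program_lattice` (Voronoi zones, disjoint gene programs) and
:func:`simulate_feature_lattice` (Gaussian features at fixed separation,
bypassing the count model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig, rng_for
from .geometry import default_zone_geometry, zone_of_points

#: program name -> (zones expressing it, gene -> fold change at full activity)
DEFAULT_PROGRAMS: dict[str, tuple[tuple[str, ...], dict[str, float]]] = {
    "sed": (("SED", "FAE"),
            {"DNASE1L3": 4.0, "C1QB": 3.0, "C1QA": 3.0, "C3": 2.5,
             "C1R": 2.5, "CCL20": 2.0, "ITGAX": 2.0}),
    "follicle": (("mantle", "GC"),
                 {"MS4A1": 5.0, "IGHM": 3.0, "TCL1A": 3.0, "CD19": 3.0}),
    "mantle_only": (("mantle",), {"IGHD": 4.0}),
    "gc": (("GC",), {"BCL6": 4.0}),
    "tzone": (("T_zone",), {"CD3D": 4.0, "CD3E": 4.0, "TRAC": 3.0}),
}

#: per-gene baseline mean counts; complement and immunoglobulin transcripts
#: are abundant in tissue, interleukin-class genes scarcer
PROGRAM_GENE_BASELINES: dict[str, float] = {
    "DNASE1L3": 8.0, "C1QB": 6.0, "C1QA": 6.0, "C3": 4.0, "C1R": 4.0,
    "CCL20": 3.0, "ITGAX": 3.0,
    "MS4A1": 6.0, "IGHM": 6.0, "TCL1A": 4.0, "CD19": 3.0, "IGHD": 4.0,
    "BCL6": 3.0, "CD3D": 4.0, "CD3E": 4.0, "TRAC": 4.0,
}

#: zones merged into the SED region label (FAE spots are part of the dome)
SED_ZONES = ("SED", "FAE")
FOLLICLE_ZONES = ("mantle", "GC")


@dataclass
class SpotTable:
    """Spot-level count matrix with array and physical coordinates."""

    counts: np.ndarray                # spots x genes, integer-valued
    genes: list[str]
    spots: pd.DataFrame               # spot_id, row, col, x, y, sample, zone, region
    lattice: str = "hex"

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.spots), len(self.genes)):
            raise ValueError("counts shape does not match spots x genes")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in table") from None

    def subset(self, mask: np.ndarray) -> "SpotTable":
        return SpotTable(self.counts[mask], list(self.genes),
                         self.spots.loc[mask].reset_index(drop=True),
                         self.lattice)


def _lattice_coords(n_rows: int, n_cols: int, lattice: str,
                    canvas: tuple[float, float]) -> pd.DataFrame:
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    rows = rows.ravel()
    cols = cols.ravel()
    dx = canvas[0] / n_cols
    dy = canvas[1] / n_rows
    if lattice == "hex":
        x = (cols + 0.5 * (rows % 2) + 0.25) * dx
    elif lattice == "square":
        x = (cols + 0.5) * dx
    else:
        raise ValueError(f"unknown lattice {lattice!r}")
    y = (rows + 0.5) * dy
    return pd.DataFrame({"row": rows, "col": cols, "x": x, "y": y})


def region_from_zone(zone: np.ndarray) -> np.ndarray:
    """Collapse zone labels to the annotation scheme SED / Follicle / none."""
    out = np.full(len(zone), "none", dtype=object)
    out[np.isin(zone, SED_ZONES)] = "SED"
    out[np.isin(zone, FOLLICLE_ZONES)] = "Follicle"
    return out.astype(str)


def _gene_panel(cfg, rng_genes: np.random.Generator) -> tuple[list[str], np.ndarray]:
    program_genes: list[str] = []
    for _, prog in DEFAULT_PROGRAMS.values():
        for g in prog:
            if g not in program_genes:
                program_genes.append(g)
    null_genes = [f"NULL_{i + 1:03d}" for i in range(cfg.n_null_genes)]
    genes = program_genes + null_genes
    baselines = np.concatenate([
        np.array([PROGRAM_GENE_BASELINES.get(g, 3.0) for g in program_genes]),
        np.exp(rng_genes.normal(cfg.baseline_meanlog, cfg.baseline_sdlog,
                                size=len(null_genes))),
    ])
    return genes, baselines


def _nb_counts(mean: np.ndarray, dispersion: "float | np.ndarray",
               rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson counts; ``dispersion`` may be scalar or per-gene."""
    disp = np.broadcast_to(np.asarray(dispersion, dtype=float),
                           mean.shape[-1:])
    out = np.empty(mean.shape, dtype=np.int64)
    pos = disp > 0
    if pos.any():
        lam = rng.gamma(shape=1.0 / disp[pos],
                        scale=mean[..., pos] * disp[pos])
        out[..., pos] = rng.poisson(lam)
    if (~pos).any():
        out[..., ~pos] = rng.poisson(mean[..., ~pos])
    return out


def _calibrated_jitter_location(sigma: float, amax: float,
                                smoothed_members: np.ndarray,
                                anchor_fc: float = 4.0) -> float:
    """Location of the lognormal activity jitter such that the mean
    multiplier over the program's member spots equals the configured fold
    change: ``mean_s E[fc ** clip(s_s * j, 0, amax)] = fc``.

    This keeps the realized zone-mean fold change calibrated despite both
    the convexity of ``fc ** j`` and boundary spots with partial membership.
    """
    from scipy.optimize import brentq
    from scipy.stats import norm

    z = norm.ppf(np.linspace(5e-4, 1 - 5e-4, 501))
    s = smoothed_members[smoothed_members > 0]
    if len(s) == 0:
        return 0.0

    def excess(mu: float) -> float:
        j = np.exp(mu + sigma * z)
        a = np.clip(s[:, None] * j[None, :], 0.0, amax)
        return float(np.mean(anchor_fc ** a)) - anchor_fc

    lo, hi = -2.0, 2.0
    if excess(lo) > 0 or excess(hi) < 0:
        return 0.0
    return brentq(excess, lo, hi)


def simulate_spot_sample(
    config: SimConfig,
    sample: str = "STA",
    batch_factors: np.ndarray | None = None,
) -> tuple[SpotTable, pd.DataFrame]:
    """Simulate one spot sample on the default zone geometry.

    Returns ``(table, truth)``. Program expression is graded per spot: a
    program's activity is its smoothed zone-membership indicator (spots near
    region boundaries capture mixed tissue) times a shared lognormal
    heterogeneity factor, and every gene of the program scales as
    ``fc ** activity`` — so co-programmed genes covary continuously across
    spots, as capture-spot transcriptomes of graded tissue content do.
    ``truth`` records each spot's zone, region and program activities.
    """
    cfg = config.spots
    for _, prog in DEFAULT_PROGRAMS.values():
        if any(fc <= 0 for fc in prog.values()):
            raise ValueError("program fold changes must be positive")
    rng = rng_for(config.seed, f"spots/{sample}")
    genes, baselines = _gene_panel(cfg, rng_for(config.seed, "spots/genes"))

    coords = _lattice_coords(cfg.n_rows, cfg.n_cols, cfg.lattice, cfg.canvas_um)
    zones = default_zone_geometry()
    xy = coords[["x", "y"]].to_numpy()
    zone = zone_of_points(xy, zones)
    region = region_from_zone(zone)

    n_spots = len(coords)
    n_genes = len(genes)
    gene_idx = {g: j for j, g in enumerate(genes)}

    # neighbourhood-smoothed program activity with shared per-spot jitter;
    # the jitter location is solved so the mean multiplier at full zone
    # membership equals the configured fold change (marginal calibration)
    from scipy.spatial import cKDTree

    pitch = max(cfg.canvas_um[0] / cfg.n_cols, cfg.canvas_um[1] / cfg.n_rows)
    tree = cKDTree(xy)
    neighbour_lists = tree.query_ball_point(xy, r=1.5 * pitch)
    activities: dict[str, np.ndarray] = {}
    multiplier = np.ones((n_spots, n_genes))
    for pname, (pzones, prog) in DEFAULT_PROGRAMS.items():
        indicator = np.isin(zone, pzones).astype(float)
        smoothed = np.array([indicator[nb].mean() for nb in neighbour_lists])
        mu_j = _calibrated_jitter_location(
            cfg.activity_sdlog, cfg.activity_max, smoothed[indicator > 0])
        jitter = np.exp(rng.normal(mu_j, cfg.activity_sdlog, size=n_spots))
        activity = np.clip(smoothed * jitter, 0.0, cfg.activity_max)
        activities[pname] = activity
        # per-spot content of the program's source cell population: shared
        # by all of the program's transcripts, independent of zone, mean 1
        content = np.exp(rng.normal(-cfg.content_sdlog ** 2 / 2,
                                    cfg.content_sdlog, size=n_spots))
        for g, f in prog.items():
            multiplier[:, gene_idx[g]] *= content * f ** activity

    lib = np.exp(rng.normal(cfg.library_meanlog, cfg.library_sdlog,
                            size=n_spots))
    mean = baselines[None, :] * multiplier * lib[:, None]
    if batch_factors is not None:
        mean = mean * np.asarray(batch_factors)[None, :]
    # program genes carry most of their overdispersion in the shared
    # content/activity factors; only the residual is independent
    n_prog = n_genes - cfg.n_null_genes
    disp = np.concatenate([
        np.full(n_prog, cfg.program_dispersion),
        np.full(cfg.n_null_genes, cfg.dispersion)])
    counts = _nb_counts(mean, disp, rng).astype(float)

    spots = coords.copy()
    spots.insert(0, "spot_id", [f"{sample}_s{i:04d}" for i in range(n_spots)])
    spots["sample"] = sample
    spots["zone"] = zone
    spots["region"] = region
    table = SpotTable(counts=counts, genes=genes, spots=spots,
                      lattice=cfg.lattice)
    truth = spots[["spot_id", "zone", "region"]].copy()
    for pname, act in activities.items():
        truth[f"activity_{pname}"] = act
    return table, truth


def simulate_spot_pair(config: SimConfig) -> tuple[SpotTable, SpotTable,
                                                   pd.DataFrame]:
    """Two samples (STA, STB); STB carries a per-gene batch factor."""
    cfg = config.spots
    genes, _ = _gene_panel(cfg, rng_for(config.seed, "spots/genes"))
    batch = np.exp(rng_for(config.seed, "spots/batch").normal(
        0.0, cfg.batch_sdlog, size=len(genes)))
    sta, truth_a = simulate_spot_sample(config, "STA")
    stb, truth_b = simulate_spot_sample(config, "STB", batch_factors=batch)
    truth = pd.concat([truth_a, truth_b], ignore_index=True)
    return sta, stb, truth


def _balanced_zones(xy: np.ndarray, n_zones: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Centroidal Voronoi partition of the lattice into contiguous zones.

    Random anchors are relaxed by Lloyd iterations so the zones emulate
    comparably sized tissue domains rather than degenerate slivers.
    """
    anchors = xy[rng.choice(len(xy), size=n_zones, replace=False)].copy()
    for _ in range(15):
        d2 = ((xy[:, None, :] - anchors[None, :, :]) ** 2).sum(axis=2)
        zone = d2.argmin(axis=1)
        for k in range(n_zones):
            members = xy[zone == k]
            if len(members):
                anchors[k] = members.mean(axis=0)
    return zone


def simulate_program_lattice(
    seed: int,
    n_rows: int = 30,
    n_cols: int = 30,
    n_zones: int = 7,
    genes_per_program: int = 10,
    fold_change: float = 4.0,
    n_null_genes: int = 100,
    baseline: float = 2.0,
    dispersion: float = 0.2,
    library_sdlog: float = 0.3,
    lattice: str = "hex",
    layout_seed: int | None = None,
    batch_sdlog: float = 0.0,
    sample: str = "L",
) -> tuple[SpotTable, np.ndarray]:
    """Counts on a lattice whose spots split into ``n_zones`` balanced
    Voronoi zones, each expressing a disjoint gene program at ``fold_change``.

    ``layout_seed`` fixes the zone layout independently of the count noise,
    so two samples can share true zones; ``batch_sdlog > 0`` applies a
    per-gene multiplicative batch factor (drawn from ``seed``). Returns
    ``(table, true_zone_labels)``.
    """
    rng = rng_for(seed, "program_lattice")
    coords = _lattice_coords(n_rows, n_cols, lattice,
                             (100.0 * n_cols, 100.0 * n_rows))
    xy = coords[["x", "y"]].to_numpy()
    zone = _balanced_zones(
        xy, n_zones,
        rng_for(seed if layout_seed is None else layout_seed,
                "program_lattice/layout"))

    genes = [f"PROG{z}_{g}" for z in range(n_zones)
             for g in range(genes_per_program)]
    genes += [f"NULL_{i + 1:03d}" for i in range(n_null_genes)]
    n_genes = len(genes)
    fc = np.ones((len(xy), n_genes))
    for z in range(n_zones):
        cols = slice(z * genes_per_program, (z + 1) * genes_per_program)
        fc[zone == z, cols] = fold_change
    lib = np.exp(rng.normal(0.0, library_sdlog, size=len(xy)))
    mean = baseline * fc * lib[:, None]
    if batch_sdlog > 0:
        mean = mean * np.exp(rng.normal(0.0, batch_sdlog, size=n_genes))[None, :]
    counts = _nb_counts(mean, dispersion, rng).astype(float)

    spots = coords.copy()
    spots.insert(0, "spot_id", [f"{sample}_s{i:04d}" for i in range(len(xy))])
    spots["sample"] = sample
    spots["zone"] = zone.astype(str)
    spots["region"] = "none"
    return SpotTable(counts, genes, spots, lattice), zone


def simulate_feature_lattice(
    seed: int,
    n_rows: int = 40,
    n_cols: int = 40,
    n_zones: int = 3,
    separation: float = 2.0,
    n_features: int = 10,
    lattice: str = "hex",
    layout: str = "voronoi",
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Gaussian features on a lattice with contiguous zones.

    Zone means are placed so every pair is exactly ``separation`` apart in
    units of the within-zone standard deviation (identity covariance).
    Returns ``(features, true_zone_labels, spots)``.
    """
    rng = rng_for(seed, "feature_lattice")
    coords = _lattice_coords(n_rows, n_cols, lattice,
                             (100.0 * n_cols, 100.0 * n_rows))
    xy = coords[["x", "y"]].to_numpy()
    if layout == "voronoi":
        anchors = xy[rng.choice(len(xy), size=n_zones, replace=False)]
        d2 = ((xy[:, None, :] - anchors[None, :, :]) ** 2).sum(axis=2)
        zone = d2.argmin(axis=1)
    elif layout == "bands":
        zone = (coords["col"].to_numpy() * n_zones) // n_cols
    else:
        raise ValueError(f"unknown layout {layout!r}")
    if n_zones > n_features:
        raise ValueError("need n_features >= n_zones for orthogonal means")
    means = np.zeros((n_zones, n_features))
    for k in range(n_zones):
        means[k, k] = separation / np.sqrt(2.0)
    X = means[zone] + rng.standard_normal((len(xy), n_features))
    spots = coords.copy()
    spots.insert(0, "spot_id", [f"F_s{i:04d}" for i in range(len(xy))])
    spots["sample"] = "F"
    return X, zone.astype(int), spots
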