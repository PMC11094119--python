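"""Default GALT zone geometry and polygon point sampling.

Coordinates are in µm with the origin at the top-left and y increasing
downward (image convention). The default layout is a stylised lymphoid
follicle section: a lumen strip at the top, the follicle-associated
epithelium (FAE) band beneath it, the subepithelial dome (SED) directly
under the FAE, a germinal centre (GC) disc nested inside the mantle disc
deeper in the tissue, a T-cell zone at the left edge, and lamina propria
elsewhere. Overlaps are by containment only (GC inside mantle, everything
below the lumen inside the lamina propria); zone assignment resolves nesting
with a smallest-containing-polygon rule.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Point, Polygon, box


def default_zone_geometry() -> dict[str, Polygon]:
    gc_centre = (520.0, 480.0)
    return {
        "lumen": box(0.0, 0.0, 1000.0, 60.0),
        "FAE": box(150.0, 60.0, 850.0, 100.0),
        "SED": box(200.0, 100.0, 800.0, 260.0),
        "GC": Point(gc_centre).buffer(140.0, quad_segs=64),
        "mantle": Point(gc_centre).buffer(210.0, quad_segs=64),
        "T_zone": box(0.0, 100.0, 150.0, 800.0),
        "lamina_propria": box(0.0, 60.0, 1000.0, 800.0),
    }


def zone_of_points(
    points: np.ndarray,
    zones: dict[str, Polygon],
    fallback: str = "other",
) -> np.ndarray:
    """Zone name per point: smallest-area containing polygon, boundary-inclusive."""
    import shapely

    points = np.asarray(points, dtype=float)
    geoms = shapely.points(points[:, 0], points[:, 1])
    order = sorted(zones, key=lambda z: zones[z].area)
    out = np.full(len(points), fallback, dtype=object)
    for name in reversed(order):   # largest first, smaller zones overwrite
        inside = shapely.covers(zones[name], geoms)
        out[inside] = name
    return out.astype(str)


def exclusive_zone_polygons(zones: dict[str, Polygon]) -> dict[str, Polygon]:
    """Each zone polygon minus any smaller overlapping zone.

    Sampling from these guarantees a point's generated zone equals its
    geometric assignment under the smallest-containing-polygon rule (the
    mantle becomes an annulus around the GC, the lamina propria excludes
    every nested zone).
    """
    names = sorted(zones, key=lambda z: zones[z].area)
    out: dict[str, Polygon] = {}
    for i, name in enumerate(names):
        poly = zones[name]
        for smaller in names[:i]:
            if poly.intersects(zones[smaller]):
                poly = poly.difference(zones[smaller])
        out[name] = poly
    return out


def sample_points_in_polygon(
    poly: Polygon,
    n: int,
    rng: np.random.Generator,
    depth_scale: float | None = None,
) -> np.ndarray:
    """Uniform rejection sampling of ``n`` points inside ``poly``.

    If ``depth_scale`` is given, the vertical coordinate is instead drawn
    from a truncated exponential measured from the polygon's top edge, so
    point density decays with depth — used to concentrate DN2 cells just
    beneath the epithelium.
    """
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((n, 2))
    filled = 0
    attempts = 0
    while filled < n:
        attempts += 1
        if attempts > 1000:
            raise RuntimeError("polygon sampling failed to converge")
        m = max(4 * (n - filled), 64)
        xs = rng.uniform(minx, maxx, size=m)
        if depth_scale is not None:
            depth = rng.exponential(depth_scale, size=m) % (maxy - miny)
            ys = miny + depth
        else:
            ys = rng.uniform(miny, maxy, size=m)
        pts = np.column_stack([xs, ys])
        keep = np.fromiter(
            (poly.covers(Point(p)) for p in pts), dtype=bool, count=m
        )
        take = min(keep.sum(), n - filled)
        out[filled:filled + take] = pts[keep][:take]
        filled += take
    return out
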