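"""Two-channel rasters with a known signal/reference overlap fraction.

Emulates the binarise-and-mask quantification of in-situ transcript images:
a reference channel carries large disc blobs, a signal channel carries small
disc blobs of which a requested fraction lie entirely inside the reference
mask (the rest are placed clear of it). Because blobs are placed fully
inside or fully outside, the ground-truth pixel fraction equals the
requested fraction up to blob granularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimConfig, rng_for


@dataclass
class ColocRaster:
    """Channel-named 2-D pixel arrays plus optional precomputed masks."""

    channels: dict[str, np.ndarray]
    um_per_px: float = 1.0
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def _disc_mask(shape: tuple[int, int], centre: tuple[int, int],
               radius: int) -> np.ndarray:
    yy, xx = np.ogrid[0:shape[0], 0:shape[1]]
    return (yy - centre[0]) ** 2 + (xx - centre[1]) ** 2 <= radius ** 2


def simulate_coloc_raster(
    config: SimConfig,
    overlap: float = 0.3,
) -> tuple[ColocRaster, dict]:
    """Simulate a signal/reference raster pair at a requested overlap.

    Returns ``(raster, truth)`` with ``truth['overlap_fraction']`` the exact
    pixel fraction of the generated signal mask lying inside the reference
    mask, plus the binary masks themselves.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError(f"overlap must be in [0, 1], got {overlap}")
    cfg = config.raster
    rng = rng_for(config.seed, f"raster/{overlap}")
    h, w = cfg.shape
    r_sig, r_ref = cfg.signal_radius, cfg.reference_radius
    margin = r_ref + 2
    if h < 4 * margin or w < 4 * margin:
        raise ValueError("raster too small for the requested blobs")

    ref_mask = np.zeros((h, w), dtype=bool)
    ref_centres = []
    attempts = 0
    while len(ref_centres) < cfg.n_reference_blobs:
        attempts += 1
        if attempts > 10000:
            raise ValueError("raster too small to place reference blobs")
        c = (int(rng.integers(margin, h - margin)),
             int(rng.integers(margin, w - margin)))
        if all((c[0] - o[0]) ** 2 + (c[1] - o[1]) ** 2 >= (2 * r_ref + 2) ** 2
               for o in ref_centres):
            ref_centres.append(c)
            ref_mask |= _disc_mask((h, w), c, r_ref)

    n_inside = int(round(overlap * cfg.n_signal_blobs))
    sig_mask = np.zeros((h, w), dtype=bool)
    sig_centres: list[tuple[int, int]] = []

    def _free(c: tuple[int, int]) -> bool:
        return all((c[0] - o[0]) ** 2 + (c[1] - o[1]) ** 2
                   >= (2 * r_sig + 2) ** 2 for o in sig_centres)

    attempts = 0
    while len(sig_centres) < n_inside:
        attempts += 1
        if attempts > 20000:
            raise ValueError("could not place signal blobs inside reference")
        base = ref_centres[int(rng.integers(len(ref_centres)))]
        offset = rng.integers(-(r_ref - r_sig - 1), r_ref - r_sig, size=2)
        c = (int(base[0] + offset[0]), int(base[1] + offset[1]))
        if ((offset ** 2).sum() <= (r_ref - r_sig - 1) ** 2 and _free(c)):
            sig_centres.append(c)
            sig_mask |= _disc_mask((h, w), c, r_sig)

    attempts = 0
    while len(sig_centres) < cfg.n_signal_blobs:
        attempts += 1
        if attempts > 20000:
            raise ValueError("could not place signal blobs outside reference")
        c = (int(rng.integers(r_sig + 1, h - r_sig - 1)),
             int(rng.integers(r_sig + 1, w - r_sig - 1)))
        clear_of_ref = all(
            (c[0] - o[0]) ** 2 + (c[1] - o[1]) ** 2 >= (r_ref + r_sig + 2) ** 2
            for o in ref_centres)
        if clear_of_ref and _free(c):
            sig_centres.append(c)
            sig_mask |= _disc_mask((h, w), c, r_sig)

    def _render(mask: np.ndarray) -> np.ndarray:
        img = rng.normal(cfg.background_level, cfg.noise_sd, size=(h, w))
        img[mask] += cfg.foreground_level
        return np.clip(img, 0.0, None)

    raster = ColocRaster(
        channels={"signal": _render(sig_mask), "reference": _render(ref_mask)},
        um_per_px=cfg.um_per_px,
        masks={"signal": sig_mask, "reference": ref_mask},
    )
    truth = {
        "overlap_fraction": float((sig_mask & ref_mask).sum() / sig_mask.sum()),
        "signal_mask": sig_mask,
        "reference_mask": ref_mask,
        "requested": float(overlap),
    }
    return raster, truth
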