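"""Marker-expression models for the simulated cell populations.

Each cell type has a set of positive markers; raw single-cell intensities are
drawn from a two-component lognormal model — a dim "negative" population and
a bright "positive" population whose log-mean sits ``separation`` natural-log
units higher. Truth is recorded on the arcsinh-transformed scale before
spillover and batch effects are applied.

Markers may carry a ``dim`` grade (a fraction, e.g. DN2 CD11c and IEDN
E-cadherin): the positive component then sits at 55% of the separation,
reflecting populations that are bright relative to their own lineage but
well below the lineage that defines the marker (myeloid CD11c, epithelial
E-cadherin). This is what lets such cells pass the lineage gates while still
reading as marker-high within the B-cell compartment.

The subset phenotypes encode the published gating logic: DN2/3 cells are
CD27- IgD- CD21-low CD11c-high, germinal-centre cells CD38++ CD10++,
marginal-zone B cells CD27+ CD45RB+ IgM+ IgD+, intraepithelial DN (IEDN)
cells carry E-cadherin from the surrounding epithelium, and plasmablasts/
plasma cells are CD38++ CD138+ with dim CD20.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SUSPENSION_MARKERS: tuple[str, ...] = (
    "CD45RB", "IgD", "CD20", "IgA", "CD138", "CD21", "CD38", "CD10",
    "CD27", "CD24", "IgG", "IgM", "FcRL4", "CD40", "HLADR", "CD11c",
)

IMC_MARKERS: tuple[str, ...] = (
    "CD20", "CD3", "CD11c", "CD11b", "CD68", "CD31", "Ecadherin",
    "CD27", "IgD", "CD21", "CD38", "CD10", "CD45RB", "IgM", "CD138",
    "Ki67", "DNA1", "DNA2",
)

# positive markers per suspension B-cell subset; value = positive fraction
_SUSPENSION_POSITIVE: dict[str, dict[str, float]] = {
    "Naive": {"IgD": 1.0, "IgM": 1.0, "CD20": 1.0, "CD21": 1.0,
              "CD24": 1.0, "CD40": 1.0, "HLADR": 1.0},
    "MZP":   {"IgD": 1.0, "IgM": 1.0, "CD20": 1.0, "CD21": 1.0,
              "CD24": 1.0, "CD45RB": 1.0, "CD40": 1.0, "HLADR": 1.0},
    "MZB":   {"IgD": 1.0, "IgM": 1.0, "CD20": 1.0, "CD21": 1.0,
              "CD27": 1.0, "CD45RB": 1.0, "CD24": 1.0, "CD40": 1.0,
              "HLADR": 1.0},
    "Mem":   {"CD20": 1.0, "CD27": 1.0, "CD21": 1.0, "IgG": 0.8,
              "CD24": 1.0, "CD40": 1.0, "HLADR": 1.0},
    "DN1":   {"CD20": 1.0, "CD21": 1.0, "IgG": 0.7, "CD24": 1.0,
              "CD40": 1.0, "HLADR": 1.0},
    "DN2/3": {"CD20": 1.0, "CD11c": (1.0, "dim"), "IgG": 0.7, "FcRL4": 0.7,
              "HLADR": 1.0},
    "GC":    {"CD20": 1.0, "CD38": 1.0, "CD10": 1.0, "CD40": 1.0,
              "HLADR": 1.0},
    "PB/PC": {"CD27": 1.0, "CD38": 1.0, "CD138": 1.0, "IgG": 0.6,
              "CD20": 0.5},
}

# positive markers per IMC cell type (lineages + B subsets); all cells are
# DNA-positive unless flagged low-DNA by the generator
_IMC_POSITIVE: dict[str, dict[str, float]] = {
    "T":           {"CD3": 1.0, "CD27": 0.8},
    "MacDC":       {"CD11c": 1.0, "CD11b": 1.0, "CD68": 1.0},
    "Endothelial": {"CD31": 1.0},
    "Epithelial":  {"Ecadherin": 1.0},
    "Naive":       {"CD20": 1.0, "IgD": 1.0, "IgM": 1.0, "CD21": 1.0},
    "MZP":         {"CD20": 1.0, "IgD": 1.0, "IgM": 1.0, "CD21": 1.0,
                    "CD45RB": 1.0},
    "MZB":         {"CD20": 1.0, "IgD": 1.0, "IgM": 1.0, "CD21": 1.0,
                    "CD27": 1.0, "CD45RB": 1.0},
    "Mem":         {"CD20": 1.0, "CD27": 1.0, "CD21": 1.0},
    "DN1":         {"CD20": 1.0, "CD21": 1.0},
    "DN2":         {"CD20": 1.0, "CD11c": (1.0, "dim")},
    "IEDN":        {"CD20": 1.0, "Ecadherin": (1.0, "dim")},
    "GC LZ":       {"CD20": 1.0, "CD38": 1.0, "CD10": 1.0},
    "GC DZ":       {"CD20": 1.0, "CD38": 1.0, "CD10": 1.0, "Ki67": 1.0},
    "PB/PC":       {"CD27": 1.0, "CD38": 1.0, "CD138": 1.0, "CD20": 0.5},
}

B_SUBSETS_SUSPENSION = tuple(_SUSPENSION_POSITIVE)
B_SUBSETS_IMC = ("Naive", "MZP", "MZB", "Mem", "DN1", "DN2", "IEDN",
                 "GC LZ", "GC DZ", "PB/PC")
LINEAGE_OF_TYPE = {
    "T": "T", "MacDC": "MacDC", "Endothelial": "Endothelial",
    "Epithelial": "Epithelial",
    **{s: "B" for s in B_SUBSETS_IMC},
}


@dataclass
class MarkerModel:
    """Two-component lognormal intensity model, per type x marker."""

    markers: tuple[str, ...]
    positive: dict[str, dict[str, float]]
    neg_meanlog: float = 0.0
    neg_sdlog: float = 0.5
    pos_sdlog: float = 0.35
    separation: float = 3.0           # pos meanlog minus neg meanlog
    background_rate: float = 0.005     # spurious positives on negative markers
    always_positive: tuple[str, ...] = ()   # e.g. DNA channels

    #: positive-component offset multiplier per grade
    GRADES = {"pos": 1.0, "dim": 0.55, "hi": 1.3}

    def __post_init__(self) -> None:
        for ctype, profile in self.positive.items():
            for marker, spec in profile.items():
                frac, grade = self._parse(spec)
                if marker not in self.markers:
                    raise ValueError(f"{ctype}: unknown marker {marker!r}")
                if not 0.0 <= frac <= 1.0:
                    raise ValueError(f"{ctype}/{marker}: fraction {frac} outside [0,1]")
                if grade not in self.GRADES:
                    raise ValueError(f"{ctype}/{marker}: unknown grade {grade!r}")

    @staticmethod
    def _parse(spec) -> tuple[float, str]:
        if isinstance(spec, tuple):
            return float(spec[0]), spec[1]
        return float(spec), "pos"

    def sample_raw(self, cell_type: str, n: int,
                   rng: np.random.Generator) -> np.ndarray:
        """Raw (untransformed, pre-spillover) intensities, ``n x n_markers``."""
        profile = self.positive[cell_type]
        p = len(self.markers)
        pos_frac = np.full(p, self.background_rate)
        offset = np.full(p, self.separation)
        for j, m in enumerate(self.markers):
            if m in profile:
                frac, grade = self._parse(profile[m])
                pos_frac[j] = frac
                offset[j] = self.separation * self.GRADES[grade]
            elif m in self.always_positive:
                pos_frac[j] = 1.0
        is_pos = rng.random((n, p)) < pos_frac
        meanlog = np.where(is_pos, self.neg_meanlog + offset, self.neg_meanlog)
        sdlog = np.where(is_pos, self.pos_sdlog, self.neg_sdlog)
        return np.exp(rng.normal(meanlog, sdlog))


def default_suspension_model(separation: float = 3.0) -> MarkerModel:
    return MarkerModel(markers=SUSPENSION_MARKERS,
                       positive=_SUSPENSION_POSITIVE,
                       separation=separation)


def default_imc_model(separation: float = 3.0) -> MarkerModel:
    return MarkerModel(markers=IMC_MARKERS,
                       positive=_IMC_POSITIVE,
                       separation=separation,
                       always_positive=("DNA1", "DNA2"))
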