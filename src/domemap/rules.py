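"""Declarative marker-positivity rules for lineages and B-cell subsets.

A :class:`SubsetRuleSet` is an ordered list of rules, each demanding a set of
markers above threshold (``high``) and a set below (``low``). A profile (a
median marker vector of a cluster/node, or a single cell) is labelled by the
first rule whose requirements it satisfies; profiles matching no rule fall
through to the ``fallback`` label. This is a reproducible stand-in for expert
"bubble" gating: the rules encode the published subset phenotypes
(e.g. DN2: CD27- IgD- CD21-low CD11c-high; GC: CD38++ CD10++;
MZB: CD27+ CD45RB+ IgM+ IgD+) while the thresholds are fitted from the data.

Thresholds are per-marker scalars on the transformed (arcsinh) scale,
typically obtained from :func:`fit_marker_thresholds`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SubsetRule",
    "SubsetRuleSet",
    "fit_marker_thresholds",
    "default_b_subset_rules",
    "default_imc_b_subset_rules",
]


@dataclass(frozen=True)
class SubsetRule:
    name: str
    high: tuple[str, ...] = ()
    low: tuple[str, ...] = ()

    def matches(self, profile: Mapping[str, float],
                thresholds: Mapping[str, float]) -> bool:
        for m in self.high:
            if profile[m] < thresholds[m]:
                return False
        for m in self.low:
            if profile[m] >= thresholds[m]:
                return False
        return True


@dataclass(frozen=True)
class SubsetRuleSet:
    rules: tuple[SubsetRule, ...]
    fallback: str = "unclassified"

    def __post_init__(self) -> None:
        seen = set()
        for r in self.rules:
            key = (tuple(sorted(r.high)), tuple(sorted(r.low)))
            if key in seen:
                raise ValueError(f"duplicate rule definition: {r.name}")
            seen.add(key)

    @property
    def markers(self) -> tuple[str, ...]:
        out: list[str] = []
        for r in self.rules:
            for m in (*r.high, *r.low):
                if m not in out:
                    out.append(m)
        return tuple(out)

    def validate_markers(self, available: Iterable[str]) -> None:
        missing = set(self.markers) - set(available)
        if missing:
            raise ValueError(f"rules reference markers absent from panel: {sorted(missing)}")

    def classify(self, profile: Mapping[str, float],
                 thresholds: Mapping[str, float]) -> str:
        """First-match classification of a single marker profile."""
        for rule in self.rules:
            if rule.matches(profile, thresholds):
                return rule.name
        return self.fallback


def fit_marker_thresholds(
    values: "np.ndarray | object",
    markers: Sequence[str] | None = None,
    max_fit_points: int = 5000,
    min_separation: float = 0.5,
    seed: int = 0,
) -> dict[str, float]:
    """Per-marker positivity thresholds from two-component Gaussian fits.

    For each marker the transformed intensities are fitted with a
    two-component mixture; the threshold is the midpoint of the component
    means. If the fit is degenerate (components closer than
    ``min_separation`` or one nearly empty) the marker is treated as
    unimodal: all-negative if its median is low, all-positive otherwise,
    with the threshold placed just outside the data range.

    ``values`` may be a pandas DataFrame (markers from columns) or a 2-D
    array with ``markers`` giving column names.
    """
    from sklearn.mixture import GaussianMixture

    import pandas as pd

    if isinstance(values, pd.DataFrame):
        frame = values
    else:
        if markers is None:
            raise ValueError("markers required when values is an array")
        frame = pd.DataFrame(np.asarray(values), columns=list(markers))

    rng = np.random.default_rng(seed)
    thresholds: dict[str, float] = {}
    for marker in frame.columns:
        x = frame[marker].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        if x.size == 0:
            raise ValueError(f"marker {marker!r} has no finite values")
        if x.size > max_fit_points:
            x = rng.choice(x, size=max_fit_points, replace=False)
        if np.ptp(x) < 1e-9:
            thresholds[marker] = float(x[0]) + (1.0 if np.median(x) < 1.0 else -1.0)
            continue
        gm = GaussianMixture(n_components=2, n_init=2, random_state=int(seed) % (2**31))
        gm.fit(x.reshape(-1, 1))
        means = np.sort(gm.means_.ravel())
        w = gm.weights_.min()
        if (means[1] - means[0]) < min_separation or w < 0.02:
            # effectively unimodal channel
            if np.median(x) < 1.0:
                thresholds[marker] = float(x.max()) + 1.0   # nothing positive
            else:
                thresholds[marker] = float(x.min()) - 1.0   # everything positive
        else:
            thresholds[marker] = float(means.mean())
    return thresholds


def gap_thresholds(
    medians: "object",
    min_gap: float = 0.25,
    markers: Sequence[str] | None = None,
) -> dict[str, float]:
    """Positivity thresholds from the largest gap between cluster medians.

    Cluster (or tree-node) median profiles denoise single-cell variation, so
    for each marker the sorted medians split cleanly into a negative and a
    positive group wherever any cluster truly expresses it; the threshold is
    the midpoint of the first consecutive gap reaching ``min_gap``
    (transformed units) — i.e. just above the negative cloud, so clusters at
    intermediate ("dim") and full brightness both count as positive. If no
    gap reaches ``min_gap`` the marker is treated as uniformly negative
    across clusters. This is robust for markers carried by a small minority
    of cells (e.g. intraepithelial B cells' E-cadherin), where pooled
    mixture fits tend to split the negative cloud instead.
    """
    import pandas as pd

    frame = medians if isinstance(medians, pd.DataFrame) else pd.DataFrame(
        np.asarray(medians), columns=list(markers))
    out: dict[str, float] = {}
    for marker in (markers if markers is not None else frame.columns):
        vals = np.sort(frame[marker].to_numpy(dtype=float))
        if len(vals) < 2:
            out[marker] = float(vals[-1]) + 1.0
            continue
        gaps = np.diff(vals)
        big = np.flatnonzero(gaps >= min_gap)
        if len(big):
            j = int(big[0])
            out[marker] = float((vals[j] + vals[j + 1]) / 2.0)
        else:
            out[marker] = float(vals[-1]) + 1.0
    return out


def default_b_subset_rules() -> SubsetRuleSet:
    """Suspension-cytometry B-cell subset phenotypes (CD19+ pre-gated events).

    Order matters: plasmablast/plasma-cell and germinal-centre phenotypes are
    matched before the CD27/IgD quadrants so that CD38-bright populations are
    not swallowed by the double-negative rules.
    """
    return SubsetRuleSet(rules=(
        SubsetRule("PB/PC", high=("CD38", "CD138")),
        SubsetRule("GC", high=("CD38", "CD10"), low=("CD138",)),
        SubsetRule("DN2/3", high=("CD11c",), low=("CD27", "IgD", "CD21", "CD38")),
        SubsetRule("DN1", high=("CD21",), low=("CD27", "IgD", "CD11c", "CD38")),
        SubsetRule("MZB", high=("CD27", "IgD")),
        SubsetRule("MZP", high=("CD45RB", "IgD"), low=("CD27",)),
        SubsetRule("Naive", high=("IgD",), low=("CD27", "CD45RB", "CD38")),
        SubsetRule("Mem", high=("CD27",), low=("IgD", "CD38")),
        # graded fallbacks for boundary profiles missing one canonical marker
        SubsetRule("PB/PC", high=("CD38", "CD27"), low=("IgD",)),
        SubsetRule("GC", high=("CD38",), low=("CD27", "IgD")),
    ))


def default_imc_b_subset_rules() -> SubsetRuleSet:
    """Imaging-mass-cytometry B-cell subsets.

    Adds the intraepithelial DN phenotype (IEDN: double-negative B cells
    carrying E-cadherin signal from the surrounding epithelium) ahead of the
    DN1/DN2 split, and splits germinal-centre cells into dark zone
    (proliferating, Ki67-high) and light zone.
    """
    return SubsetRuleSet(rules=(
        SubsetRule("PB/PC", high=("CD38", "CD138")),
        SubsetRule("GC DZ", high=("CD38", "CD10", "Ki67"), low=("CD138",)),
        SubsetRule("GC LZ", high=("CD38", "CD10"), low=("CD138", "Ki67")),
        SubsetRule("IEDN", high=("Ecadherin",), low=("CD27", "IgD", "CD38")),
        SubsetRule("DN2", high=("CD11c",),
                   low=("CD27", "IgD", "CD21", "CD38", "Ecadherin")),
        SubsetRule("DN1", high=("CD21",),
                   low=("CD27", "IgD", "CD11c", "CD38", "Ecadherin")),
        SubsetRule("MZB", high=("CD27", "IgD")),
        SubsetRule("MZP", high=("CD45RB", "IgD"), low=("CD27",)),
        SubsetRule("Naive", high=("IgD",), low=("CD27", "CD45RB", "CD38")),
        SubsetRule("Mem", high=("CD27",), low=("IgD", "CD38")),
        # graded fallbacks for boundary profiles missing one canonical marker
        SubsetRule("PB/PC", high=("CD38", "CD27"), low=("IgD",)),
        SubsetRule("GC DZ", high=("CD38", "Ki67"), low=("CD27", "IgD")),
        SubsetRule("GC LZ", high=("CD38",), low=("CD27", "IgD", "Ki67")),
    ), fallback="none")
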