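"""Suspension-cytometry B-cell subset analysis.

The stage mirrors the classical density-normalised clustering-tree workflow:
equal numbers of events are drawn from every sample (default 9214), local
density-dependent downsampling flattens abundance differences, the retained
events are clustered into tree nodes joined by a minimum spanning tree, every
event (including those removed by downsampling) is assigned to its nearest
node, and nodes are placed into B-cell subset "bubbles" by declarative
marker rules on their median profiles. Per-sample subset proportions are then
compared between paired tissue (GALT) and blood (PBMC) samples with paired
t tests.

The 2-D embedding used for visualisation is pluggable; clustering operates
directly in transformed marker space by default, since subset recovery — not
the embedding — is what the stage asserts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .rules import SubsetRuleSet, default_b_subset_rules, gap_thresholds
from .stats import TestResult, t_test

#: markers used for tree construction (the dimensionality-reduction panel)
REDUCTION_MARKERS: tuple[str, ...] = (
    "CD45RB", "IgD", "CD20", "IgA", "CD138", "CD21", "CD38", "CD10",
    "CD27", "CD24", "IgG", "IgM",
)

DEFAULT_EVENTS_PER_SAMPLE = 9214


@dataclass
class SpadeTree:
    """Clustering-tree result: nodes, MST edges, event assignment, bubbles."""

    node_medians: pd.DataFrame        # node x marker medians over assigned events
    node_counts: pd.DataFrame         # node x sample event counts
    edges: list[tuple[int, int]]      # MST edge list over nodes
    assignment: np.ndarray            # event -> node id
    markers: tuple[str, ...]
    bubble_labels: pd.Series | None = None   # node -> subset name

    @property
    def n_nodes(self) -> int:
        return len(self.node_medians)


def subsample_equal(
    events: pd.DataFrame,
    n_per_sample: int = DEFAULT_EVENTS_PER_SAMPLE,
    seed: int = 0,
    sample_col: str = "sample_id",
) -> pd.DataFrame:
    """Draw exactly ``n_per_sample`` events per sample without replacement.

    If a sample is smaller than requested the draw is capped at its size
    (with a warning), mirroring equal-event extraction from unequal samples.
    """
    rng = np.random.default_rng(seed)
    sizes = events.groupby(sample_col).size()
    if (sizes == 0).any() or events.empty:
        raise ValueError("every sample must contain at least one event")
    if n_per_sample > sizes.min():
        warnings.warn(
            f"n_per_sample={n_per_sample} exceeds smallest sample "
            f"({sizes.min()}); capping per-sample draws", stacklevel=2)
    picks = []
    for _, idx in events.groupby(sample_col).indices.items():
        k = min(n_per_sample, len(idx))
        picks.append(np.sort(rng.choice(idx, size=k, replace=False)))
    return events.iloc[np.concatenate(picks)]


def density_dependent_downsample(
    points: np.ndarray,
    target_density: float | None = None,
    k_density: int = 15,
    seed: int = 0,
    target_percentile: float = 3.0,
    radius_factor: float = 5.0,
) -> np.ndarray:
    """Indices of points retained after density-dependent thinning.

    Local density is the number of points within a fixed radius
    (``radius_factor`` times the median ``k_density``-th nearest-neighbour
    distance). Each point is kept with probability
    ``min(1, target_density / density)``, so the expected post-thinning
    point density is uniform at the target: abundant populations are
    flattened while rare ones are retained in full. The default target is
    the ``target_percentile``-th percentile of the density distribution.
    """
    points = np.asarray(points, dtype=float)
    if len(points) <= k_density:
        raise ValueError(f"need more than k_density={k_density} points")
    if target_density is not None and target_density <= 0:
        raise ValueError("target_density must be positive")
    rng_ref = np.random.default_rng(seed)
    n_ref = min(len(points), 3000)
    ref = points[rng_ref.choice(len(points), size=n_ref, replace=False)]
    tree = cKDTree(ref)
    dists, _ = tree.query(points, k=min(k_density + 1, n_ref))
    radius = radius_factor * float(np.median(dists[:, -1]))
    # neighbour counts against the reference subsample scale the same way
    # as full counts, at a fraction of the cost
    density = np.asarray(
        tree.query_ball_point(points, r=radius, return_length=True),
        dtype=float) * (len(points) / n_ref)
    if target_density is None:
        target_density = float(np.percentile(density, target_percentile))
    keep_prob = np.minimum(1.0, target_density / density)
    rng = np.random.default_rng(seed)
    return np.flatnonzero(rng.random(len(points)) < keep_prob)


def build_spade_tree(
    events: pd.DataFrame,
    k_nodes: int = 100,
    markers: tuple[str, ...] = REDUCTION_MARKERS,
    seed: int = 0,
    downsample: bool = True,
    k_density: int = 15,
    sample_col: str = "sample_id",
    median_markers: tuple[str, ...] | None = None,
) -> SpadeTree:
    """Cluster events into tree nodes and assign every event to one node.

    Downsampled points are clustered with k-means (the density-normalised
    stand-in for the original agglomerative step, which is quadratic), a
    Euclidean minimum spanning tree joins the node centres, and all events
    are "upsampled" onto their nearest node. Node medians are recomputed
    over the full assignment and cover every marker column (``median_markers``
    defaults to all numeric columns), so bubble rules may use markers that
    did not drive the clustering (e.g. CD11c).
    """
    if k_nodes < 2:
        raise ValueError("k_nodes must be >= 2")
    X = events[list(markers)].to_numpy(dtype=float)
    if downsample and len(X) > k_density + 1:
        retained = density_dependent_downsample(
            X, k_density=k_density, seed=seed)
        if len(retained) < k_nodes:
            retained = np.arange(len(X))
    else:
        retained = np.arange(len(X))
    if len(retained) < k_nodes:
        raise ValueError(
            f"only {len(retained)} retained points for k_nodes={k_nodes}")
    km = KMeans(n_clusters=k_nodes, n_init=3, random_state=seed % (2**31))
    km.fit(X[retained])

    assignment = km.predict(X)
    if median_markers is None:
        meta = {sample_col, "donor", "compartment", "event_id"}
        median_markers = tuple(
            c for c in events.columns
            if c not in meta and pd.api.types.is_numeric_dtype(events[c]))
    M = events[list(median_markers)].to_numpy(dtype=float)
    medians = np.empty((k_nodes, len(median_markers)))
    for node in range(k_nodes):
        members = M[assignment == node]
        if len(members):
            medians[node] = np.median(members, axis=0)
        else:
            centre = km.cluster_centers_[node]
            nearest = np.argmin(np.linalg.norm(X - centre, axis=1))
            medians[node] = M[nearest]
    node_medians = pd.DataFrame(medians, columns=list(median_markers))

    counts = (pd.crosstab(assignment, events[sample_col])
              .reindex(range(k_nodes), fill_value=0))
    counts.index.name = "node"

    d = np.linalg.norm(medians[:, None, :] - medians[None, :, :], axis=2)
    mst = minimum_spanning_tree(d).tocoo()
    edges = sorted((min(i, j), max(i, j)) for i, j in zip(mst.row, mst.col))

    return SpadeTree(node_medians=node_medians, node_counts=counts,
                     edges=edges, assignment=assignment, markers=markers)


def assign_bubbles(
    tree: SpadeTree,
    rules: SubsetRuleSet | None = None,
    thresholds: dict[str, float] | None = None,
) -> SpadeTree:
    """Label every node with the first subset rule its median profile matches.

    ``thresholds`` may be supplied explicitly; by default each marker's
    threshold is the largest-gap split over the node medians
    (:func:`domemap.rules.gap_thresholds`), which separates the
    marker-positive nodes from the rest.
    """
    rules = default_b_subset_rules() if rules is None else rules
    if thresholds is None:
        missing = set(rules.markers) - set(tree.node_medians.columns)
        if missing:
            raise ValueError(f"rule markers absent from panel: {sorted(missing)}")
        thresholds = gap_thresholds(tree.node_medians, markers=rules.markers)
    rules.validate_markers(set(tree.node_medians.columns) | set(thresholds))
    missing = set(rules.markers) - set(tree.node_medians.columns)
    if missing:
        raise ValueError(f"rule markers absent from node medians: {sorted(missing)}")
    labels = tree.node_medians.apply(
        lambda row: rules.classify(row, thresholds), axis=1)
    labels.name = "bubble"
    tree.bubble_labels = labels
    return tree


def event_bubble_labels(tree: SpadeTree) -> np.ndarray:
    """Per-event subset label via each event's node bubble."""
    if tree.bubble_labels is None:
        raise ValueError("assign_bubbles has not been run")
    return tree.bubble_labels.to_numpy()[tree.assignment]


def subset_proportion_report(
    events: pd.DataFrame,
    labels: np.ndarray,
    sample_col: str = "sample_id",
    donor_col: str = "donor",
    compartment_col: str = "compartment",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample subset proportions and paired GALT-vs-PBMC tests.

    Returns ``(proportions, tests)``. Proportions sum to 1 per sample over
    labelled subsets plus the unclassified sink. Donors missing either
    compartment are excluded from the paired tests with a warning.
    """
    df = events[[sample_col, donor_col, compartment_col]].copy()
    df["subset"] = labels
    prop = (df.groupby([sample_col, donor_col, compartment_col, "subset"])
            .size().unstack(fill_value=0))
    prop = prop.div(prop.sum(axis=1), axis=0).reset_index()

    by_donor = prop.groupby(donor_col)[compartment_col].nunique()
    complete = by_donor[by_donor == 2].index
    dropped = set(by_donor.index) - set(complete)
    if dropped:
        warnings.warn(f"donors missing a compartment excluded: {sorted(dropped)}",
                      stacklevel=2)
    paired = prop[prop[donor_col].isin(complete)]
    subsets = [c for c in prop.columns
               if c not in (sample_col, donor_col, compartment_col)]
    rows = []
    for subset in subsets:
        wide = paired.pivot_table(index=donor_col, columns=compartment_col,
                                  values=subset, fill_value=0.0)
        if not {"GALT", "PBMC"} <= set(wide.columns) or len(wide) < 2:
            continue
        res: TestResult = t_test(wide["GALT"], wide["PBMC"], mode="paired")
        rows.append({
            "subset": subset,
            "galt_mean": float(wide["GALT"].mean()),
            "pbmc_mean": float(wide["PBMC"].mean()),
            "statistic": res.statistic,
            "df": res.df,
            "p_value": res.p_value,
            "n_donors": len(wide),
            "degenerate": res.degenerate,
        })
    return prop, pd.DataFrame(rows)


@dataclass
class CytofResult:
    tree: SpadeTree
    events: pd.DataFrame
    event_labels: np.ndarray
    proportions: pd.DataFrame
    tests: pd.DataFrame
    thresholds: dict[str, float]


def run_cytof_stage(
    events: pd.DataFrame,
    n_per_sample: int = DEFAULT_EVENTS_PER_SAMPLE,
    k_nodes: int = 100,
    rules: SubsetRuleSet | None = None,
    markers: tuple[str, ...] = REDUCTION_MARKERS,
    seed: int = 0,
) -> CytofResult:
    """End-to-end suspension stage on a combined event table."""
    rules = default_b_subset_rules() if rules is None else rules
    sub = subsample_equal(events, n_per_sample, seed=seed).reset_index(drop=True)
    tree = build_spade_tree(sub, k_nodes=k_nodes, markers=markers, seed=seed)
    assign_bubbles(tree, rules)
    thresholds = gap_thresholds(tree.node_medians, markers=rules.markers)
    labels = event_bubble_labels(tree)
    proportions, tests = subset_proportion_report(sub, labels)
    return CytofResult(tree=tree, events=sub, event_labels=labels,
                       proportions=proportions, tests=tests,
                       thresholds=thresholds)
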