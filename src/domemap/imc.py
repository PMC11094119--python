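"""Segmented-image cytometry: QC, compensation, gating, propagation, subsets.

The stage consumes per-cell mean channel intensities from segmented ROIs and
mirrors the standard single-cell IMC workflow: size/DNA quality control,
spillover compensation by nonnegative least squares, per-image threshold
gating with negative gates enforcing mutually exclusive lineage calls,
random-forest propagation of labels to unassigned cells, batch integration
of B-cell marker intensities across ROIs, and clustering of the corrected
embedding into named B-cell subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier

from .rules import (SubsetRuleSet, default_imc_b_subset_rules,
                    fit_marker_thresholds, gap_thresholds)
from .stats import arcsinh_transform

LINEAGE_GATE_CHANNELS = ("CD20", "CD3", "CD11c", "CD11b", "CD68", "CD31",
                         "Ecadherin")

#: markers carried into B-cell batch integration; E-cadherin is included
#: because intraepithelial B cells carry epithelial signal
B_CELL_MARKERS = ("CD20", "CD27", "IgD", "CD21", "CD38", "CD10", "CD45RB",
                  "IgM", "CD138", "CD11c", "Ki67", "Ecadherin")


@dataclass(frozen=True)
class Gate:
    """One lineage gate: positive channels with any/all semantics."""

    label: str
    channels: tuple[str, ...]
    semantics: str = "all"            # "all" or "any"

    def matches(self, transformed: pd.DataFrame,
                thresholds: dict[str, float]) -> np.ndarray:
        cols = [transformed[c].to_numpy() >= thresholds[c]
                for c in self.channels]
        stack = np.column_stack(cols)
        return stack.all(axis=1) if self.semantics == "all" else stack.any(axis=1)


@dataclass
class GatingScheme:
    gates: tuple[Gate, ...] = (
        Gate("B", ("CD20",)),
        Gate("T", ("CD3",)),
        Gate("MacDC", ("CD11c", "CD11b", "CD68"), semantics="any"),
        Gate("Endothelial", ("CD31",)),
        Gate("Epithelial", ("Ecadherin",)),
    )
    bt_neighbour_channels: tuple[str, str] = ("CD20", "CD3")

    @property
    def channels(self) -> tuple[str, ...]:
        out: list[str] = []
        for g in self.gates:
            for c in g.channels:
                if c not in out:
                    out.append(c)
        return tuple(out)


@dataclass
class PropagationReport:
    split: float
    accuracy: float
    per_class_accuracy: dict[str, float]
    n_propagated: int
    dropped_classes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.split < 1.0:
            raise ValueError("split fraction must be in (0, 1)")
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must be in [0, 1]")


def qc_filter(
    cells: pd.DataFrame,
    min_area_px: int = 11,
    dna_channels: tuple[str, ...] = ("DNA1", "DNA2"),
    dna_percentile: float = 1.0,
    dna_floor: float = 1.0,
    roi_col: str = "roi",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove small and DNA-negative cells.

    A cell fails if its area is below ``min_area_px`` or its total DNA signal
    falls below the per-ROI threshold (the ``dna_percentile``-th percentile
    of the ROI's DNA distribution, or the absolute ``dna_floor``, whichever
    is higher). Returns the retained table and a per-ROI removal log.
    """
    missing = [c for c in dna_channels if c not in cells.columns]
    if "area_px" not in cells.columns or missing:
        raise ValueError(f"cells need area_px and DNA channels; missing {missing}")
    dna = cells[list(dna_channels)].sum(axis=1)
    small = cells["area_px"] < min_area_px
    low_dna = pd.Series(False, index=cells.index)
    for _, idx in cells.groupby(roi_col).indices.items():
        idx = cells.index[idx]
        thr = max(float(np.percentile(dna.loc[idx], dna_percentile)), dna_floor)
        low_dna.loc[idx] = dna.loc[idx] < thr
    removed = small | low_dna
    log = (pd.DataFrame({
        roi_col: cells[roi_col], "small": small,
        "low_dna": low_dna & ~small, "removed": removed})
        .groupby(roi_col).sum().reset_index())
    kept = cells.loc[~removed].copy()
    if kept.empty:
        warnings.warn("QC removed every cell; downstream stages will refuse",
                      stacklevel=2)
    return kept, log


def compensate_spillover(
    observed: np.ndarray | pd.DataFrame,
    S: np.ndarray | pd.DataFrame,
) -> np.ndarray | pd.DataFrame:
    """Undo channel spillover per cell: solve ``observed = x @ S`` with x >= 0.

    A fast unconstrained solve handles the bulk; rows driven negative by
    noise are re-solved with nonnegative least squares, so compensated
    intensities are never negative.
    """
    is_frame = isinstance(observed, pd.DataFrame)
    if is_frame and isinstance(S, pd.DataFrame):
        if list(observed.columns) != list(S.index):
            S = S.loc[observed.columns, observed.columns]
    Sm = np.asarray(S, dtype=float)
    obs = np.asarray(observed, dtype=float)
    cond = np.linalg.cond(Sm)
    if cond > 1e8:
        raise ValueError(
            f"spillover matrix ill-conditioned (cond={cond:.3g}); "
            "check near-duplicate channels")
    x = np.linalg.solve(Sm.T, obs.T).T
    bad = np.flatnonzero((x < -1e-9).any(axis=1))
    for i in bad:
        x[i], _ = nnls(Sm.T, obs[i])
    x = np.clip(x, 0.0, None)
    if is_frame:
        return pd.DataFrame(x, index=observed.index, columns=observed.columns)
    return x


def fit_gate_thresholds(
    transformed: pd.DataFrame,
    channels: tuple[str, ...],
    roi_col: str = "roi",
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Per-image, per-channel positivity thresholds from mixture fits."""
    out: dict[str, dict[str, float]] = {}
    for roi, idx in transformed.groupby(roi_col).indices.items():
        block = transformed.iloc[idx]
        out[str(roi)] = fit_marker_thresholds(block[list(channels)], seed=seed)
    return out


def gate_cells(
    cells: pd.DataFrame,
    transformed: pd.DataFrame,
    scheme: GatingScheme | None = None,
    thresholds: dict[str, dict[str, float]] | None = None,
    roi_col: str = "roi",
    seed: int = 0,
) -> pd.Series:
    """Mutually exclusive lineage gating per image.

    Every cell is evaluated against every gate; exactly one match labels the
    cell, zero or multiple matches (including the CD20+CD3+ B-T neighbour
    profile) leave it unassigned. Evaluation-order independent by
    construction.
    """
    scheme = GatingScheme() if scheme is None else scheme
    missing = set(scheme.channels) - set(transformed.columns)
    if missing:
        raise ValueError(f"gate channels missing from data: {sorted(missing)}")
    if thresholds is None:
        thresholds = fit_gate_thresholds(
            pd.concat([cells[[roi_col]], transformed], axis=1),
            scheme.channels, roi_col=roi_col, seed=seed)
    labels = pd.Series("unassigned", index=cells.index, dtype=object)
    for roi, idx in cells.groupby(roi_col).indices.items():
        idx = cells.index[idx]
        block = transformed.loc[idx]
        thr = thresholds[str(roi)]
        match = np.zeros(len(idx), dtype=int)
        roi_labels = np.full(len(idx), "unassigned", dtype=object)
        for gate in scheme.gates:
            hit = gate.matches(block, thr)
            roi_labels = np.where(hit & (match == 0), gate.label, roi_labels)
            match += hit.astype(int)
        b, t = scheme.bt_neighbour_channels
        bt = ((block[b].to_numpy() >= thr[b]) &
              (block[t].to_numpy() >= thr[t]))
        roi_labels[(match != 1) | bt] = "unassigned"
        labels.loc[idx] = roi_labels
    return labels


def propagate_labels(
    transformed: pd.DataFrame,
    gated: pd.Series,
    split: float = 0.7,
    seed: int = 0,
    min_class_size: int = 10,
    classifier: str = "knn",
    n_estimators: int = 500,
    n_neighbors: int = 25,
) -> tuple[pd.Series, PropagationReport]:
    """Train a supervised classifier on gated cells and label the rest.

    Gated labels are never overwritten; held-out accuracy is computed on the
    30% test split of the gated cells only. The default classifier is
    distance-weighted k-nearest-neighbours, which extrapolates to the
    mixed-marker profiles (e.g. CD20+CD11c-dim DN2 cells) that mutual
    exclusion leaves unassigned far better than axis-aligned tree ensembles;
    ``classifier="random_forest"`` selects the tree ensemble instead.
    """
    gated = gated.astype(object)
    labelled = gated[gated != "unassigned"]
    class_sizes = labelled.value_counts()
    dropped = tuple(class_sizes[class_sizes < min_class_size].index)
    if dropped:
        warnings.warn(f"classes below min size dropped from training: {dropped}",
                      stacklevel=2)
        labelled = labelled[~labelled.isin(dropped)]
    if labelled.nunique() < 2:
        raise ValueError("need >= 2 gated classes to propagate")
    X = transformed.loc[labelled.index].to_numpy()
    y = labelled.to_numpy()
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=split, random_state=seed % (2**31), stratify=y)
    if classifier == "knn":
        clf = KNeighborsClassifier(n_neighbors=n_neighbors, weights="distance")
    elif classifier == "random_forest":
        clf = RandomForestClassifier(
            n_estimators=n_estimators, max_features="sqrt",
            random_state=seed % (2**31), n_jobs=1)
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    clf.fit(X_tr, y_tr)
    pred_te = clf.predict(X_te)
    acc = float((pred_te == y_te).mean())
    per_class = {
        cls: float((pred_te[y_te == cls] == cls).mean())
        for cls in np.unique(y_te)
    }
    out = gated.copy()
    unassigned = gated.index[gated == "unassigned"]
    if len(unassigned):
        out.loc[unassigned] = clf.predict(
            transformed.loc[unassigned].to_numpy())
    report = PropagationReport(split=split, accuracy=acc,
                               per_class_accuracy=per_class,
                               n_propagated=int(len(unassigned)),
                               dropped_classes=dropped)
    return out, report


def integrate_batches(
    features: np.ndarray | pd.DataFrame,
    batches: np.ndarray,
    n_pcs: int = 10,
    n_clusters: int = 8,
    max_iter: int = 10,
    theta: float = 1.0,
    tol: float = 1e-6,
    seed: int = 0,
) -> np.ndarray:
    """Batch-corrected PCA embedding by iterative matched-centroid shifts.

    PCA of the standardised feature matrix is followed by rounds of soft
    k-means and linear per-batch corrections with two regimes:

    * clusters whose soft membership straddles batches ("mixed", measured by
      batch evenness) receive per-cluster, per-batch centroid shifts — this
      is the diversity-weighted soft-clustering correction of
      Harmony-style integration;
    * if a round finds no mixed cluster at all (a batch offset larger than
      the cluster spacing), mutually nearest batch-pure cluster pairs vote
      on one rigid per-batch shift (component-wise median), which aligns the
      batches enough for the per-cluster regime to take over.

    Batch-pure clusters are never moved by the per-cluster regime, so
    populations genuinely unique to one batch are not collapsed onto
    another batch's populations. With a single batch the embedding is
    returned uncorrected.
    """
    X = np.asarray(features, dtype=float)
    batches = np.asarray(batches)
    uniq = np.unique(batches)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    n_pcs = min(n_pcs, X.shape[1], X.shape[0])
    Z = PCA(n_components=n_pcs, random_state=seed % (2**31)).fit_transform(
        (X - mu) / sd)
    if len(uniq) < 2:
        warnings.warn("single batch: returning uncorrected embedding",
                      stacklevel=2)
        return Z
    onehot = np.column_stack([batches == b for b in uniq]).astype(float)
    prop = onehot.mean(axis=0)
    n_batches = len(uniq)
    k = min(n_clusters, len(Z))
    km = KMeans(n_clusters=k, n_init=3,
                random_state=seed % (2**31)).fit(Z)
    centers = km.cluster_centers_
    from scipy.spatial.distance import pdist, squareform

    spacing = np.median(pdist(centers)) if k > 1 else 1.0
    sigma2 = max((0.25 * spacing) ** 2, 1e-12)

    def batch_gap(emb: np.ndarray) -> float:
        means = np.vstack([emb[batches == b].mean(axis=0) for b in uniq])
        return float(pdist(means).max()) if len(means) > 1 else 0.0

    best_Z = Z.copy()
    best_gap = batch_gap(Z)
    for _ in range(max_iter):
        d2 = ((Z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        logR = -d2 / (2 * sigma2)
        logR -= logR.max(axis=1, keepdims=True)
        R = np.exp(logR)
        R /= R.sum(axis=1, keepdims=True)
        # diversity weighting shapes the clustering only
        O = onehot.T @ R
        E = prop[:, None] * R.sum(axis=0)[None, :]
        R_div = R * (onehot @ ((E + 1) / (O + 1)) ** theta)
        R_div /= R_div.sum(axis=1, keepdims=True)
        centers = (R_div.T @ Z) / np.maximum(R_div.sum(axis=0), 1e-12)[:, None]

        O = onehot.T @ R
        share = O / np.maximum(O.sum(axis=0), 1e-12)
        evenness = (1.0 - share.max(axis=0)) / (1.0 - 1.0 / n_batches)
        batch_centers = {}
        for bi, b in enumerate(uniq):
            mask = batches == b
            w = R[mask]
            bc = (w.T @ Z[mask]) / np.maximum(w.sum(axis=0), 1e-12)[:, None]
            bc[w.sum(axis=0) < 1e-8] = np.nan
            batch_centers[b] = bc

        correction = np.zeros_like(Z)
        if (evenness > 0.2).any():
            mass = O.sum(axis=0)
            w_k = evenness * mass
            for b in uniq:
                mask = batches == b
                delta = np.nan_to_num(batch_centers[b] - centers)
                # consensus shift from mixed clusters, inherited by pure
                # ones so a large offset is not pinned by its flanks
                consensus = (w_k[:, None] * delta).sum(axis=0) / w_k.sum()
                blended = (evenness[:, None] * delta
                           + (1 - evenness[:, None]) * consensus)
                correction[mask] = R[mask] @ blended
        else:
            # batches fully separated: rigid alignment from mutually
            # nearest pure-cluster pairs
            ref = uniq[0]
            hard = share.argmax(axis=0)
            for bi, b in enumerate(uniq[1:], start=1):
                mine = np.flatnonzero(hard == bi)
                theirs = np.flatnonzero(hard == 0)
                if len(mine) == 0 or len(theirs) == 0:
                    continue
                diffs = []
                for ci in mine:
                    d_ct = np.linalg.norm(
                        centers[theirs] - centers[ci], axis=1)
                    cj = theirs[int(np.argmin(d_ct))]
                    back = np.linalg.norm(centers[mine] - centers[cj], axis=1)
                    if mine[int(np.argmin(back))] == ci:
                        diffs.append(centers[ci] - centers[cj])
                if diffs:
                    shift = np.median(np.vstack(diffs), axis=0)
                    correction[batches == b] = shift
        Z = Z - correction
        # do-no-harm: a correction must never widen the batch separation
        # (beyond the unidentifiable fully-disjoint regime this cannot help)
        gap = batch_gap(Z)
        if gap > best_gap * 1.05 + 1e-9:
            Z = best_Z
            break
        if gap < best_gap:
            best_gap = gap
            best_Z = Z.copy()
        if float(np.abs(correction).max()) < tol:
            break
    return best_Z if batch_gap(Z) > best_gap else Z


def cluster_and_classify_b_cells(
    corrected: np.ndarray,
    transformed: pd.DataFrame,
    rules: SubsetRuleSet | None = None,
    k: int = 20,
    seed: int = 0,
    thresholds: dict[str, float] | None = None,
) -> tuple[pd.Series, np.ndarray, pd.DataFrame]:
    """Cluster the corrected B-cell embedding and name clusters by rules.

    Returns ``(labels, coords2d, cluster_medians)``: per-cell subset labels
    from the first rule matching each cluster's median transformed profile
    (unmatched clusters are labelled "none"), the first two embedding
    dimensions for visualisation, and the median table. Positivity
    thresholds default to the largest-gap split over the cluster medians
    themselves (see :func:`domemap.rules.gap_thresholds`).
    """
    rules = default_imc_b_subset_rules() if rules is None else rules
    if k < 1:
        raise ValueError("k must be >= 1")
    n_rule_subsets = len({r.name for r in rules.rules})
    if k < n_rule_subsets:
        warnings.warn(f"k={k} below number of rule subsets ({n_rule_subsets}); "
                      "subsets may merge", stacklevel=2)
    km = KMeans(n_clusters=min(k, len(corrected)), n_init=3,
                random_state=seed % (2**31)).fit(corrected)
    member = km.labels_
    medians = transformed.groupby(member).median()
    if thresholds is None:
        thresholds = gap_thresholds(medians, markers=rules.markers)
    names = {c: rules.classify(medians.loc[c], thresholds)
             for c in medians.index}
    labels = pd.Series([names[c] for c in member],
                       index=transformed.index, name="b_subset")
    return labels, corrected[:, :2], medians


@dataclass
class ImcResult:
    cells: pd.DataFrame               # QC-passed cells
    transformed: pd.DataFrame         # compensated arcsinh intensities
    qc_log: pd.DataFrame
    lineage: pd.Series
    propagation: PropagationReport
    b_subset: pd.Series               # indexed by B-cell rows
    b_embedding: np.ndarray
    cluster_medians: pd.DataFrame


def run_imc_stage(
    cells: pd.DataFrame,
    spillover: pd.DataFrame,
    channels: tuple[str, ...],
    min_area_px: int = 11,
    split: float = 0.7,
    cofactor: float = 5.0,
    k_b_clusters: int = 20,
    seed: int = 0,
) -> ImcResult:
    """End-to-end segmented-image stage on a multi-ROI cell table."""
    kept, qc_log = qc_filter(cells, min_area_px=min_area_px)
    if kept.empty:
        raise ValueError("no cells passed QC")
    compensated = compensate_spillover(kept[list(channels)], spillover)
    transformed = pd.DataFrame(
        arcsinh_transform(compensated.to_numpy(), cofactor),
        index=kept.index, columns=list(channels))
    gated = gate_cells(kept, transformed, seed=seed)
    lineage, report = propagate_labels(transformed, gated, split=split,
                                       seed=seed)
    b_mask = lineage == "B"
    b_t = transformed.loc[b_mask, list(B_CELL_MARKERS)]
    corrected = integrate_batches(
        b_t, kept.loc[b_mask, "roi"].to_numpy(), seed=seed)
    b_subset, coords, medians = cluster_and_classify_b_cells(
        corrected, b_t, k=k_b_clusters, seed=seed)
    return ImcResult(cells=kept, transformed=transformed, qc_log=qc_log,
                     lineage=lineage, propagation=report, b_subset=b_subset,
                     b_embedding=coords, cluster_medians=medians)
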