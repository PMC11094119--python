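"""Spot-level spatial transcriptomics.

Log-normalisation, highly-variable-gene selection and PCA; a lattice
neighbour graph; spatially regularised clustering by Gibbs sampling under a
Potts prior (the full conditional for spot *i* is proportional to
``N(pc_i; mu_k, sigma^2 I) * exp(gamma * n_i(k) / deg_i)`` where ``n_i(k)``
counts neighbours currently labelled *k*); a pseudo-likelihood tuning curve
over the cluster count q with an advisory elbow; marker-score selection of
the lymphoid cluster; batch-corrected subclustering across samples; region
differential expression (Wilcoxon with log-fold-change and minimum
expression-fraction filters, Bonferroni corrected over all genes); and
gene-gene Spearman correlation matrices with Holm adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .stats import adjust_pvalues, spearman_correlation, wilcoxon_rank_sum
from .synth.spots import SpotTable

LYMPHOID_MARKERS = ("MS4A1", "IGHD", "IGHM", "CD19")

#: gene list for the autoimmunity-associated correlation matrix
SLE_GENES = ("C1QB", "C1QA", "C1R", "C1S", "C3", "DNASE1L3", "ACP2", "AGER",
             "CTBB", "DNASE1", "FAS", "TMEM173")


@dataclass
class Preprocessed:
    lognorm: np.ndarray               # spots x genes, log1p CPM-scaled
    genes: list[str]
    hvg_idx: np.ndarray
    pcs: np.ndarray                   # spots x n_pcs
    kept_spots: np.ndarray            # indices into the input table


@dataclass
class SpotGraph:
    """Symmetric lattice adjacency with a fixed node order."""

    neighbours: list[np.ndarray]
    lattice: str

    @property
    def n_spots(self) -> int:
        return len(self.neighbours)

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(n) for n in self.neighbours])

    def edge_array(self) -> np.ndarray:
        return np.array([(i, j) for i, nb in enumerate(self.neighbours)
                         for j in nb if i < j])


@dataclass
class PottsModelState:
    pcs: np.ndarray
    q: int
    gamma: float
    means: np.ndarray | None = None
    sigma2: float | None = None
    labels: np.ndarray | None = None
    trace: list[float] = field(default_factory=list)
    label_samples: np.ndarray | None = None
    seed: int = 0


def log_normalise(counts: np.ndarray, scale: float = 1e4) -> np.ndarray:
    """``log1p(count / spot_total * scale)`` per spot."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(counts / totals * scale)


def select_hvgs(lognorm: np.ndarray, n_hvg: int, n_bins: int = 20) -> np.ndarray:
    """Indices of the top ``n_hvg`` genes by binned standardised dispersion.

    Dispersion (variance/mean of the log-normalised values) is z-scored
    within 20 bins of gene mean, so highly expressed genes do not dominate.
    Constant genes have statistic -inf and are never selected.
    """
    mean = lognorm.mean(axis=0)
    var = lognorm.var(axis=0)
    disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    order = np.argsort(mean)
    stat = np.full(len(mean), -np.inf)
    bins = np.array_split(order, min(n_bins, len(mean)))
    for b in bins:
        d = disp[b]
        sd = d.std()
        stat[b] = (d - d.mean()) / sd if sd > 0 else 0.0
    stat[var == 0] = -np.inf
    n_hvg = min(n_hvg, int((var > 0).sum()))
    return np.sort(np.argsort(stat)[::-1][:n_hvg])


def preprocess_spots(
    table: SpotTable,
    n_hvg: int = 2000,
    n_pcs: int = 15,
    scale: float = 1e4,
    seed: int = 0,
    scale_genes: bool = True,
) -> Preprocessed:
    """Log-normalise, select HVGs, and compute PCA.

    Genes are standardised (zero mean, unit variance) before PCA by
    default: on targeted panels much smaller than a whole transcriptome the
    HVG cut retains everything, and without standardisation sparse
    low-count genes dominate the log-scale variance and bury the
    coordinated zone programs.
    """
    counts = np.asarray(table.counts, dtype=float)
    totals = counts.sum(axis=1)
    kept = np.flatnonzero(totals > 0)
    if len(kept) < len(counts):
        warnings.warn(f"removed {len(counts) - len(kept)} zero-count spots",
                      stacklevel=2)
    counts = counts[kept]
    if len(counts) < n_pcs:
        raise ValueError("need at least n_pcs spots")
    lognorm = log_normalise(counts, scale)
    hvg = select_hvgs(lognorm, n_hvg)
    n_pcs = min(n_pcs, len(hvg))
    sub = lognorm[:, hvg] - lognorm[:, hvg].mean(axis=0)
    if scale_genes:
        sub = sub / np.maximum(lognorm[:, hvg].std(axis=0), 1e-8)
    pcs = PCA(n_components=n_pcs, random_state=seed % (2**31)).fit_transform(sub)
    return Preprocessed(lognorm=lognorm, genes=list(table.genes),
                        hvg_idx=hvg, pcs=pcs, kept_spots=kept)


def build_spot_graph(spots: pd.DataFrame, lattice: str = "hex") -> SpotGraph:
    """Neighbour graph from array (row, col) coordinates.

    Hex (odd-row offset): 6 neighbours for interior spots; square: 4.
    """
    rows = spots["row"].to_numpy(dtype=int)
    cols = spots["col"].to_numpy(dtype=int)
    if "sample" in spots.columns and spots["sample"].nunique() > 1:
        keys = list(zip(spots["sample"], rows, cols))
    else:
        keys = list(zip(rows, cols))
    index = {}
    for i, k in enumerate(keys):
        if k in index:
            raise ValueError(f"duplicate array coordinate {k}")
        index[k] = i
    if lattice == "hex":
        def offsets(r):
            par = r % 2
            return ((0, -1), (0, 1), (-1, par - 1), (-1, par),
                    (1, par - 1), (1, par))
    elif lattice == "square":
        def offsets(r):
            return ((0, -1), (0, 1), (-1, 0), (1, 0))
    else:
        raise ValueError(f"unknown lattice {lattice!r}")
    neighbours: list[np.ndarray] = []
    for i, k in enumerate(keys):
        *prefix, r, c = k if len(k) == 3 else (None, *k)
        nb = []
        for dr, dc in offsets(r):
            kk = (prefix[0], r + dr, c + dc) if prefix and prefix[0] is not None \
                else (r + dr, c + dc)
            j = index.get(kk)
            if j is not None:
                nb.append(j)
        neighbours.append(np.array(nb, dtype=int))
    return SpotGraph(neighbours=neighbours, lattice=lattice)


def _colour_classes(graph: SpotGraph) -> list[np.ndarray]:
    """Greedy graph colouring so each class can be Gibbs-updated in parallel."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(graph.n_spots))
    g.add_edges_from((i, j) for i, nb in enumerate(graph.neighbours)
                     for j in nb if i < j)
    colouring = nx.greedy_color(g, strategy="largest_first")
    n_colours = max(colouring.values(), default=0) + 1
    return [np.array([v for v, c in colouring.items() if c == colour])
            for colour in range(n_colours)]


def potts_cluster(
    pcs: np.ndarray,
    graph: SpotGraph,
    q: int,
    gamma: float = 4.0,
    iterations: int = 1000,
    burn_in: int = 200,
    seed: int = 0,
    state: PottsModelState | None = None,
) -> PottsModelState:
    """Gibbs sampling of spot labels under a Gaussian likelihood and Potts prior.

    Shared spherical covariance; component means and the variance are
    re-estimated each sweep; labels are updated by colour classes (valid
    parallel Gibbs). The returned labels are the per-spot marginal mode over
    post-burn-in samples. ``gamma=0`` reduces to a plain Gaussian-mixture
    Gibbs sampler.
    """
    X = np.asarray(pcs, dtype=float)
    n, d = X.shape
    if q < 1:
        raise ValueError("q must be >= 1")
    if q > n:
        raise ValueError(f"q={q} exceeds number of spots {n}")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    rng = np.random.default_rng(seed % (2**31))
    if q == 1:
        labels = np.zeros(n, dtype=int)
        mu = X.mean(axis=0, keepdims=True)
        sigma2 = float(np.mean((X - mu) ** 2))
        return PottsModelState(pcs=X, q=1, gamma=gamma, means=mu,
                               sigma2=max(sigma2, 1e-9),
                               labels=labels, trace=[], seed=seed)

    km = KMeans(n_clusters=q, n_init=3, random_state=seed % (2**31)).fit(X)
    labels = km.labels_.copy()
    means = km.cluster_centers_.copy()
    sigma2 = max(float(np.mean((X - means[labels]) ** 2)), 1e-9)
    colours = _colour_classes(graph)
    degrees = np.maximum(graph.degrees, 1)
    # sparse adjacency for fast neighbour-label counting
    edges = graph.edge_array()
    if len(edges):
        A = sparse.coo_matrix(
            (np.ones(2 * len(edges)),
             (np.concatenate([edges[:, 0], edges[:, 1]]),
              np.concatenate([edges[:, 1], edges[:, 0]]))),
            shape=(n, n)).tocsr()
    else:
        A = sparse.csr_matrix((n, n))

    trace: list[float] = []
    samples = np.empty((max(iterations - burn_in, 0), n), dtype=np.int32)
    onehot = np.zeros((n, q))
    for sweep in range(iterations):
        onehot[:] = 0.0
        onehot[np.arange(n), labels] = 1.0
        for cls in colours:
            if len(cls) == 0:
                continue
            neigh_counts = (A[cls] @ onehot)
            d2 = ((X[cls, None, :] - means[None, :, :]) ** 2).sum(axis=2)
            logp = (-d2 / (2 * sigma2)
                    + gamma * neigh_counts / degrees[cls, None])
            logp -= logp.max(axis=1, keepdims=True)
            p = np.exp(logp)
            p /= p.sum(axis=1, keepdims=True)
            u = rng.random(len(cls))
            new = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
            labels[cls] = new
            onehot[cls] = 0.0
            onehot[cls, new] = 1.0
        # conjugate-style parameter refresh
        for k in range(q):
            members = X[labels == k]
            if len(members):
                means[k] = members.mean(axis=0)
            else:
                means[k] = X[rng.integers(n)]
        sigma2 = max(float(np.mean((X - means[labels]) ** 2)), 1e-9)
        neigh_same = (A @ onehot)[np.arange(n), labels]
        pll = (-((X - means[labels]) ** 2).sum() / (2 * sigma2)
               - n * d / 2 * np.log(2 * np.pi * sigma2)
               + gamma * float((neigh_same / degrees).sum()))
        trace.append(float(pll))
        if sweep >= burn_in:
            samples[sweep - burn_in] = labels
    if len(samples):
        final = np.empty(n, dtype=int)
        for i in range(n):
            final[i] = np.bincount(samples[:, i], minlength=q).argmax()
    else:
        final = labels
    return PottsModelState(pcs=X, q=q, gamma=gamma, means=means,
                           sigma2=sigma2, labels=final, trace=trace,
                           label_samples=samples, seed=seed)


def tune_q(
    pcs: np.ndarray,
    graph: SpotGraph,
    q_range: range | list[int] = range(2, 11),
    gamma: float = 4.0,
    iterations: int = 60,
    burn_in: int = 30,
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Negative pseudo-log-likelihood curve over q with an advisory elbow.

    Short chains are run per q; the suggested q is the point of maximum
    discrete curvature (largest drop in marginal improvement) on the curve.
    The full curve is always returned — the choice of q remains an
    inspection decision, and the caller may override it.
    """
    qs = sorted(set(int(q) for q in q_range))
    if len(qs) < 3:
        raise ValueError("q_range must contain >= 3 values")
    rows = []
    for q in qs:
        try:
            st = potts_cluster(pcs, graph, q, gamma=gamma,
                               iterations=iterations, burn_in=burn_in,
                               seed=seed)
            npll = -float(np.mean(st.trace[burn_in:])) if st.trace else np.nan
            rows.append({"q": q, "npll": npll, "failed": False})
        except Exception as exc:        # noqa: BLE001 - per-q failures flagged
            warnings.warn(f"q={q} failed: {exc}", stacklevel=2)
            rows.append({"q": q, "npll": np.nan, "failed": True})
    curve = pd.DataFrame(rows)
    ok = curve[~curve["failed"] & curve["npll"].notna()]
    suggested = _elbow(ok["q"].to_numpy(), ok["npll"].to_numpy())
    return curve, suggested


def _elbow(qs: np.ndarray, npll: np.ndarray) -> int:
    """Maximum-curvature point of a decreasing tuning curve.

    A curve that ends no lower than it starts carries no evidence of
    structure beyond the smallest q (extra components only pay the spatial
    prior's penalty), so the smallest q is suggested. Otherwise interior
    points are scored by the second difference of the min-max normalised
    curve — the largest drop in marginal improvement.
    """
    if len(qs) < 3:
        return int(qs[np.argmin(npll)])
    span = float(npll.max() - npll.min())
    scale = max(abs(float(np.median(npll))), 1e-12)
    if span / scale < 1e-4 or span == 0 or npll[-1] >= npll[0]:
        return int(qs[0])
    y = (npll - npll.min()) / span
    curv = y[:-2] - 2 * y[1:-1] + y[2:]
    return int(qs[1:-1][int(np.argmax(curv))])


def select_lymphoid_cluster(
    labels: np.ndarray,
    lognorm: np.ndarray,
    genes: list[str],
    markers: tuple[str, ...] = LYMPHOID_MARKERS,
    tie_tolerance: float = 0.05,
) -> tuple[int, np.ndarray, pd.DataFrame]:
    """Cluster with the highest mean lymphoid marker score.

    Returns ``(cluster_id, spot_mask, score_table)``. A runner-up within
    ``tie_tolerance`` of the winner's score flags a tie: both are reported
    and the caller must choose explicitly.
    """
    present = [m for m in markers if m in genes]
    if not present:
        raise ValueError(f"none of the marker genes {markers} are present")
    missing = set(markers) - set(present)
    if missing:
        warnings.warn(f"marker genes absent: {sorted(missing)}", stacklevel=2)
    idx = [genes.index(m) for m in present]
    score = lognorm[:, idx].mean(axis=1)
    table = (pd.DataFrame({"cluster": labels, "score": score})
             .groupby("cluster")["score"].mean().reset_index()
             .sort_values("score", ascending=False).reset_index(drop=True))
    best = int(table.loc[0, "cluster"])
    margin = float(table.loc[0, "score"] - table.loc[1, "score"]) \
        if len(table) > 1 else np.inf
    table["selected"] = table["cluster"] == best
    table.attrs["margin"] = margin
    if margin < tie_tolerance:
        raise ValueError(
            f"ambiguous lymphoid cluster: top scores within {tie_tolerance} "
            f"({table.loc[0, 'score']:.3f} vs {table.loc[1, 'score']:.3f}); "
            "choose explicitly")
    return best, labels == best, table


def subcluster_lymphoid(
    lognorm_by_sample: dict[str, np.ndarray],
    genes: list[str],
    n_subclusters: int = 5,
    n_pcs: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merge lymphoid spots from all samples, correct batches, subcluster.

    Returns ``(labels, corrected_embedding, sample_ids)``. With a single
    sample the subclustering runs without correction (notice emitted).
    """
    from .imc import integrate_batches

    samples = list(lognorm_by_sample)
    X = np.vstack([lognorm_by_sample[s] for s in samples])
    batch = np.concatenate([[s] * len(lognorm_by_sample[s]) for s in samples])
    if len(samples) == 1:
        warnings.warn("single sample: subclustering without batch correction",
                      stacklevel=2)
    hvg = select_hvgs(X, min(2000, X.shape[1]))
    corrected = integrate_batches(X[:, hvg], batch, n_pcs=n_pcs,
                                  n_clusters=max(n_subclusters, 2), seed=seed)
    km = KMeans(n_clusters=n_subclusters, n_init=5,
                random_state=seed % (2**31)).fit(corrected)
    return km.labels_, corrected, batch


def region_de(
    table: SpotTable,
    region_a: str = "SED",
    region_b: str = "Follicle",
    logfc_min: float = 0.25,
    min_fraction: float = 0.10,
    min_spots: int = 10,
    lognorm: np.ndarray | None = None,
) -> pd.DataFrame:
    """Region-contrast differential expression.

    Genes passing ``|logFC| >= logfc_min`` (difference of mean log-normalised
    expression, natural log) AND expression in at least ``min_fraction`` of
    spots in either region are tested with the Wilcoxon rank-sum test on the
    log-normalised values; Bonferroni correction uses the total number of
    genes in the table (the convention of spot-level marker detection tools,
    which keeps family-wise control over the whole panel despite the
    filters). Genes failing the filters are flagged, not dropped; the table
    is sorted by adjusted p then |logFC|.
    """
    regions = table.spots["region"].to_numpy()
    a_mask = regions == region_a
    b_mask = regions == region_b
    if a_mask.sum() < min_spots or b_mask.sum() < min_spots:
        raise ValueError(
            f"need >= {min_spots} spots per region "
            f"({region_a}: {a_mask.sum()}, {region_b}: {b_mask.sum()})")
    ln = log_normalise(table.counts) if lognorm is None else lognorm
    A, B = ln[a_mask], ln[b_mask]
    counts_a, counts_b = table.counts[a_mask], table.counts[b_mask]
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    logfc = mean_a - mean_b
    frac_a = (counts_a > 0).mean(axis=0)
    frac_b = (counts_b > 0).mean(axis=0)
    passes = ((np.abs(logfc) >= logfc_min)
              & (np.maximum(frac_a, frac_b) >= min_fraction))
    m_total = len(table.genes)
    pvals = np.full(m_total, np.nan)
    for j in np.flatnonzero(passes):
        pvals[j] = wilcoxon_rank_sum(A[:, j], B[:, j]).p_value
    padj = np.full(m_total, np.nan)
    tested = ~np.isnan(pvals)
    padj[tested] = np.minimum(1.0, pvals[tested] * m_total)
    out = pd.DataFrame({
        "gene": table.genes,
        f"mean_log_{region_a}": mean_a,
        f"mean_log_{region_b}": mean_b,
        "logfc": logfc,
        f"frac_{region_a}": frac_a,
        f"frac_{region_b}": frac_b,
        "passed_filters": passes,
        "p_value": pvals,
        "p_adjusted": padj,
    })
    if not passes.any():
        warnings.warn(
            "no genes passed the log-FC/fraction filters; table returned "
            "with diagnostics only", stacklevel=2)
    return out.sort_values(
        ["p_adjusted", "logfc"],
        key=lambda s: s if s.name == "p_adjusted" else -s.abs(),
        na_position="last").reset_index(drop=True)


def gene_correlation_matrix(
    lognorm: np.ndarray,
    genes: list[str],
    gene_list: tuple[str, ...] = SLE_GENES,
    spot_mask: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlations with Holm-adjusted p values.

    Missing genes are reported (warning), not fatal; constant genes yield
    NaN rows/columns. Returns symmetric ``(rho, p_adjusted)`` frames with
    unit diagonal.
    """
    present = [g for g in gene_list if g in genes]
    missing = set(gene_list) - set(present)
    if missing:
        warnings.warn(f"genes absent from matrix: {sorted(missing)}",
                      stacklevel=2)
    if len(present) < 2:
        raise ValueError("need >= 2 present genes")
    X = lognorm[:, [genes.index(g) for g in present]]
    if spot_mask is not None:
        X = X[spot_mask]
    if len(X) < 3:
        raise ValueError("need >= 3 spots")
    m = len(present)
    rho = np.eye(m)
    praw = np.zeros((m, m))
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    raw_list = []
    for i, j in pairs:
        r, p = spearman_correlation(X[:, i], X[:, j])
        rho[i, j] = rho[j, i] = r
        raw_list.append(p)
    finite = [p for p in raw_list if np.isfinite(p)]
    adj_map = {}
    if finite:
        adj = adjust_pvalues(finite, "holm").adjusted
        it = iter(adj)
        adj_map = {k: next(it) for k, p in enumerate(raw_list)
                   if np.isfinite(p)}
    for k, (i, j) in enumerate(pairs):
        val = adj_map.get(k, np.nan)
        praw[i, j] = praw[j, i] = val
    rho_df = pd.DataFrame(rho, index=present, columns=present)
    p_df = pd.DataFrame(praw, index=present, columns=present)
    np.fill_diagonal(p_df.values, 0.0)
    return rho_df, p_df
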