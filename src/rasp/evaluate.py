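"""Clustering of smoothed PCs and label-free quality metrics.

Spatial domains / cell types are obtained by clustering the smoothed PC
scores: a UMAP-style fuzzy kNN connectivity graph is built in PC space
(distances between expression profiles, *not* spatial distances) and
partitioned with Leiden, Louvain or Walktrap; a Gaussian mixture model is
available as the model-based alternative (the analog of Mclust).

Partitions are scored with the adjusted Rand index against ground truth
when available, and label-free with Moran's I (spatial autocorrelation of
the one-hot cluster indicators on a spatial kNN weight graph) and the CHAOS
statistic (mean within-cluster 1-nearest-neighbour edge length on
unit-scaled coordinates; lower = more compact domains).  A (kNN, beta)
parameter sweep computes the PCA embedding once, rebuilds only the sparse
spatial weights per grid cell, and records all metrics so the best
combination can be selected with or without labels.
"""

from __future__ import annotations

import random as _pyrandom
import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

from .core import CovariateSpec, RaspConfig, compute_embedding, smooth_embedding

__all__ = [
    "ClusterLabels",
    "build_expression_graph",
    "cluster",
    "match_cluster_count",
    "ari",
    "morans_i",
    "chaos",
    "parameter_sweep",
    "select_parameters",
]

_GRAPH_METHODS = {"louvain", "leiden", "walktrap"}
_METHODS = _GRAPH_METHODS | {"gmm"}


@dataclass
class ClusterLabels:
    """A partition of locations with provenance.

    Labels are contiguous nonnegative integers ordered by decreasing
    cluster size.  ``resolution_or_k`` records the graph resolution (Leiden
    / Louvain) or requested component count (GMM / Walktrap).
    """

    labels: np.ndarray
    method: str
    n_neighbors: int
    resolution_or_k: float
    seed: int
    matched: bool = True  # False when match_cluster_count missed target_k
    trace: list[tuple[float, int]] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Map labels to contiguous ints, largest cluster first."""
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.argsort(-counts, kind="stable")]
    mapping = {old: new for new, old in enumerate(order)}
    return np.array([mapping[v] for v in labels], dtype=int)


def build_expression_graph(Ps: np.ndarray, n_neighbors: int = 10) -> ig.Graph:
    """UMAP-style fuzzy kNN connectivity graph over locations in PC space.

    The kNN search and fuzzy-union connectivities follow the standard
    scanpy/UMAP neighborhood construction; edge weights are the
    connectivity strengths.  Distances are measured on the smoothed PCs,
    not on spatial coordinates.
    """
    Ps = np.asarray(Ps, dtype=float)
    n = Ps.shape[0]
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be >= 1")
    if n_neighbors >= n:
        raise ValueError(f"n_neighbors={n_neighbors} must be < n={n}")
    import anndata
    import scanpy as sc

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adata = anndata.AnnData(X=Ps)
        # scanpy counts the point itself among n_neighbors; +1 keeps the
        # requested number of true neighbours
        sc.pp.neighbors(
            adata, n_neighbors=min(n_neighbors + 1, n), use_rep="X", random_state=0
        )
    conn = sparse.triu(adata.obsp["connectivities"], k=1).tocoo()
    g = ig.Graph(
        n=n,
        edges=list(zip(conn.row.tolist(), conn.col.tolist())),
        edge_attrs={"weight": conn.data.tolist()},
    )
    return g


def cluster(
    Ps: np.ndarray,
    method: str = "leiden",
    *,
    n_neighbors: int = 10,
    resolution: float = 1.0,
    k: int | None = None,
    seed: int = 0,
    graph: ig.Graph | None = None,
) -> ClusterLabels:
    """Cluster locations on the smoothed PCs.

    Graph methods (``leiden``, ``louvain``, ``walktrap``) partition the
    expression kNN graph; ``gmm`` fits a Gaussian mixture (full covariance,
    k-means initialization) directly on ``Ps`` and requires ``k``.
    Deterministic given ``seed``.
    """
    Ps = np.asarray(Ps, dtype=float)
    if method not in _METHODS:
        raise ValueError(f"unknown clustering method {method!r}")
    if method == "gmm":
        if k is None:
            raise ValueError("gmm requires a component count k")
        gm = GaussianMixture(
            n_components=k, covariance_type="full", random_state=seed, n_init=1
        )
        labels = gm.fit_predict(Ps)
        return ClusterLabels(
            _relabel_by_size(labels), method, 0, float(k), seed
        )
    if graph is None:
        graph = build_expression_graph(Ps, n_neighbors)
    weights = graph.es["weight"] if "weight" in graph.es.attributes() else None
    if method == "leiden":
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            weights=weights,
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=2,
        )
        labels = np.asarray(part.membership)
        res_or_k = resolution
    elif method == "louvain":
        _pyrandom.seed(seed)
        ig.set_random_number_generator(_pyrandom)
        part = graph.community_multilevel(weights=weights, resolution=resolution)
        labels = np.asarray(part.membership)
        res_or_k = resolution
    else:  # walktrap
        dend = graph.community_walktrap(weights=weights, steps=4)
        part = dend.as_clustering(n=k) if k is not None else dend.as_clustering()
        labels = np.asarray(part.membership)
        res_or_k = float(k) if k is not None else float(len(part))
    return ClusterLabels(
        _relabel_by_size(labels), method, n_neighbors, res_or_k, seed
    )


def match_cluster_count(
    Ps: np.ndarray,
    method: str,
    target_k: int,
    *,
    n_neighbors: int = 10,
    resolution_bounds: tuple[float, float] = (1e-3, 10.0),
    max_iter: int = 25,
    seed: int = 0,
    graph: ig.Graph | None = None,
) -> ClusterLabels:
    """Search the resolution so a graph partition has ``target_k`` clusters.

    Bisection over the resolution parameter (cluster count is
    non-decreasing in resolution for modularity-style objectives); if the
    exact count is never hit within the bounds the closest achieved
    partition is returned with ``matched=False``.  Walktrap and GMM take
    the cluster count directly.
    """
    if target_k < 1:
        raise ValueError("target_k must be >= 1")
    if method in {"gmm", "walktrap"}:
        if method == "walktrap" and graph is None:
            graph = build_expression_graph(Ps, n_neighbors)
        out = cluster(
            Ps, method, n_neighbors=n_neighbors, k=target_k, seed=seed, graph=graph
        )
        out.matched = out.n_clusters == target_k
        return out
    if method not in _GRAPH_METHODS:
        raise ValueError(f"unknown clustering method {method!r}")
    if graph is None:
        graph = build_expression_graph(Ps, n_neighbors)
    lo, hi = resolution_bounds
    trace: list[tuple[float, int]] = []
    best: ClusterLabels | None = None

    def run(res: float) -> ClusterLabels:
        nonlocal best
        out = cluster(
            Ps, method, n_neighbors=n_neighbors, resolution=res, seed=seed, graph=graph
        )
        trace.append((res, out.n_clusters))
        if best is None or abs(out.n_clusters - target_k) < abs(
            best.n_clusters - target_k
        ):
            best = out
        return out

    out_lo = run(lo)
    if out_lo.n_clusters >= target_k:
        out_lo.matched = out_lo.n_clusters == target_k
        out_lo.trace = trace
        return out_lo
    out_hi = run(hi)
    if out_hi.n_clusters <= target_k:
        out_hi.matched = out_hi.n_clusters == target_k
        out_hi.trace = trace
        return out_hi
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi) if lo > 0 else 0.5 * (lo + hi)
        out = run(mid)
        if out.n_clusters == target_k:
            out.matched = True
            out.trace = trace
            return out
        if out.n_clusters < target_k:
            lo = mid
        else:
            hi = mid
    assert best is not None
    best.matched = best.n_clusters == target_k
    best.trace = trace
    return best


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions (permutation model)."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("partitions must have equal length")
    return float(adjusted_rand_score(labels_a, labels_b))


def _spatial_weight_graph(
    C: np.ndarray, n_neighbors: int
) -> sparse.csr_matrix:
    """Row-standardized binary kNN weights on spatial coordinates."""
    n = C.shape[0]
    nn = NearestNeighbors(n_neighbors=min(n_neighbors, n - 1) + 1).fit(C)
    A = nn.kneighbors_graph(C, mode="connectivity")
    A = A.tolil()
    A.setdiag(0)
    A = A.tocsr()
    A.eliminate_zeros()
    rowsum = np.asarray(A.sum(axis=1)).ravel()
    rowsum[rowsum == 0] = 1.0
    return sparse.diags(1.0 / rowsum) @ A


def _moran_stat(z: np.ndarray, W: sparse.csr_matrix) -> float:
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0:
        warnings.warn("Moran's I is undefined for constant input", stacklevel=3)
        return float("nan")
    S0 = float(W.sum())
    n = z.size
    return (n / S0) * float(z @ (W @ z)) / denom


def morans_i(
    values_or_labels,
    C: np.ndarray,
    w_neighbors: int = 6,
    *,
    weights: sparse.spmatrix | None = None,
    per_cluster: bool = False,
):
    """Moran's I spatial autocorrelation on a kNN spatial weight graph.

    Numeric (float) input is scored directly.  Integer input is treated as
    cluster labels: each cluster's one-hot indicator is scored and the
    cluster-size-weighted mean is returned (with the per-cluster values when
    ``per_cluster=True``).  ``weights`` overrides the default
    row-standardized kNN graph built from the coordinates.
    """
    x = np.asarray(values_or_labels)
    C = np.asarray(C, dtype=float)
    if weights is None:
        W = _spatial_weight_graph(C, w_neighbors)
    else:
        W = sparse.csr_matrix(weights)
    if np.issubdtype(x.dtype, np.floating):
        return _moran_stat(x.astype(float), W)
    labels = x.astype(int)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size == 1:
        warnings.warn("Moran's I is undefined for a single cluster", stacklevel=2)
        return float("nan")
    vals = {}
    for u in uniq:
        vals[int(u)] = _moran_stat((labels == u).astype(float), W)
    weighted = float(
        np.average([vals[int(u)] for u in uniq], weights=counts)
    )
    if per_cluster:
        return weighted, vals
    return weighted


def chaos(labels, C: np.ndarray) -> float:
    """CHAOS: mean within-cluster 1-NN edge length on unit-scaled coords.

    Coordinates are shifted to the origin and divided by the largest axis
    range (scale-free).  For every cluster with at least two members, each
    location contributes the distance to its nearest neighbour *within the
    cluster*; CHAOS is the mean contribution over all such locations.
    Lower values indicate spatially compact, continuous clusters.
    Singleton clusters are skipped with a warning.
    """
    labels = np.asarray(labels)
    C = np.asarray(C, dtype=float)
    if labels.shape[0] != C.shape[0]:
        raise ValueError("labels and coordinates must be aligned")
    span = (C.max(axis=0) - C.min(axis=0)).max()
    if span == 0:
        raise ValueError("degenerate coordinates: zero spatial extent")
    Cs = (C - C.min(axis=0)) / span
    dists: list[np.ndarray] = []
    skipped = 0
    for u in np.unique(labels):
        pts = Cs[labels == u]
        if pts.shape[0] < 2:
            skipped += 1
            continue
        nn = NearestNeighbors(n_neighbors=2).fit(pts)
        d, _ = nn.kneighbors(pts)
        dists.append(d[:, 1])
    if skipped:
        warnings.warn(f"{skipped} singleton cluster(s) skipped in CHAOS", stacklevel=2)
    if not dists:
        raise ValueError("CHAOS is undefined: all clusters are singletons")
    return float(np.mean(np.concatenate(dists)))


def parameter_sweep(
    X,
    C: np.ndarray,
    knn_grid,
    beta_grid=None,
    methods=("leiden",),
    cluster_params: dict | None = None,
    truth=None,
    seed: int = 0,
    config: RaspConfig | None = None,
    covariates: CovariateSpec | None = None,
) -> pd.DataFrame:
    """Grid sweep over (kNN, beta) x clustering method.

    The randomized PCA embedding is computed exactly once; each grid cell
    rebuilds only the sparse spatial weights, re-smooths the fixed PC
    scores, clusters them and records n_clusters, Moran's I, CHAOS and
    (when ``truth`` labels are given) the ARI.  ``cluster_params`` may carry
    ``n_neighbors`` (expression-graph kNN, default 10), ``target_k`` (match
    the cluster count), ``resolution`` and ``moran_neighbors``.
    """
    knn_grid = list(knn_grid)
    beta_grid = list(beta_grid) if beta_grid is not None else _DEFAULT_BETA_GRID.copy()
    if not knn_grid or not beta_grid:
        raise ValueError("parameter grids must be non-empty")
    params = dict(cluster_params or {})
    n_neighbors = params.get("n_neighbors", 10)
    target_k = params.get("target_k")
    resolution = params.get("resolution", 1.0)
    moran_neighbors = params.get("moran_neighbors", 6)
    C = np.asarray(C, dtype=float)
    base = config or RaspConfig(seed=seed)
    from dataclasses import replace as _replace

    base = _replace(base, seed=seed)
    embedding = compute_embedding(X.X if hasattr(X, "X") else X, base)
    rows = []
    for knn in knn_grid:
        for beta in beta_grid:
            cfg = _replace(base, threshold=int(knn), beta=float(beta))
            result = smooth_embedding(embedding, C, cfg, covariates)
            scores = result.Pc if result.Pc is not None else result.Ps
            graph = None
            for method in methods:
                if method in _GRAPH_METHODS and graph is None:
                    graph = build_expression_graph(scores, n_neighbors)
                if target_k is not None:
                    lab = match_cluster_count(
                        scores,
                        method,
                        target_k,
                        n_neighbors=n_neighbors,
                        seed=seed,
                        graph=graph,
                    )
                else:
                    extra = (
                        {"k": params.get("k")} if method in {"gmm", "walktrap"} else {}
                    )
                    lab = cluster(
                        scores,
                        method,
                        n_neighbors=n_neighbors,
                        resolution=resolution,
                        seed=seed,
                        graph=graph,
                        **extra,
                    )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    mi = morans_i(lab.labels, C, moran_neighbors)
                    ch = chaos(lab.labels, C)
                row = {
                    "knn": int(knn),
                    "beta": float(beta),
                    "method": method,
                    "n_clusters": lab.n_clusters,
                    "morans_i": mi,
                    "chaos": ch,
                    "seed": seed,
                }
                if truth is not None:
                    row["ari"] = ari(truth, lab.labels)
                rows.append(row)
    return pd.DataFrame(rows)


#: Default beta grid: nine values spanning the rectangular (0) to the
#: strongly localized (2) kernel in steps of 0.25.
_DEFAULT_BETA_GRID = [0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0]
DEFAULT_BETA_GRID = _DEFAULT_BETA_GRID


def select_parameters(table: pd.DataFrame, criterion: str = "max_moran") -> pd.Series:
    """Pick the best sweep row by a named criterion.

    ``max_moran`` / ``max_ari`` maximize, ``min_chaos`` minimizes.  Ties are
    broken by smaller kNN, then smaller beta.
    """
    columns = {"max_moran": "morans_i", "min_chaos": "chaos", "max_ari": "ari"}
    if criterion not in columns:
        raise ValueError(f"unknown criterion {criterion!r}")
    col = columns[criterion]
    if col not in table.columns:
        raise ValueError(f"criterion column {col!r} absent from table")
    if table.empty:
        raise ValueError("sweep table is empty")
    ascending = criterion == "min_chaos"
    ordered = table.sort_values(
        [col, "knn", "beta"], ascending=[ascending, True, True], kind="stable"
    )
    return ordered.iloc[0]
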