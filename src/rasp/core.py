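"""The RASP algorithm: randomized PCA plus kNN inverse-distance smoothing.

The pipeline is

1. randomized truncated PCA of the (implicitly centered) sparse
   location-by-gene matrix ``X`` -> loadings ``W`` and scores ``P``;
2. an exact kNN search on the spatial coordinates -> a row-wise sparse
   distance matrix ``D`` (each row stores the distances to its ``threshold``
   nearest neighbours);
3. the diagonal of ``D`` is set to a per-row ``alpha`` (by default the
   row's minimum off-diagonal distance) so self-weights stay finite;
4. a weight kernel is applied entrywise — by default ``w = 1 / d**beta`` —
   and each *column* of the weight matrix is divided by its maximum
   (column-max standardization, kept deliberately instead of the more common
   row-stochastic normalization);
5. smoothed scores ``Ps = D_I @ P``.

If location covariates are supplied, selected covariate columns are smoothed
with the same weights, covariates are standardized, and a second randomized
PCA of ``[Ps, Ys]`` yields covariate-integrated scores ``Pc``.

The expensive embedding (steps 1–2 of the list above) is exposed separately
(:func:`compute_embedding` / :func:`smooth_embedding`) so that parameter
sweeps over (kNN, beta) reuse the PCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "RaspConfig",
    "SparseSpatialWeights",
    "RaspResult",
    "CovariateSpec",
    "Embedding",
    "randomized_pca",
    "build_sparse_distance",
    "apply_diagonal",
    "weight_kernel",
    "smooth",
    "compute_embedding",
    "smooth_embedding",
    "rasp",
]

_METRICS = {"euclidean", "manhattan", "chebyshev"}
_KERNELS = {"inverse_distance", "gaussian", "quadratic"}
_ALPHA_MODES = {"row_min", "half_row_min"}


@dataclass(frozen=True)
class RaspConfig:
    """Tunable parameters of the RASP pipeline.

    p
        Number of principal components (default 20).
    threshold
        kNN count used to sparsify the spatial distance matrix.
    alpha_mode
        Diagonal self-distance rule: ``"row_min"`` (default; the row's
        minimum off-diagonal distance), ``"half_row_min"`` (half that value,
        appropriate for regular spot grids such as Visium), or ``"fixed:V"``
        for a constant V in spatial units.
    beta
        Power of the inverse-distance weighting (default 2).  ``beta=0``
        degenerates to a rectangular kernel (all retained neighbours weighted
        equally); large beta concentrates weight on the closest neighbours.
    distance_metric, kernel
        Spatial metric and weight kernel; the Gaussian and quadratic kernels
        require ``bandwidth`` (same units as the coordinates).
    center, scale
        Column centering/scaling of X inside the PCA.  Default: center, do
        not scale.
    """

    p: int = 20
    threshold: int = 50
    alpha_mode: str = "row_min"
    beta: float = 2.0
    distance_metric: str = "euclidean"
    kernel: str = "inverse_distance"
    bandwidth: float | None = None
    center: bool = True
    scale: bool = False
    n_oversamples: int = 10
    n_power_iterations: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.distance_metric not in _METRICS:
            raise ValueError(f"unknown distance metric {self.distance_metric!r}")
        if self.kernel not in _KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        _parse_alpha(self.alpha_mode)


def _parse_alpha(mode: str) -> tuple[str, float | None]:
    if mode in _ALPHA_MODES:
        return mode, None
    if mode.startswith("fixed:"):
        value = float(mode.split(":", 1)[1])
        if value <= 0:
            raise ValueError("fixed alpha must be positive")
        return "fixed", value
    raise ValueError(f"unknown alpha_mode {mode!r}")


@dataclass
class SparseSpatialWeights:
    """Column-max-standardized sparse spatial weights ``D_I``.

    Row i stores weights for location i's ``threshold`` nearest neighbours
    plus its diagonal self-weight; every stored entry lies in (0, 1] and each
    column's maximum is exactly 1.  The kNN relation is row-wise and *not*
    symmetrized.
    """

    D_I: sparse.csr_matrix
    threshold: int
    alpha_mode: str
    beta: float
    metric: str
    kernel: str


@dataclass
class CovariateSpec:
    """Location-level covariates for the second-stage PCA.

    ``Y`` is n x b, rows aligned with X's locations.  ``smooth_flags[j]``
    says whether covariate j is spatially smoothed before integration
    (inherently spatial covariates such as local cell density should not
    be re-smoothed).  ``names`` is optional bookkeeping.
    """

    Y: np.ndarray
    smooth_flags: np.ndarray | None = None
    names: list[str] | None = None

    def __post_init__(self) -> None:
        Y = np.asarray(self.Y, dtype=float)
        if Y.ndim == 1:  # a vector is one covariate over n locations
            Y = Y[:, None]
        self.Y = Y
        if self.smooth_flags is None:
            self.smooth_flags = np.ones(self.Y.shape[1], dtype=bool)
        else:
            self.smooth_flags = np.asarray(self.smooth_flags, dtype=bool)
        if self.smooth_flags.shape != (self.Y.shape[1],):
            raise ValueError("one smooth flag per covariate is required")


@dataclass
class Embedding:
    """First-stage randomized PCA embedding (reusable across sweeps)."""

    W: np.ndarray  # m x p loadings
    P: np.ndarray  # n x p scores of the centered matrix
    column_means: np.ndarray  # length-m
    column_scales: np.ndarray | None
    config: RaspConfig


@dataclass
class RaspResult:
    """Outputs of the RASP pipeline.

    ``Ps`` are the spatially smoothed PC scores; ``W`` the gene loadings;
    ``column_means`` the gene means used for implicit centering (needed to
    reconstruct expression).  When covariates are supplied, ``Ys`` holds the
    (optionally smoothed) covariates, ``Pc``/``Wc`` the second-stage scores
    and loadings, and ``ps_column_means`` the column means of ``[Ps, Ys]``
    removed by the second-stage centering.
    """

    Ps: np.ndarray
    W: np.ndarray
    column_means: np.ndarray
    config: RaspConfig
    weights: SparseSpatialWeights | None = None
    column_scales: np.ndarray | None = None
    Ys: np.ndarray | None = None
    Pc: np.ndarray | None = None
    Wc: np.ndarray | None = None
    ps_column_means: np.ndarray | None = None
    P: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))


def _center_operator(X, column_means, column_scales):
    """Matvec helpers for A = (X - 1 xbar^T) diag(1/sd) without densifying."""
    if column_scales is None:
        inv_sd = None
    else:
        inv_sd = 1.0 / column_scales

    def matmat(V):
        Vs = V if inv_sd is None else V * inv_sd[:, None]
        out = X @ Vs
        out = np.asarray(out)
        out -= np.outer(np.ones(X.shape[0]), column_means @ Vs)
        return out

    def rmatmat(U):
        out = X.T @ U
        out = np.asarray(out)
        out -= np.outer(column_means, U.sum(axis=0))
        if inv_sd is not None:
            out *= inv_sd[:, None]
        return out

    return matmat, rmatmat


def randomized_pca(
    X,
    p: int,
    *,
    center: bool = True,
    scale: bool = False,
    seed: int = 0,
    n_oversamples: int = 10,
    n_power_iterations: int = 4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Randomized truncated PCA with implicit centering of a sparse matrix.

    Returns ``(W, P, column_means)`` where ``W`` (m x p) approximates the
    top-p right singular vectors of the centered (optionally scaled) matrix
    and ``P = X_centered @ W`` are the scores.  Centering is performed
    through a rank-one update inside the mat-vec products, so sparse input
    is never densified.  Uses a Gaussian range finder with ``n_oversamples``
    extra directions and ``n_power_iterations`` QR-stabilized power
    iterations; column signs follow the largest-magnitude loading.
    """
    n, m = X.shape
    if p > min(n, m):
        raise ValueError(f"p={p} exceeds min(n, m)={min(n, m)}")
    if sparse.issparse(X):
        X = X.tocsr()
        column_means = np.asarray(X.mean(axis=0)).ravel()
    else:
        X = np.asarray(X, dtype=float)
        column_means = X.mean(axis=0)
    if not center:
        column_means = np.zeros(m)
    column_scales = None
    if scale:
        if sparse.issparse(X):
            mean_sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
        else:
            mean_sq = (X**2).mean(axis=0)
        true_means = column_means if center else (
            np.asarray(X.mean(axis=0)).ravel() if sparse.issparse(X) else X.mean(axis=0)
        )
        var = np.maximum(mean_sq - true_means**2, 0.0) * n / max(n - 1, 1)
        column_scales = np.sqrt(var)
        column_scales[column_scales == 0] = 1.0

    matmat, rmatmat = _center_operator(X, column_means, column_scales)
    rng = np.random.default_rng(seed)
    k = min(p + n_oversamples, min(n, m))
    G = rng.standard_normal((m, k))
    Q, _ = np.linalg.qr(matmat(G))
    for _ in range(n_power_iterations):
        Q, _ = np.linalg.qr(rmatmat(Q))
        Q, _ = np.linalg.qr(matmat(Q))
    B = rmatmat(Q).T  # k x m
    Ub, s, Vt = np.linalg.svd(B, full_matrices=False)
    W = Vt[:p].T  # m x p
    # deterministic sign: make the largest-magnitude loading positive
    flip = np.sign(W[np.argmax(np.abs(W), axis=0), np.arange(p)])
    flip[flip == 0] = 1.0
    W *= flip
    P = matmat(W)
    return W, P, column_means


def build_sparse_distance(
    C: np.ndarray,
    threshold: int,
    metric: str = "euclidean",
) -> sparse.csr_matrix:
    """Row-wise sparse kNN distance matrix on spatial coordinates.

    Row i stores exact metric distances to its ``threshold`` nearest
    neighbours, excluding self (fewer if ``n - 1 < threshold``).  Coincident
    points produce stored zeros here; they are replaced by the row's
    smallest positive distance (or the diagonal alpha if the whole row is
    coincident) inside :func:`weight_kernel`, preserving their "nearest"
    status without infinite weights.
    """
    C = np.asarray(C, dtype=float)
    if not np.all(np.isfinite(C)):
        raise ValueError("coordinates must be finite")
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if metric not in _METRICS:
        raise ValueError(f"unknown distance metric {metric!r}")
    n = C.shape[0]
    k = min(threshold, n - 1)
    if k < 1:
        raise ValueError("need at least two locations to build distances")
    nn = NearestNeighbors(n_neighbors=k + 1, metric=metric)
    nn.fit(C)
    dist, idx = nn.kneighbors(C)
    rows = np.repeat(np.arange(n), k)
    cols = np.empty(n * k, dtype=int)
    data = np.empty(n * k, dtype=float)
    for i in range(n):
        # drop the self match (any position among tied zero distances)
        self_pos = np.nonzero(idx[i] == i)[0]
        keep = np.delete(np.arange(k + 1), self_pos[0] if self_pos.size else k)
        keep = keep[:k]
        cols[i * k : (i + 1) * k] = idx[i, keep]
        data[i * k : (i + 1) * k] = dist[i, keep]
    D = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    # csr construction drops explicit zeros from coincident points; rebuild
    # them via coo to keep exactly k stored entries per row
    D = sparse.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    return D


def apply_diagonal(D: sparse.csr_matrix, alpha_mode: str = "row_min") -> sparse.csr_matrix:
    """Set the diagonal self-distance of each row.

    ``row_min`` uses the row's minimum *positive* off-diagonal stored
    distance, ``half_row_min`` half of it, ``fixed:V`` the constant V.
    """
    kind, value = _parse_alpha(alpha_mode)
    D = D.tocsr(copy=True)
    n = D.shape[0]
    diag = np.empty(n)
    for i in range(n):
        row = D.data[D.indptr[i] : D.indptr[i + 1]]
        pos = row[row > 0]
        if kind == "fixed":
            diag[i] = value
            continue
        if pos.size == 0:
            raise ValueError(
                f"row {i} has no positive off-diagonal distance; cannot derive alpha"
            )
        diag[i] = pos.min() if kind == "row_min" else 0.5 * pos.min()
    D = D.tolil()
    D.setdiag(diag)
    return D.tocsr()


def weight_kernel(
    D: sparse.csr_matrix,
    beta: float = 2.0,
    kernel: str = "inverse_distance",
    bandwidth: float | None = None,
    *,
    threshold: int | None = None,
    alpha_mode: str = "row_min",
    metric: str = "euclidean",
) -> SparseSpatialWeights:
    """Turn a sparse distance matrix into column-max-standardized weights.

    ``inverse_distance``: ``w = 1 / d**beta`` on stored entries (absent
    entries stay 0).  ``gaussian``: ``w = exp(-d^2 / (2 bandwidth^2))``.
    ``quadratic``: ``w = max(0, 1 - (d / bandwidth)^2)`` (weights that hit 0
    are dropped).  Every column is then divided by its maximum stored value.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if kernel not in _KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}")
    if kernel in {"gaussian", "quadratic"} and bandwidth is None:
        raise ValueError(f"{kernel} kernel requires a bandwidth")
    D = D.tocsr(copy=True)
    n = D.shape[0]
    # replace residual zero distances (coincident neighbours) by the row's
    # smallest positive stored distance (includes the diagonal alpha)
    for i in range(n):
        row = D.data[D.indptr[i] : D.indptr[i + 1]]
        if row.size and np.any(row == 0):
            pos = row[row > 0]
            if pos.size == 0:
                raise ValueError(f"row {i} has no positive stored distance")
            row[row == 0] = pos.min()
            D.data[D.indptr[i] : D.indptr[i + 1]] = row
    W = D
    if kernel == "inverse_distance":
        W.data = 1.0 / W.data**beta
    elif kernel == "gaussian":
        W.data = np.exp(-(W.data**2) / (2.0 * bandwidth**2))
    else:  # quadratic
        W.data = np.maximum(0.0, 1.0 - (W.data / bandwidth) ** 2)
        W.eliminate_zeros()
    colmax = W.max(axis=0).toarray().ravel()
    if np.any(colmax <= 0):
        # a column with no stored entries cannot be standardized; leave as-is
        colmax[colmax <= 0] = 1.0
    W = (W @ sparse.diags(1.0 / colmax)).tocsr()
    return SparseSpatialWeights(
        D_I=W,
        threshold=threshold if threshold is not None else -1,
        alpha_mode=alpha_mode,
        beta=beta,
        metric=metric,
        kernel=kernel,
    )


def smooth(weights: SparseSpatialWeights, M: np.ndarray) -> np.ndarray:
    """Spatially smooth the columns of M: returns ``D_I @ M``."""
    D_I = weights.D_I
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    if D_I.shape[1] != M.shape[0]:
        raise ValueError(
            f"weights are {D_I.shape[0]}x{D_I.shape[1]} but M has {M.shape[0]} rows"
        )
    return np.asarray(D_I @ M)


def compute_embedding(X, config: RaspConfig) -> Embedding:
    """First stage: randomized PCA of X (no spatial information involved).

    This is the expensive step; a (kNN, beta) sweep only needs to call
    :func:`smooth_embedding` on the result.
    """
    Xmat = X.X if hasattr(X, "X") else X
    W, P, means = randomized_pca(
        Xmat,
        config.p,
        center=config.center,
        scale=config.scale,
        seed=config.seed,
        n_oversamples=config.n_oversamples,
        n_power_iterations=config.n_power_iterations,
    )
    return Embedding(W=W, P=P, column_means=means, column_scales=None, config=config)


def _build_weights(C: np.ndarray, config: RaspConfig) -> SparseSpatialWeights:
    D = build_sparse_distance(C, config.threshold, config.distance_metric)
    D = apply_diagonal(D, config.alpha_mode)
    return weight_kernel(
        D,
        beta=config.beta,
        kernel=config.kernel,
        bandwidth=config.bandwidth,
        threshold=config.threshold,
        alpha_mode=config.alpha_mode,
        metric=config.distance_metric,
    )


def smooth_embedding(
    embedding: Embedding,
    C: np.ndarray,
    config: RaspConfig | None = None,
    covariates: CovariateSpec | None = None,
) -> RaspResult:
    """Second stage: build spatial weights, smooth the PCs, optionally
    integrate covariates via a second randomized PCA on ``[Ps, Ys]``."""
    config = config or embedding.config
    C = np.asarray(C, dtype=float)
    if C.shape[0] != embedding.P.shape[0]:
        raise ValueError("coordinate rows do not match the embedding")
    weights = _build_weights(C, config)
    Ps = smooth(weights, embedding.P)
    result = RaspResult(
        Ps=Ps,
        W=embedding.W,
        column_means=embedding.column_means,
        config=config,
        weights=weights,
        column_scales=embedding.column_scales,
        P=embedding.P,
    )
    if covariates is None:
        return result
    Y = covariates.Y
    if Y.shape[0] != Ps.shape[0]:
        raise ValueError("covariate rows do not align with the expression matrix")
    Ys = Y.copy()
    flags = covariates.smooth_flags
    if flags.any():
        Ys[:, flags] = smooth(weights, Y[:, flags])
    # standardize covariate columns so one covariate is not swamped by p PCs
    Ys_std = Ys.copy()
    sd = Ys_std.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Ys_std = (Ys_std - Ys_std.mean(axis=0)) / sd
    Z = np.hstack([Ps, Ys_std])
    Wc, Pc, z_means = randomized_pca(
        Z,
        config.p,
        center=True,
        scale=False,
        seed=config.seed,
        n_oversamples=config.n_oversamples,
        n_power_iterations=config.n_power_iterations,
    )
    result.Ys = Ys
    result.Wc = Wc
    result.Pc = Pc
    result.ps_column_means = z_means
    return result


def rasp(
    X,
    C: np.ndarray,
    config: RaspConfig = RaspConfig(),
    covariates: CovariateSpec | None = None,
) -> RaspResult:
    """Run the full RASP pipeline on normalized expression and coordinates.

    ``X`` may be a :class:`~rasp.preprocess.NormalizedExpression` or any
    (sparse) n x m matrix; ``C`` is the aligned n x 2 coordinate matrix.
    Returns smoothed scores ``Ps`` (and covariate-integrated ``Pc`` when a
    :class:`CovariateSpec` is given).  Deterministic given ``config.seed``.
    """
    Xmat = X.X if hasattr(X, "X") else X
    C = np.asarray(C, dtype=float)
    if Xmat.shape[0] != C.shape[0]:
        raise ValueError(
            f"X has {Xmat.shape[0]} rows but C has {C.shape[0]}; rows must align"
        )
    embedding = compute_embedding(Xmat, config)
    return smooth_embedding(embedding, C, config, covariates)
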