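"""Quality-control filtering and normalization of spatial count matrices.

QC removes locations that are dominated by mitochondrial/ribosomal
transcripts, have too few reads, or are upper-tail read-depth outliers under
a median + k*MAD rule.  All three rules are evaluated on the *pre-filter*
matrix, so the retained set does not depend on the order the rules are
applied.  Normalization is standard library-size scaling to a common target
(default: the median per-location total) followed by log1p, with optional
per-gene unit-variance scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .synthdata import CountMatrix

__all__ = ["QCThresholds", "QCReport", "NormalizedExpression", "qc_filter", "normalize"]


class EmptyResultError(ValueError):
    """Raised when a filtering step removes every location."""


@dataclass(frozen=True)
class QCThresholds:
    """Location-level QC thresholds.

    max_mito_ribo_fraction
        Maximum tolerated fraction of counts from mitochondrial/ribosomal
        genes (default 0.10).
    min_reads
        Minimum total reads per location (default 100).
    mad_multiplier
        Locations with totals above ``median + mad_multiplier * MAD`` are
        removed; the MAD is the unscaled median absolute deviation of the
        per-location totals (no 1.4826 consistency constant).
    """

    max_mito_ribo_fraction: float = 0.10
    min_reads: int = 100
    mad_multiplier: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_mito_ribo_fraction <= 1.0:
            raise ValueError("max_mito_ribo_fraction must lie in [0, 1]")
        if self.min_reads <= 0 or self.mad_multiplier <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class QCReport:
    """Counts of locations removed by each rule (evaluated pre-filter)."""

    n_input: int
    n_removed_mito_ribo: int
    n_removed_min_reads: int
    n_removed_mad: int
    n_kept: int
    mad: float
    median_total: float
    upper_bound: float
    removed_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))


@dataclass
class NormalizedExpression:
    """Log-scale normalized location-by-gene expression.

    ``total_counts_per_location`` retains the pre-normalization library
    sizes, which are a natural candidate covariate for the two-stage PCA.
    """

    X: sparse.csr_matrix
    location_ids: np.ndarray
    gene_ids: np.ndarray
    total_counts_per_location: np.ndarray
    target_sum: float
    log_transformed: bool = True
    gene_scaled: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape


def qc_filter(
    counts: CountMatrix,
    mito_ribo_gene_ids: set[str] | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[CountMatrix, QCReport]:
    """Remove low-quality locations; genes are untouched.

    A location is removed if its mito+ribo count fraction exceeds
    ``max_mito_ribo_fraction``, its total reads fall below ``min_reads``, or
    its total reads exceed ``median + mad_multiplier * MAD`` of the totals.
    An empty mito/ribo gene set makes the fraction rule a no-op.
    """
    X = counts.counts.tocsr()
    totals = np.asarray(X.sum(axis=1)).ravel()
    n = X.shape[0]

    if mito_ribo_gene_ids:
        mask = np.isin(counts.gene_ids, list(mito_ribo_gene_ids))
        mito_totals = np.asarray(X[:, mask].sum(axis=1)).ravel()
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(totals > 0, mito_totals / np.maximum(totals, 1), 0.0)
        bad_frac = frac > thresholds.max_mito_ribo_fraction
    else:
        bad_frac = np.zeros(n, dtype=bool)

    bad_low = totals < thresholds.min_reads

    med = float(np.median(totals))
    mad = float(np.median(np.abs(totals - med)))
    upper = med + thresholds.mad_multiplier * mad
    bad_mad = totals > upper

    keep = ~(bad_frac | bad_low | bad_mad)
    if not keep.any():
        raise EmptyResultError("QC filtering removed every location")

    report = QCReport(
        n_input=n,
        n_removed_mito_ribo=int(bad_frac.sum()),
        n_removed_min_reads=int(bad_low.sum()),
        n_removed_mad=int(bad_mad.sum()),
        n_kept=int(keep.sum()),
        mad=mad,
        median_total=med,
        upper_bound=upper,
        removed_ids=counts.location_ids[~keep],
    )
    layout = counts.layout
    if layout is not None:
        from .synthdata import TissueLayout

        layout = TissueLayout(
            layout.coords[keep],
            layout.domain_labels[keep],
            layout.model_name,
            layout.seed,
            layout.extent,
        )
    filtered = CountMatrix(
        counts=X[keep],
        location_ids=counts.location_ids[keep],
        gene_ids=counts.gene_ids,
        gene_class=counts.gene_class,
        layout=layout,
    )
    return filtered, report


def normalize(
    counts: CountMatrix,
    target_sum: float | None = None,
    log_transform: bool = True,
    scale_genes: bool = False,
) -> NormalizedExpression:
    """Library-size normalize, log1p, optionally scale genes to unit variance.

    Each location's counts are rescaled so its total equals ``target_sum``
    (default: the median of the per-location totals), then ``log(1 + x)`` is
    applied if requested.  Gene scaling divides each gene by its sample
    standard deviation without centering, which preserves sparsity; the PCA
    stage centers implicitly.
    """
    X = counts.counts.tocsr().astype(float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        raise ValueError(
            "zero-total locations reached normalize(); run qc_filter first"
        )
    if target_sum is None:
        target_sum = float(np.median(totals))
    sf = target_sum / totals
    X = sparse.diags(sf) @ X
    if log_transform:
        X.data = np.log1p(X.data)
    if scale_genes:
        mean = np.asarray(X.mean(axis=0)).ravel()
        mean_sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
        n = X.shape[0]
        var = np.maximum(mean_sq - mean**2, 0.0) * n / max(n - 1, 1)
        sd = np.sqrt(var)
        sd[sd == 0] = 1.0
        X = X @ sparse.diags(1.0 / sd)
    X = sparse.csr_matrix(X)
    if not np.all(np.isfinite(X.data)):
        raise ValueError("normalization produced non-finite values")
    return NormalizedExpression(
        X=X,
        location_ids=counts.location_ids,
        gene_ids=counts.gene_ids,
        total_counts_per_location=totals,
        target_sum=float(target_sum),
        log_transformed=log_transform,
        gene_scaled=scale_genes,
    )
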