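# Methods

## Model and pipeline

RASP decomposes spatially aware dimensionality reduction into two
orthogonal linear stages. The first is a randomized truncated PCA of the
normalized location-by-gene matrix `X` (n × m). Centering is implicit: the
range-finder and projection steps apply `X_c v = X v − 1 (x̄·v)` so the
sparse matrix is never densified. The randomized SVD uses a Gaussian test
matrix with 10 oversamples and 4 QR-stabilized power iterations — a
standard accuracy/cost point for expression matrices, whose spectra decay
quickly. Column signs are fixed by making the largest-magnitude loading of
each component positive, so results are reproducible across runs.

The second stage smooths the scores spatially. For each location the
`threshold` nearest neighbours (exact search; Euclidean by default,
Manhattan/Chebyshev optional) are stored with their true distances. The
diagonal self-distance is set to α to keep the inverse kernel finite:
per-row minimum neighbour distance by default, half of it for regular spot
grids where all neighbour distances are equal (Visium-style), or a fixed
constant. Weights are `w = 1/d^β` (alternatively Gaussian
`exp(−d²/2h²)` or quadratic `max(0, 1−(d/h)²)` with an explicit bandwidth
h in coordinate units), then every **column** is divided by its maximum.
Column-max standardization is kept deliberately even though row-stochastic
smoothing is more common; at β = 0 all stored weights become exactly 1
(a rectangular kernel) and `Ps = D_I P` is then (k+1) times the
neighbourhood mean. The kNN relation is row-wise and intentionally not
symmetrized. Ties at the kNN boundary follow the underlying exact-search
order; coincident points (stored distance 0 off the diagonal) are replaced
by the row's smallest positive stored distance before inversion, which
preserves their "nearest" status without infinite weights.

With covariates, the selected columns are smoothed by the same `D_I`
(covariates that are already spatial statistics, such as local density,
should be excluded), all covariate columns are standardized to zero mean
and unit variance so one covariate is not swamped by p PC columns, and a
second randomized PCA of `[Ps, Ys]` yields `Pc`. Whether the source
pipeline standardized covariates at this point is not documented; we
standardize, because without it a single covariate contributes negligible
variance relative to twenty PC columns and the integration would be
vacuous. The second-stage column means are retained so the reconstruction
path can undo the centering.

## Reduced-rank reconstruction

`Xr = Ps W^T + x̄` (via `Pc Wc^T` first when covariates were used)
projects expression onto the smoothed basis and back. Each gene column is
then thresholded at its q-quantile: the quantile is taken over the
*signed* reconstructed values (an absolute-value mode is available as an
option), computed as the linear-interpolation sample quantile — the
convention matters because thresholds shift with it. Entries whose
reconstructed magnitude falls below |x_q| revert to the original value if
it was positive and to exact zero otherwise; original entries that are
negative (possible after gene scaling) fall to zero by this rule, which we
keep as written. Optional variance matching multiplies the column by
`s = σ(orig ≠ 0) / max(σ(rec ≠ 0), 1e−10)` with sample (n−1) standard
deviations on both sides; genes with fewer than two nonzero original
values skip scaling with a warning. Reconstruction is intended for
visualization of spatial gene signatures, not for calibrated imputation.

## Clustering and metrics

Clustering operates on the smoothed scores, never on the coordinates: a
UMAP-style fuzzy kNN connectivity graph (default 10 neighbours) is
partitioned by Leiden, Louvain (igraph multilevel) or Walktrap (4 steps),
or a full-covariance Gaussian mixture is fit directly to the scores as the
model-based alternative. A bisection over the resolution parameter matches
a requested cluster count for the modularity-based methods; Walktrap and
the GMM take the count directly. Labels are relabeled to contiguous
integers by decreasing cluster size, and all methods are deterministic
given a seed.

Moran's I uses a row-standardized binary kNN weight graph on the
coordinates (default 6 neighbours; any weight matrix can be supplied).
For a partition, each cluster's one-hot indicator is scored and the
cluster-size-weighted mean is reported (per-cluster values available);
this aggregation is a package choice — conventions differ — so the weight
graph and aggregation are documented here and fixed by default. CHAOS
shifts the coordinates to the origin, divides by the largest axis range,
and averages each location's distance to its nearest neighbour *within its
cluster*; singleton clusters are skipped with a warning. Lower CHAOS means
spatially more compact domains. The ARI is the standard permutation-model
adjusted Rand index.

The parameter sweep computes the PCA embedding exactly once and rebuilds
only the sparse weights per (kNN, β) cell; the default β grid is 0 to 2 in
steps of 0.25. Selection maximizes Moran's I or ARI or minimizes CHAOS,
with ties broken toward smaller kNN, then smaller β.

## Synthetic tissues

The generator emulates reference-free ST simulation with two tissue
models. *Stripes*: cells scattered uniformly over a rectangle, domain =
vertical band index (8 equal-width bands by default). *Dots*: seven
circles of radius 60–130 spatial units at fixed positions over a dominant
background on a 1000 × 1000 rectangle — a synthetic fixture of this
package spanning small and large structures, emulating (not copying) any
particular published geometry.

Counts are ZINB: structural zeros with probability 0.5, otherwise NB with
mean `μ · fc[domain, gene]` and dispersion θ = 0.5 (variance μ + μ²/θ);
μ = 2 at baseline. The analytic zero probability
`π + (1−π)(θ/(θ+μ))^θ ≈ 0.724` anchors the generator tests. The default
panel holds 50 low-signal, 50 high-signal and 50 noise genes. Signal genes
are domain *markers*: gene g in a class is up-regulated only in domain
g mod K, by that domain's unique fold change — evenly spaced over 2.5–4
(low) and 6–10 (high). Two modelling points motivated this structure.
First, a single per-class fold change shared by all 50 genes makes the
signal rank-2, and under θ = 0.5 dispersion its leading eigenvalues sit
inside the Marchenko–Pastur noise bulk of a 2,000 × 150 matrix, so no
PCA-based method (spatial or not) can recover the domains at desk scale;
marker blocks spread the signal over K directions, which is also how real
tissue domains differ. Second, each domain still carries a unique fold
change per class, so domain identity is a scalar program strength, not an
arbitrary profile.

Stripes layouts default to width 1000 with height n/10, holding the cell
density at 0.01 cells/unit² — the density of the 10,000-cell reference
tissue on the full square. This keeps the ratio of smoothing radius (≈ 40
units at kNN = 50) to stripe width (125 units) invariant when n is scaled
down; with a fixed square extent, a 2,000-cell simulation would be
smoothed 2.2× more aggressively relative to its domains than the tissue it
emulates. The dots model keeps the fixed square (circle geometry does not
rescale along one axis); its acceptance property is a direction (local
beats domain-scale smoothing), which survives the density change.

What the generator does *not* emulate: segmentation noise, spatially
varying capture efficiency, within-domain cell-type mixtures, curved or
nested domain boundaries, and gene-gene correlation beyond the low-rank
domain programs. Passing the simulation benchmarks therefore demonstrates
that the pipeline recovers planted low-rank spatial signal under realistic
ZINB noise — not that it resolves arbitrary real tissues.

## Problem sizes and determinism

Test and acceptance runs use 2,000-cell tissues with 150 genes, 20 PCs and
the (kNN, β) settings recommended for each label scale; the ZINB
zero-fraction check uses 10⁶ draws. At these sizes the stripes domain
recovery lands at ARI ≈ 0.73–0.84 across simulation seeds (unsmoothed PCA:
≈ 0.25), and the dots tissue favours the local grid by a wide margin
(≈ 0.6–0.75 vs ≲ 0.1). Every stochastic step — layout, counts, PCA test
matrix, Leiden/Louvain, GMM — takes an explicit seed; identical seeds give
bitwise-identical smoothed scores. Oracle-equivalence tests (randomized
PCA vs exact SVD; sparse pipeline vs dense computation) use
decaying-spectrum low-rank fixtures whose rank is below p + oversamples,
where the randomized range finder is exact to machine precision; on
flat-spectrum random matrices randomized SVD does not (and should not be
expected to) reach such tolerances for trailing components.

## Known limitations

- Column-max standardization makes smoothed scores scale with the local
  weight-sum; at β > 0 this couples smoothing slightly to local density.
  It is retained for fidelity to the method definition.
- Walktrap cost grows quickly with n; prefer Leiden/Louvain beyond ~10⁴
  locations.
- `half_row_min` applies the halving per row; on an exactly regular grid
  this equals the global convention, on irregular data they differ and the
  per-row form is used for both modes.
- Reduced-rank reconstruction assumes neighbouring cells share expression;
  large kNN values smooth across tissue boundaries.
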