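# rasp-st — randomized spatial PCA for spatial transcriptomics

Spatial transcriptomics (ST) assays — Visium, Visium HD, MERFISH, Xenium,
Stereo-seq — measure gene expression at thousands to hundreds of thousands
of known tissue positions. Finding spatial domains (cortical layers, tumor
compartments, follicles) and cell types from such data benefits from
dimensionality reduction that is *spatially aware*, but most spatially
informed methods are far too slow for modern subcellular datasets.

`rasp-st` implements RASP (randomized spatial PCA), a two-stage approach
that stays within ordinary sparse linear algebra:

1. **Randomized PCA.** A randomized truncated SVD of the implicitly
   centered, sparse location-by-gene matrix `X` (n × m) gives loadings
   `W` (m × p) and scores `P = X_c W` (p = 20 by default).
2. **Spatial smoothing.** An exact kNN search on the spatial coordinates
   builds a row-wise sparse distance matrix `D`; the diagonal is set to a
   per-row α (the row's minimum neighbour distance, or half of it for
   regular spot grids); the inverse-distance kernel `w = 1/d^β` is applied
   entrywise, each *column* of the weight matrix is standardized by its
   maximum, and the smoothed scores are `Ps = D_I P`. β = 0 is a
   rectangular (uniform) kernel for tissue-scale domains; β ≈ 2
   concentrates weight on the closest neighbours for cell-type-scale
   structure. Gaussian and quadratic kernels and Manhattan/Chebyshev
   metrics are available as alternatives.
3. **Covariates (optional).** Location covariates (cell density, library
   size, volume) are optionally smoothed, standardized, appended to `Ps`,
   and a second randomized PCA returns covariate-integrated scores `Pc` —
   keeping a handful of covariates from being drowned by thousands of
   genes.

Downstream, the package clusters the smoothed scores on a UMAP-style
expression kNN graph (Leiden, Louvain, Walktrap, or a Gaussian mixture),
scores partitions with ARI (given truth labels), Moran's I and the CHAOS
statistic, sweeps the (kNN, β) grid while computing the PCA embedding only
once, and reconstructs de-noised gene expression by projecting through the
smoothed basis with ALRA-style per-gene quantile thresholding.

A synthetic-data module generates fully labeled test tissues — laminar
*stripes* and heterogeneous *dots* — with zero-inflated negative binomial
counts (μ = 2, θ = 0.5, 50% structural zeros; 50 low-signal, 50 high-signal
and 50 noise genes with per-domain marker fold changes), so the whole
pipeline is testable without external downloads.

## Worked example

```python
import numpy as np
from rasp import (RaspConfig, ari, default_gene_model, make_stripes_layout,
                  match_cluster_count, normalize, qc_filter, QCThresholds,
                  rasp, simulate_counts)

layout = make_stripes_layout(2000, 8, seed=0)          # 8 vertical bands
counts = simulate_counts(layout, default_gene_model(8), seed=1)
filtered, report = qc_filter(counts, set(), QCThresholds(min_reads=1))
expr = normalize(filtered)                             # median-target + log1p

config = RaspConfig(p=20, threshold=50, beta=0.0, seed=0)  # domain preset
result = rasp(expr, filtered.layout.coords, config)

labels = match_cluster_count(result.Ps, "leiden", 8, seed=0)
print("clusters:", labels.n_clusters)
print("ARI vs truth:", round(ari(filtered.layout.domain_labels, labels.labels), 3))
```

Output:

```
clusters: 8
ARI vs truth: 0.828
```

An ARI of 0.83 means the eight simulated laminar domains are essentially
recovered; clustering the *unsmoothed* PCA scores of the same matrix at the
same settings yields ARI ≈ 0.27, the gain contributed by the spatial
smoothing stage. For small heterogeneous structures (the dots tissue) the
cell-type settings (β = 2, kNN 2–20) recover the circular regions far
better than the domain settings (β = 0, kNN 50–100) — parameter guidance
that the `rasp sweep` / `rasp select` commands automate with label-free
Moran's I / CHAOS selection.

The same pipeline is available from the shell:

```sh
rasp simulate --model stripes --n-cells 2000 --seed 0 --out sim/
rasp run --counts sim/counts.mtx --coords sim/locations.csv \
         --preset hires-domain --seed 0 --out run/
rasp sweep --counts sim/counts.mtx --coords sim/locations.csv \
           --knn-grid 10,30,50 --beta-grid 0:2:0.5 --target-k 8 --out sweep.csv
rasp select --table sweep.csv --criterion max_moran
```

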