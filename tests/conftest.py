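import numpy as np
import pytest

from rasp import (
    QCThresholds,
    RaspConfig,
    compute_embedding,
    default_gene_model,
    make_stripes_layout,
    normalize,
    qc_filter,
    simulate_counts,
)


def low_rank_sparse(n, m, rank, seed, density=0.05):
    """Sparse nonneg-structured low-rank matrix with decaying spectrum.

    Built as a product of two sparse factors so the result is sparse and has
    rank <= ``rank``; singular values decay geometrically, emulating the
    spectral profile of expression data where a randomized range finder
    converges to machine precision.
    """
    from scipy import sparse

    rng = np.random.default_rng(seed)
    A = sparse.random(n, rank, density=density, random_state=rng, format="csr")
    scales = 10.0 * 0.7 ** np.arange(rank)
    B = sparse.random(rank, m, density=density, random_state=rng, format="csr")
    return sparse.csr_matrix(A @ sparse.diags(scales) @ B)


@pytest.fixture(scope="session")
def stripes_sim():
    """2,000-cell, 8-stripe tissue with the default marker panel (seed 0)."""
    layout = make_stripes_layout(2000, 8, seed=0)
    genes = default_gene_model(8)
    counts = simulate_counts(layout, genes, seed=1)
    filtered, _ = qc_filter(counts, set(), QCThresholds(min_reads=1))
    expr = normalize(filtered)
    return expr, filtered.layout


@pytest.fixture(scope="session")
def stripes_embedding(stripes_sim):
    expr, layout = stripes_sim
    config = RaspConfig(p=20, threshold=50, beta=0.0, seed=0)
    return compute_embedding(expr.X, config), expr, layout
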