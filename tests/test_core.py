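"""Core pipeline: randomized PCA, sparse distances, kernels, smoothing."""

import numpy as np
import pytest
from scipy import sparse
from scipy.spatial.distance import cdist

from rasp.core import (
    CovariateSpec,
    RaspConfig,
    apply_diagonal,
    build_sparse_distance,
    compute_embedding,
    randomized_pca,
    rasp,
    smooth,
    smooth_embedding,
    weight_kernel,
)
from tests.conftest import low_rank_sparse


def dense_pipeline_ps(X, C, p, threshold, beta, alpha_mode="row_min"):
    """Dense oracle for the full pipeline: exact SVD, dense kernel, dense
    multiply.  Only valid at desk scale."""
    X = np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X, float)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    P = U[:, :p] * s[:p]
    n = C.shape[0]
    D = cdist(C, C)
    D_masked = D.copy()
    np.fill_diagonal(D_masked, np.inf)
    order = np.argsort(D_masked, axis=1, kind="stable")
    W = np.zeros((n, n))
    for i in range(n):
        neigh = order[i, :threshold]
        W[i, neigh] = D[i, neigh]
        d0 = W[i, neigh][W[i, neigh] > 0].min()
        W[i, i] = d0 if alpha_mode == "row_min" else 0.5 * d0
    mask = W > 0
    Winv = np.zeros_like(W)
    Winv[mask] = 1.0 / W[mask] ** beta
    Winv /= Winv.max(axis=0)
    return Winv @ P, P


class TestRandomizedPCA:
    def test_rank_one_exact_recovery(self):
        rng = np.random.default_rng(0)
        u, v = rng.standard_normal(30), rng.standard_normal(10)
        X = np.outer(u, v)
        W, P, means = randomized_pca(X, 1, seed=0)
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(P @ W.T, Xc, atol=1e-10)

    def test_matches_exact_svd_on_decaying_spectrum(self):
        X = low_rank_sparse(200, 50, rank=25, seed=1)
        p = 15
        W, P, means = randomized_pca(X, p, seed=2)
        Xc = np.asarray(X.todense()) - np.asarray(X.mean(axis=0)).ravel()
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        for j in range(p):
            ref = U[:, j] * s[j]
            err = min(
                np.abs(P[:, j] - ref).max(), np.abs(P[:, j] + ref).max()
            )
            assert err < 1e-6 * s[0]

    def test_default_centers_but_does_not_scale(self):
        X = low_rank_sparse(60, 20, rank=10, seed=3)
        W, P, means = randomized_pca(X, 3, seed=0)
        np.testing.assert_allclose(means, np.asarray(X.mean(axis=0)).ravel())
        # scores of the centered matrix have zero column means
        np.testing.assert_allclose(P.mean(axis=0), 0, atol=1e-8)

    def test_loadings_orthonormal(self):
        X = low_rank_sparse(100, 40, rank=20, seed=4)
        W, _, _ = randomized_pca(X, 10, seed=0)
        np.testing.assert_allclose(W.T @ W, np.eye(10), atol=1e-8)

    def test_p_too_large_rejected(self):
        with pytest.raises(ValueError, match="p="):
            randomized_pca(np.ones((5, 3)), 4)

    def test_seed_determinism(self):
        X = low_rank_sparse(80, 30, rank=15, seed=5)
        W1, P1, _ = randomized_pca(X, 5, seed=42)
        W2, P2, _ = randomized_pca(X, 5, seed=42)
        np.testing.assert_array_equal(P1, P2)
        np.testing.assert_array_equal(W1, W2)


class TestBuildSparseDistance:
    def test_collinear_unit_spacing(self):
        C = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        D = build_sparse_distance(C, threshold=1)
        assert D.nnz == 3
        np.testing.assert_allclose(D.data, 1.0)

    def test_threshold_n_minus_one_is_full_matrix(self):
        rng = np.random.default_rng(0)
        C = rng.uniform(0, 10, size=(20, 2))
        D = np.asarray(build_sparse_distance(C, threshold=19).todense())
        full = cdist(C, C)
        np.testing.assert_allclose(D + np.diag(np.full(20, 0.0)), full, atol=1e-12)

    def test_sparsity_pattern_matches_argsort_oracle(self):
        rng = np.random.default_rng(1)
        C = rng.uniform(0, 100, size=(100, 2))
        k = 5
        D = build_sparse_distance(C, threshold=k).tolil()
        full = cdist(C, C)
        np.fill_diagonal(full, np.inf)
        for i in range(100):
            expected = set(np.argsort(full[i])[:k])
            assert set(D.rows[i]) == expected

    @pytest.mark.parametrize("metric", ["manhattan", "chebyshev"])
    def test_alternative_metrics_store_exact_distances(self, metric):
        rng = np.random.default_rng(2)
        C = rng.uniform(0, 10, size=(30, 2))
        D = build_sparse_distance(C, threshold=3, metric=metric).tocoo()
        full = cdist(C, C, metric={"manhattan": "cityblock", "chebyshev": "chebyshev"}[metric])
        for i, j, v in zip(D.row, D.col, D.data):
            assert v == pytest.approx(full[i, j], abs=1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            build_sparse_distance(np.array([[np.inf, 0.0]]), 1)
        with pytest.raises(ValueError):
            build_sparse_distance(np.zeros((5, 2)), 0)


class TestApplyDiagonal:
    def make_row(self):
        # one location with off-diagonal stored distances {2, 3, 5}
        D = sparse.lil_matrix((4, 4))
        D[0, 1], D[0, 2], D[0, 3] = 2.0, 3.0, 5.0
        D[1, 0] = 2.0
        D[2, 0] = 3.0
        D[3, 0] = 5.0
        return D.tocsr()

    def test_row_min(self):
        D = apply_diagonal(self.make_row(), "row_min")
        assert D[0, 0] == 2.0

    def test_half_row_min(self):
        D = apply_diagonal(self.make_row(), "half_row_min")
        assert D[0, 0] == 1.0

    def test_fixed(self):
        D = apply_diagonal(self.make_row(), "fixed:0.5")
        assert D[0, 0] == 0.5
        assert D[2, 2] == 0.5

    def test_empty_row_rejected(self):
        D = sparse.csr_matrix((1, 1))
        with pytest.raises(ValueError, match="no positive"):
            apply_diagonal(D, "row_min")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="alpha_mode"):
            apply_diagonal(self.make_row(), "median")


class TestWeightKernel:
    def prepared(self, n=50, threshold=5, seed=0):
        rng = np.random.default_rng(seed)
        C = rng.uniform(0, 100, size=(n, 2))
        D = apply_diagonal(build_sparse_distance(C, threshold), "row_min")
        return C, D

    def test_beta_zero_is_rectangular_kernel(self):
        _, D = self.prepared()
        w = weight_kernel(D, beta=0.0)
        np.testing.assert_array_equal(w.D_I.data, 1.0)

    def test_matches_dense_inverse_square_oracle(self):
        C, D = self.prepared()
        w = weight_kernel(D, beta=2.0)
        dense = np.asarray(D.todense())
        mask = dense > 0
        ref = np.zeros_like(dense)
        ref[mask] = 1.0 / dense[mask] ** 2
        ref /= ref.max(axis=0)
        np.testing.assert_allclose(np.asarray(w.D_I.todense()), ref, atol=1e-12)

    def test_column_max_is_one(self):
        _, D = self.prepared(seed=3)
        w = weight_kernel(D, beta=1.5)
        colmax = w.D_I.max(axis=0).toarray().ravel()
        np.testing.assert_allclose(colmax[colmax > 0], 1.0)
        assert w.D_I.data.min() > 0 and w.D_I.data.max() <= 1.0

    def test_gaussian_kernel_formula(self):
        _, D = self.prepared()
        h = 10.0
        w = weight_kernel(D, kernel="gaussian", bandwidth=h)
        dense = np.asarray(D.todense())
        mask = dense > 0
        ref = np.zeros_like(dense)
        ref[mask] = np.exp(-(dense[mask] ** 2) / (2 * h**2))
        ref /= ref.max(axis=0)
        np.testing.assert_allclose(np.asarray(w.D_I.todense()), ref, atol=1e-12)

    def test_quadratic_kernel_drops_out_of_range(self):
        D = sparse.csr_matrix(np.diag([1.0, 1.0]) + np.array([[0, 5.0], [5.0, 0]]))
        w = weight_kernel(D, kernel="quadratic", bandwidth=2.0)
        assert w.D_I[0, 1] == 0  # distance 5 > bandwidth 2 -> weight 0
        assert w.D_I[0, 0] > 0

    def test_bandwidth_required_for_kernels(self):
        _, D = self.prepared()
        with pytest.raises(ValueError, match="bandwidth"):
            weight_kernel(D, kernel="gaussian")

    def test_negative_beta_rejected(self):
        _, D = self.prepared()
        with pytest.raises(ValueError, match="beta"):
            weight_kernel(D, beta=-1.0)

    def test_increasing_beta_concentrates_weight_on_near_neighbours(self):
        # monotone locality: the near/far weight ratio grows strictly with beta
        C, D = self.prepared(seed=5)
        i = 0
        row = D.getrow(i).tocoo()
        off = [(j, v) for j, v in zip(row.col, row.data) if j != i]
        near = min(off, key=lambda t: t[1])[0]
        far = max(off, key=lambda t: t[1])[0]
        dense = np.asarray(D.todense())
        ratios = []
        for beta in [0.0, 0.5, 1.0, 2.0, 3.0]:
            w = weight_kernel(D, beta=beta)
            # undo the column standardization to compare raw kernel values
            raw = np.zeros_like(dense)
            raw[dense > 0] = 1.0 / dense[dense > 0] ** beta
            colmax = raw.max(axis=0)
            ratios.append(
                (w.D_I[i, near] * colmax[near]) / (w.D_I[i, far] * colmax[far])
            )
        assert all(b > a for a, b in zip(ratios, ratios[1:]))

    def test_coincident_points_get_row_min_positive_distance(self):
        C = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 0.0]])
        D = apply_diagonal(build_sparse_distance(C, threshold=2), "row_min")
        w = weight_kernel(D, beta=1.0)
        assert np.isfinite(w.D_I.data).all()
        assert w.D_I.data.min() > 0


class TestSmooth:
    def test_identity_weights_return_input(self):
        from rasp.core import SparseSpatialWeights

        M = np.random.default_rng(0).standard_normal((10, 3))
        w = SparseSpatialWeights(sparse.identity(10, format="csr"), 1, "row_min", 0, "euclidean", "inverse_distance")
        np.testing.assert_array_equal(smooth(w, M), M)

    def test_matches_dense_product(self):
        from rasp.core import SparseSpatialWeights

        rng = np.random.default_rng(1)
        A = sparse.random(100, 100, density=0.05, random_state=rng, format="csr")
        M = rng.standard_normal((100, 5))
        w = SparseSpatialWeights(A, 5, "row_min", 2, "euclidean", "inverse_distance")
        np.testing.assert_allclose(smooth(w, M), np.asarray(A.todense()) @ M, atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        from rasp.core import SparseSpatialWeights

        w = SparseSpatialWeights(sparse.identity(4, format="csr"), 1, "row_min", 0, "euclidean", "inverse_distance")
        with pytest.raises(ValueError):
            smooth(w, np.ones((5, 2)))


class TestRaspPipeline:
    def setup_case(self, n=120, m=40, p=8, seed=0):
        rng = np.random.default_rng(seed)
        X = low_rank_sparse(n, m, rank=p + 5, seed=seed)
        C = rng.uniform(0, 50, size=(n, 2))
        return X, C

    def test_sparse_pipeline_matches_dense_oracle(self):
        X, C = self.setup_case()
        cfg = RaspConfig(p=8, threshold=10, beta=2.0, seed=0)
        res = rasp(X, C, cfg)
        ref, _ = dense_pipeline_ps(X, C, p=8, threshold=10, beta=2.0)
        for j in range(8):
            err = min(
                np.abs(res.Ps[:, j] - ref[:, j]).max(),
                np.abs(res.Ps[:, j] + ref[:, j]).max(),
            )
            assert err < 1e-6

    def test_no_covariates_returns_ps_only(self):
        X, C = self.setup_case()
        res = rasp(X, C, RaspConfig(p=5, threshold=5, seed=0))
        assert res.Pc is None and res.Ys is None and res.Wc is None
        assert res.Ps.shape == (120, 5)
        assert res.W.shape == (40, 5)

    def test_covariates_give_pc_of_requested_rank(self):
        X, C = self.setup_case()
        rng = np.random.default_rng(3)
        cov = CovariateSpec(rng.standard_normal((120, 2)))
        res = rasp(X, C, RaspConfig(p=5, threshold=5, seed=0), cov)
        assert res.Pc.shape == (120, 5)
        assert res.Wc.shape == (7, 5)
        assert res.Ys.shape == (120, 2)

    def test_duplicated_pc_covariate_preserves_subspace(self):
        # a covariate equal to Ps[:, 0] adds no information: the second-stage
        # top-p subspace equals the span of Ps (principal angles ~ 0)
        X, C = self.setup_case(p=4)
        cfg = RaspConfig(p=4, threshold=5, seed=0)
        base = rasp(X, C, cfg)
        cov = CovariateSpec(base.Ps[:, 0].copy(), smooth_flags=[False])
        res = rasp(X, C, cfg, cov)
        Ps_c = base.Ps - base.Ps.mean(axis=0)
        Pc_c = res.Pc - res.Pc.mean(axis=0)
        Qa, _ = np.linalg.qr(Ps_c)
        Qb, _ = np.linalg.qr(Pc_c)
        sv = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
        angles = np.arccos(np.clip(sv, -1, 1))
        assert angles.max() < 1e-6

    def test_covariate_misalignment_rejected(self):
        X, C = self.setup_case()
        cov = CovariateSpec(np.ones((50, 1)))
        with pytest.raises(ValueError, match="align"):
            rasp(X, C, RaspConfig(p=3, threshold=5), cov)

    def test_row_misalignment_rejected(self):
        X, C = self.setup_case()
        with pytest.raises(ValueError, match="rows"):
            rasp(X, C[:-10], RaspConfig(p=3, threshold=5))

    def test_seed_determinism_bitwise(self):
        X, C = self.setup_case()
        cfg = RaspConfig(p=6, threshold=8, beta=1.0, seed=7)
        a = rasp(X, C, cfg)
        b = rasp(X, C, cfg)
        np.testing.assert_array_equal(a.Ps, b.Ps)

    def test_embedding_reused_across_smoothing_settings(self):
        # the rPCA embedding is computed once; new (threshold, beta) reuse it
        X, C = self.setup_case()
        cfg = RaspConfig(p=6, threshold=8, beta=1.0, seed=7)
        emb = compute_embedding(X, cfg)
        from dataclasses import replace

        res1 = smooth_embedding(emb, C, replace(cfg, threshold=3, beta=0.0))
        res2 = smooth_embedding(emb, C, replace(cfg, threshold=12, beta=2.0))
        np.testing.assert_array_equal(res1.W, res2.W)
        np.testing.assert_array_equal(res1.P, res2.P)
        assert not np.array_equal(res1.Ps, res2.Ps)

    def test_identity_weights_recover_unsmoothed_scores(self):
        # with D_I = I the smoothed scores equal the plain PCA scores
        from rasp.core import SparseSpatialWeights

        X, C = self.setup_case()
        cfg = RaspConfig(p=5, threshold=5, seed=0)
        emb = compute_embedding(X, cfg)
        w = SparseSpatialWeights(sparse.identity(120, format="csr"), 1, "row_min", 0, "euclidean", "inverse_distance")
        np.testing.assert_array_equal(smooth(w, emb.P), emb.P)


def test_config_validation():
    with pytest.raises(ValueError):
        RaspConfig(p=0)
    with pytest.raises(ValueError):
        RaspConfig(beta=-0.5)
    with pytest.raises(ValueError):
        RaspConfig(distance_metric="cosine")
    with pytest.raises(ValueError):
        RaspConfig(alpha_mode="bogus")
    assert RaspConfig(alpha_mode="fixed:1.5").alpha_mode == "fixed:1.5"
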