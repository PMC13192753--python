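import itertools

import numpy as np
import pytest

from gutlink.scca import (component_significance_loocv, fit_sparse_cca,
                          pmd_rank_one, soft_threshold, tune_penalties_loocv)


class TestSoftThreshold:
    @pytest.mark.parametrize("x,delta,expect", [
        (3.0, 1.0, 2.0),
        (-0.5, 1.0, 0.0),
        (-3.0, 1.0, -2.0),
    ])
    def test_scalar_examples(self, x, delta, expect):
        assert soft_threshold(np.array([x]), delta)[0] == expect

    def test_zero_delta_is_identity(self):
        x = np.array([1.0, -2.0, 0.0])
        assert np.array_equal(soft_threshold(x, 0.0), x)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.ones(3), -0.1)


class TestPmdRankOne:
    def test_no_penalty_recovers_svd_of_rank_one(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(10)
        a /= np.linalg.norm(a)
        b = rng.standard_normal(6)
        b /= np.linalg.norm(b)
        u, v, d, ok = pmd_rank_one(4.2 * np.outer(a, b), 1.0, 1.0)
        assert ok
        assert np.isclose(d, 4.2, atol=1e-6)
        assert min(np.abs(u - a).max(), np.abs(u + a).max()) < 1e-6

    def test_dominant_entry_selects_basis_vectors(self):
        # enumeration oracle on a 5x4 matrix: with a strict L1 budget the
        # best single-support factor is the largest-magnitude entry
        K = np.array([
            [0.1, -0.2, 0.3, 0.1],
            [0.2, 5.0, -0.1, 0.0],
            [-0.3, 0.1, 0.2, 0.4],
            [0.0, 0.3, -0.2, 0.1],
            [0.2, -0.1, 0.1, 0.3],
        ])
        best = max(itertools.product(range(5), range(4)),
                   key=lambda ij: abs(K[ij]))
        u, v, d, _ = pmd_rank_one(K, 0.21, 0.26)  # c1=0.21*sqrt(5)<1 forces a spike
        assert np.flatnonzero(u).tolist() == [best[0]]
        assert np.flatnonzero(v).tolist() == [best[1]]
        assert np.isclose(d, abs(K[best]), atol=1e-9)

    def test_sign_flip_leaves_d_unchanged(self):
        rng = np.random.default_rng(1)
        K = rng.standard_normal((8, 5))
        u1, v1, d1, _ = pmd_rank_one(K, 0.7, 0.7)
        u2, v2, d2, _ = pmd_rank_one(-K, 0.7, 0.7)
        assert np.isclose(d1, d2, atol=1e-8)

    def test_loadings_satisfy_constraints(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p, q = rng.integers(4, 30, size=2)
            c1, c2 = rng.uniform(0.2, 1.0, size=2)
            u, v, d, _ = pmd_rank_one(rng.standard_normal((p, q)), c1, c2)
            if np.any(u):
                assert np.isclose(np.linalg.norm(u), 1.0, atol=1e-6)
                assert np.abs(u).sum() <= max(1.0, c1 * np.sqrt(p)) + 1e-6
            if np.any(v):
                assert np.isclose(np.linalg.norm(v), 1.0, atol=1e-6)
                assert np.abs(v).sum() <= max(1.0, c2 * np.sqrt(q)) + 1e-6

    def test_invalid_penalty_fraction(self):
        with pytest.raises(ValueError):
            pmd_rank_one(np.eye(3), 0.0, 0.5)


def _planted_two_modules(rng, n=60, noiseless=True):
    """Two disjoint gene modules mapped exactly to two taxon groups.

    The factors are orthogonalized in-sample so the standardized
    cross-product is exactly block diagonal; the first module is larger
    (10 genes / 4 taxa vs 6 / 2) so extraction order is determined.
    """
    f1 = rng.standard_normal(n)
    f2 = rng.standard_normal(n)
    design = np.column_stack([np.ones(n), f1])
    f2 = f2 - design @ np.linalg.lstsq(design, f2, rcond=None)[0]
    noise = 0.0 if noiseless else 0.3
    X = rng.standard_normal((n, 50)) * noise
    X[:, 16:] = 0.0 if noiseless else X[:, 16:]
    X[:, :10] += np.outer(f1, rng.uniform(0.9, 1.1, 10))
    X[:, 10:16] += np.outer(f2, rng.uniform(0.9, 1.1, 6))
    Z = rng.standard_normal((n, 20)) * noise
    Z[:, 6:] = 0.0 if noiseless else Z[:, 6:]
    Z[:, :4] += np.outer(f1, rng.uniform(0.9, 1.1, 4))
    Z[:, 4:6] += np.outer(f2, rng.uniform(0.9, 1.1, 2))
    return X, Z


class TestFitSparseCca:
    def test_planted_disjoint_modules_recovered_exactly(self):
        rng = np.random.default_rng(3)
        X, Z = _planted_two_modules(rng)
        model = fit_sparse_cca(X, Z, 0.82, 0.85, K=2)
        assert set(model.gene_support(1)) == set(range(10))
        assert set(model.gene_support(2)) == set(range(10, 16))
        assert set(model.taxon_support(1)) == set(range(4))
        assert set(model.taxon_support(2)) == set(range(4, 6))

    def test_k1_matches_rank_one_on_standardized_cross_product(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((20, 8))
        Z = rng.standard_normal((20, 6))
        model = fit_sparse_cca(X, Z, 0.8, 0.8, K=1)

        def std(M):
            return (M - M.mean(0)) / M.std(0, ddof=1)

        u, v, d, _ = pmd_rank_one(std(X).T @ std(Z), 0.8, 0.8)
        assert np.isclose(model.d[0], d, atol=1e-6)
        assert np.allclose(np.abs(model.u.to_numpy()[:, 0]), np.abs(u), atol=1e-5)

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((15, 10))
        Z = rng.standard_normal((15, 7))
        perm = rng.permutation(15)
        a = fit_sparse_cca(X, Z, 0.6, 0.6, K=2)
        b = fit_sparse_cca(X[perm], Z[perm], 0.6, 0.6, K=2)
        assert np.allclose(a.u.to_numpy(), b.u.to_numpy(), atol=1e-8)
        assert np.allclose(a.d, b.d, atol=1e-8)

    def test_full_penalty_matches_truncated_svd(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((25, 9))
        Z = rng.standard_normal((25, 7))
        model = fit_sparse_cca(X, Z, 1.0, 1.0, K=3, tol=1e-10, max_iter=5000)

        def std(M):
            return (M - M.mean(0)) / M.std(0, ddof=1)

        U, s, Vt = np.linalg.svd(std(X).T @ std(Z))
        assert np.allclose(model.d, s[:3], atol=1e-5)
        for k in range(3):
            u = model.u.to_numpy()[:, k]
            assert min(np.abs(u - U[:, k]).max(), np.abs(u + U[:, k]).max()) < 1e-5

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_sparse_cca(np.ones((2, 4)), np.ones((2, 3)), 0.5, 0.5, K=1)


class TestTunePenalties:
    def test_single_point_grid_returned(self):
        rng = np.random.default_rng(7)
        X, Z = _planted_two_modules(rng, n=30, noiseless=False)
        best, scores = tune_penalties_loocv(X, Z, grid=[(0.4, 0.4)])
        assert best == (0.4, 0.4)
        assert len(scores) == 1

    def test_selected_score_is_grid_maximum(self):
        rng = np.random.default_rng(8)
        X, Z = _planted_two_modules(rng, n=30, noiseless=False)
        grid = [(a, b) for a in (0.2, 0.6, 1.0) for b in (0.2, 0.6, 1.0)]
        best, scores = tune_penalties_loocv(X, Z, grid=grid)
        top = scores.loc[scores["score"].idxmax()]
        best_rows = scores[np.isclose(scores["score"], top["score"])]
        assert any(np.isclose(best[0], r.c1_frac) and np.isclose(best[1], r.c2_frac)
                   for r in best_rows.itertuples())

    def test_pure_noise_scores_near_zero(self):
        rng = np.random.default_rng(9)
        low = 0
        for _ in range(10):
            X = rng.standard_normal((40, 12))
            Z = rng.standard_normal((40, 8))
            best, scores = tune_penalties_loocv(X, Z, grid=[(0.5, 0.5), (1.0, 1.0)])
            if scores["score"].abs().max() < 0.5:
                low += 1
        assert low >= 9


class TestComponentSignificance:
    def test_planted_factor_flagged_noise_not(self):
        rng = np.random.default_rng(10)
        hits = trailing = 0
        n_seeds = 20
        for _ in range(n_seeds):
            f = rng.standard_normal(40)
            X = rng.standard_normal((40, 25))
            X[:, :5] += np.outer(f, rng.uniform(0.8, 1.2, 5)) * 1.5
            Z = rng.standard_normal((40, 15))
            Z[:, :3] += np.outer(f, rng.uniform(0.8, 1.2, 3)) * 1.5
            sig = component_significance_loocv(X, Z, 0.6, 0.6, K=5)
            flags = sig.table.set_index("component")["flagged"]
            hits += bool(flags[1])
            trailing += not (flags[3] or flags[4] or flags[5])
        assert hits >= 0.9 * n_seeds
        assert trailing >= 0.9 * n_seeds

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            component_significance_loocv(np.ones((3, 4)), np.ones((3, 4)),
                                         0.5, 0.5, K=2)

    def test_k_exceeding_dimension_rejected(self):
        rng = np.random.default_rng(11)
        with pytest.raises(ValueError):
            component_significance_loocv(rng.standard_normal((10, 4)),
                                         rng.standard_normal((10, 3)),
                                         0.5, 0.5, K=5)
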