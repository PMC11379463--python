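

import numpy as np
import pytest

from cclone import fit_wnmf, solve_weighted_nnls, weighted_cost
from cclone.wnmf import _batched_gram_nnls


def grid_nnls_oracle(A, b, w, upper=4.0, steps=21, refinements=4):
    """Exhaustive non-negative minimizer on a grid, refined around the best."""
    A, b, w = np.asarray(A, float), np.asarray(b, float), np.asarray(w, float)
    k = A.shape[1]
    lo = np.zeros(k)
    hi = np.full(k, upper)
    best = None
    for _ in range(refinements):
        axes = [np.linspace(lo[i], hi[i], steps) for i in range(k)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, k)
        resid = b[None, :] - grid @ A.T
        f = (w[None, :] * resid * resid).sum(axis=1)
        best = grid[int(np.argmin(f))]
        span = (hi - lo) / (steps - 1)
        lo = np.maximum(best - 2 * span, 0.0)
        hi = best + 2 * span
    return best


class TestWeightedCost:
    def test_exact_fit_on_weighted_entries(self):
        M = np.array([[1.0, 0.5], [0.0, 0.0]])
        W = np.array([[1.0, 1.0], [1.0, 0.0]])
        C = np.array([[1.0], [0.0]])
        V = np.array([[1.0, 0.5]])
        assert weighted_cost(M, W, C, V) == 0.0

    def test_single_term_arithmetic(self):
        assert weighted_cost([[1.0]], [[0.5]], [[0.0]], [[1.0]]) == pytest.approx(0.5)

    def test_zero_weight_entries_never_contribute(self):
        rng = np.random.default_rng(0)
        M = rng.random((6, 5))
        W = rng.integers(0, 2, (6, 5)).astype(float)
        C, V = rng.random((6, 2)), rng.random((2, 5))
        e1 = weighted_cost(M, W, C, V)
        M2 = M.copy()
        M2[W == 0] = rng.random((W == 0).sum()) * 100
        assert weighted_cost(M2, W, C, V) == pytest.approx(e1)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_cost(np.ones((2, 2)), np.ones((2, 3)), np.ones((2, 1)), np.ones((1, 2)))


class TestSolveWeightedNnls:
    def test_unconstrained_optimum_nonnegative(self):
        x = solve_weighted_nnls([[1.0], [1.0]], [2.0, 4.0], [1.0, 1.0])
        assert x == pytest.approx([3.0])

    def test_nonnegativity_binds(self):
        assert solve_weighted_nnls([[1.0]], [-1.0], [1.0]) == pytest.approx([0.0])

    def test_all_zero_weights_give_zero(self):
        np.testing.assert_array_equal(
            solve_weighted_nnls(np.ones((3, 2)), np.ones(3), np.zeros(3)), np.zeros(2)
        )

    def test_weights_reweight_the_solution(self):
        # two inconsistent observations; heavy weight pulls x toward it
        x = solve_weighted_nnls([[1.0], [1.0]], [1.0, 3.0], [9.0, 1.0])
        assert x == pytest.approx([(9 * 1 + 3) / 10])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.random((5, 4))
        b = rng.uniform(-1, 2, 5)
        w = rng.uniform(0, 2, 5)
        x = solve_weighted_nnls(A, b, w)
        x_oracle = grid_nnls_oracle(A, b, w)
        r, ro = b - A @ x, b - A @ x_oracle
        f = float(np.sum(w * r * r))
        fo = float(np.sum(w * ro * ro))
        assert f <= fo + 1e-4

    @pytest.mark.parametrize("seed", range(8))
    def test_batched_solver_agrees_with_nnls_route(self, seed):
        rng = np.random.default_rng(seed + 100)
        A = rng.random((10, 3))
        B = rng.uniform(-1, 2, (10, 6))
        Wt = rng.uniform(0, 2, (10, 6))
        G = np.einsum("ij,ik,il->jkl", Wt, A, A)
        H = (Wt * B).T @ A
        X = _batched_gram_nnls(G, H)
        for j in range(6):
            x_ref = solve_weighted_nnls(A, B[:, j], Wt[:, j])
            r1 = B[:, j] - A @ X[j]
            r2 = B[:, j] - A @ x_ref
            f1 = float(np.sum(Wt[:, j] * r1 * r1))
            f2 = float(np.sum(Wt[:, j] * r2 * r2))
            assert f1 <= f2 + 1e-10


def random_instance(rng, n=50, m=40, k=3):
    M = rng.choice([0.0, 0.5, 1.0], size=(n, m))
    W = rng.choice([0.0, 0.5, 1.0], size=(n, m), p=[0.5, 0.3, 0.2])
    return M, W, k


class TestFitWnmf:
    def test_exact_rank2_recovery(self):
        rng = np.random.default_rng(1)
        C_true = np.zeros((30, 2))
        C_true[:15, 0] = 1.0
        C_true[15:, 1] = 1.0
        V_true = rng.choice([0.0, 0.5, 1.0], size=(2, 20))
        M = C_true @ V_true
        W = np.ones_like(M)
        model = fit_wnmf(M, W, K=2, seed=0)
        assert model.E < 1e-8 * M.size

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        M, W, k = random_instance(rng)
        m1 = fit_wnmf(M, W, k, seed=42)
        m2 = fit_wnmf(M, W, k, seed=42)
        np.testing.assert_array_equal(m1.C, m2.C)
        np.testing.assert_array_equal(m1.V, m2.V)
        np.testing.assert_array_equal(m1.cost_trace, m2.cost_trace)

    @pytest.mark.parametrize("seed", range(5))
    def test_cost_trace_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        M, W, k = random_instance(rng)
        model = fit_wnmf(M, W, k, seed=seed)
        diffs = np.diff(model.cost_trace)
        assert np.all(diffs <= 1e-9 * max(model.cost_trace[0], 1.0))

    def test_final_cost_matches_weighted_cost(self):
        rng = np.random.default_rng(3)
        M, W, k = random_instance(rng)
        model = fit_wnmf(M, W, k, seed=0)
        assert model.E == pytest.approx(weighted_cost(M, W, model.C, model.V))
        assert (model.C >= 0).all() and (model.V >= 0).all()

    def test_masking_invariance(self):
        rng = np.random.default_rng(4)
        M, W, k = random_instance(rng)
        m1 = fit_wnmf(M, W, k, seed=7)
        M2 = M.copy()
        M2[W == 0] = 99.0
        m2 = fit_wnmf(M2, W, k, seed=7)
        np.testing.assert_array_equal(m1.cost_trace, m2.cost_trace)
        np.testing.assert_array_equal(m1.C, m2.C)
        np.testing.assert_array_equal(m1.V, m2.V)

    def test_scale_indeterminacy(self):
        rng = np.random.default_rng(5)
        M, W, k = random_instance(rng, n=20, m=15)
        model = fit_wnmf(M, W, k, seed=0)
        a = np.array([2.0, 0.5, 3.0])
        e1 = weighted_cost(M, W, model.C, model.V)
        e2 = weighted_cost(M, W, model.C * a, model.V / a[:, None])
        assert e2 == pytest.approx(e1)

    def test_unweighted_limit_matches_plain_nnls(self):
        # with W == 1, one V half-step equals column-wise unconstrained NNLS
        import scipy.optimize

        rng = np.random.default_rng(6)
        M = rng.random((8, 5))
        W = np.ones_like(M)
        C = rng.random((8, 3))
        from cclone.wnmf import _update_V

        V = _update_V(M, W, C, np.zeros((3, 5)))
        for j in range(5):
            x_ref, _ = scipy.optimize.nnls(C, M[:, j])
            np.testing.assert_allclose(V[:, j], x_ref, atol=1e-8)

    def test_zero_weight_rows_and_columns_handled(self):
        rng = np.random.default_rng(7)
        M, W, k = random_instance(rng, n=20, m=15)
        W[3, :] = 0.0
        W[:, 5] = 0.0
        model = fit_wnmf(M, W, k, seed=0)
        np.testing.assert_array_equal(model.C[3], np.zeros(k))
        np.testing.assert_array_equal(model.V[:, 5], np.zeros(k))

    @pytest.mark.parametrize("bad_k", [1, 100])
    def test_invalid_k_rejected(self, bad_k):
        with pytest.raises(ValueError):
            fit_wnmf(np.ones((5, 5)), np.ones((5, 5)), K=bad_k)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            fit_wnmf(np.empty((0, 0)), np.empty((0, 0)), K=2)
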