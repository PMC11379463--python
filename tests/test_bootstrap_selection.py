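import itertools

import numpy as np
import pytest

from cclone import align_factors, bootstrap_wnmf, orthogonality_score, select_best
from cclone.bootstrap import BootstrapResult


def brute_force_alignment(ref, cand):
    """Best column permutation by exhaustive search over all K! options."""
    K = ref.shape[1]

    def cos(a, b):
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        return 0.0 if na == 0 or nb == 0 else float(a @ b / (na * nb))

    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(K)):
        score = sum(cos(ref[:, i], cand[:, perm[i]]) for i in range(K))
        if score > best_score:
            best_score, best_perm = score, perm
    return np.array(best_perm), best_score


class TestAlignFactors:
    def test_identity(self):
        C = np.random.default_rng(0).random((6, 3))
        np.testing.assert_array_equal(align_factors(C, C), [0, 1, 2])

    def test_recovers_column_swap(self):
        C = np.random.default_rng(1).random((6, 3))
        swapped = C[:, [2, 0, 1]]
        perm = align_factors(C, swapped)
        np.testing.assert_allclose(swapped[:, perm], C)

    @pytest.mark.parametrize("K", [2, 3, 4, 5, 6])
    def test_matches_brute_force(self, K):
        rng = np.random.default_rng(K)
        for _ in range(10):
            ref = rng.random((8, K))
            cand = rng.random((8, K))
            perm = align_factors(ref, cand)
            _, best_score = brute_force_alignment(ref, cand)
            score = sum(
                float(ref[:, i] @ cand[:, perm[i]]
                      / (np.linalg.norm(ref[:, i]) * np.linalg.norm(cand[:, perm[i]])))
                for i in range(K)
            )
            assert score == pytest.approx(best_score, abs=1e-10)

    def test_zero_norm_column_tolerated(self):
        ref = np.eye(3)
        cand = np.eye(3)
        cand[:, 1] = 0.0
        perm = align_factors(ref, cand)
        assert sorted(perm) == [0, 1, 2]


class TestOrthogonalityScore:
    def test_disjoint_supports_score_zero(self):
        C = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        assert orthogonality_score(C) == pytest.approx(0.0)

    def test_identical_columns_score_minus_one(self):
        C = np.array([[1.0, 1.0], [2.0, 2.0]])
        assert orthogonality_score(C) == pytest.approx(-1.0)

    def test_half_overlap_closed_form(self):
        C = np.array([[1.0, 1.0], [1.0, 0.0]])
        assert orthogonality_score(C) == pytest.approx(-1 / np.sqrt(2))

    def test_invariant_to_column_rescaling(self):
        rng = np.random.default_rng(0)
        C = rng.random((10, 4))
        scale = np.array([0.1, 3.0, 7.5, 1.0])
        assert orthogonality_score(C * scale) == pytest.approx(orthogonality_score(C))

    def test_k2_equals_negative_cosine(self):
        rng = np.random.default_rng(1)
        C = rng.random((12, 2))
        cos = C[:, 0] @ C[:, 1] / (np.linalg.norm(C[:, 0]) * np.linalg.norm(C[:, 1]))
        assert orthogonality_score(C) == pytest.approx(-cos)

    def test_range_for_nonnegative_factors(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            s = orthogonality_score(rng.random((15, 3)))
            assert -1.0 - 1e-12 <= s <= 0.0 + 1e-12

    def test_single_factor_rejected(self):
        with pytest.raises(ValueError):
            orthogonality_score(np.ones((5, 1)))


def planted_two_clone(n=40, m=30):
    C = np.zeros((n, 2))
    C[: n // 2, 0] = 1.0
    C[n // 2 :, 1] = 1.0
    rng = np.random.default_rng(0)
    V = rng.choice([0.0, 0.5, 1.0], size=(2, m))
    M = C @ V
    return M, np.ones_like(M)


class TestBootstrap:
    def test_replicates_agree_on_noiseless_data(self):
        M, W = planted_two_clone()
        res = bootstrap_wnmf(M, W, K=2, n_bootstrap=8, seed=0)
        # normalize scale before comparing variance across replicates
        assert res.var_C.max() / max(res.mean_C.max() ** 2, 1e-12) < 1e-3

    def test_single_replicate_has_zero_variance(self):
        M, W = planted_two_clone()
        res = bootstrap_wnmf(M, W, K=2, n_bootstrap=1, seed=3)
        np.testing.assert_array_equal(res.var_C, np.zeros_like(res.var_C))
        sampled = res.n_sampled > 0
        np.testing.assert_array_equal(res.var_V[:, sampled], 0.0)

    def test_deterministic_given_master_seed(self):
        M, W = planted_two_clone()
        r1 = bootstrap_wnmf(M, W, K=2, n_bootstrap=5, seed=11)
        r2 = bootstrap_wnmf(M, W, K=2, n_bootstrap=5, seed=11)
        np.testing.assert_array_equal(r1.mean_C, r2.mean_C)
        np.testing.assert_array_equal(r1.mean_V, r2.mean_V)
        assert r1.replicate_seeds == r2.replicate_seeds

    def test_subsample_fraction_respected(self):
        M, W = planted_two_clone(m=30)
        res = bootstrap_wnmf(M, W, K=2, n_bootstrap=4, fraction=0.9, seed=0)
        assert res.n_sampled.max() <= 4
        # each replicate draws round(0.9 * 30) = 27 variants
        assert res.n_sampled.sum() == 4 * 27

    def test_too_few_variants_rejected(self):
        M, W = planted_two_clone(m=8)
        with pytest.raises(ValueError, match="10"):
            bootstrap_wnmf(M, W, K=2, n_bootstrap=2, seed=0)

    def test_permutations_recorded_and_invertible(self):
        M, W = planted_two_clone()
        res = bootstrap_wnmf(M, W, K=2, n_bootstrap=6, seed=1)
        assert len(res.permutations) == 6
        for perm in res.permutations:
            assert sorted(perm) == [0, 1]


def _result_with_C(C, n_vars=20):
    K = C.shape[1]
    return BootstrapResult(
        mean_C=C,
        var_C=np.zeros_like(C),
        mean_V=np.ones((K, n_vars)),
        var_V=np.zeros((K, n_vars)),
        n_bootstrap=1,
        subsample_fraction=0.9,
        replicate_seeds=[0],
        permutations=[np.arange(K)],
        n_sampled=np.ones(n_vars, int),
        low_confidence=np.zeros(n_vars, bool),
    )


class TestSelectBest:
    def test_score_closest_to_zero_wins(self):
        sharp = _result_with_C(np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.1]]))
        blurry = _result_with_C(np.array([[1.0, 0.9], [1.0, 1.1], [1.0, 1.0]]))
        sel = select_best({("a", 2): blurry, ("b", 2): sharp})
        assert sel.best == ("b", 2)
        assert sel.scores[("a", 2)] < sel.scores[("b", 2)] <= 0

    def test_single_candidate_returned(self):
        only = _result_with_C(np.eye(2))
        sel = select_best({("a", 2): only})
        assert sel.best == ("a", 2) and sel.chosen is only

    def test_tie_broken_by_smaller_k(self):
        c2 = _result_with_C(np.eye(2))
        c3 = _result_with_C(np.eye(3))
        sel = select_best({("a", 3): c3, ("a", 2): c2})
        assert sel.best == ("a", 2)

    def test_tie_broken_by_fewer_variants(self):
        loose = _result_with_C(np.eye(2), n_vars=50)
        strict = _result_with_C(np.eye(2), n_vars=20)
        sel = select_best({("loose", 2): loose, ("strict", 2): strict})
        assert sel.best == ("strict", 2)

    def test_all_degenerate_is_error(self):
        dead = _result_with_C(np.array([[1.0, 0.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="zero"):
            select_best({("a", 2): dead})

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            select_best({})
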