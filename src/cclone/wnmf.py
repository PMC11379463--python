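"""Weighted non-negative matrix factorization by alternating exact NNLS.

The observation matrix M (discretized VAF, cells x variants) is factorized
as M ~ C V with C (n_cells x K) and V (K x n_vars) non-negative, minimizing
the elementwise-weighted squared error

    E = sum_ij W_ij (M_ij - sum_k C_ik V_kj)^2 .

Entries with W = 0 (no coverage) contribute nothing, so the factorization
never has to explain missing data. The fit alternates two exact half-steps:
with C fixed, each variant column of V is an independent weighted
non-negative least-squares problem with design C; with V fixed, each cell
row of C is the symmetric problem with design V^T. Because every half-step
solves its subproblem exactly, the cost sequence is non-increasing.

Each K-dimensional weighted NNLS is reduced to its Gram (normal-equation)
form and solved exactly by enumerating all candidate active sets — cheap
for the small K (2-6) used for clone inference, and vectorizable across all
columns at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import scipy.optimize

_FEAS_TOL = 1e-12


@dataclass
class FactorModel:
    """Result of one wNMF fit: non-negative factors and the final cost."""

    C: np.ndarray            # (n_cells, K)
    V: np.ndarray            # (K, n_vars)
    K: int
    E: float                 # final weighted sum of squared errors
    n_iter: int
    seed: int | None
    cost_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    degenerate: bool = False  # a factor collapsed to zero and stayed there


def weighted_cost(M: np.ndarray, W: np.ndarray, C: np.ndarray, V: np.ndarray) -> float:
    """E = sum_ij W_ij (M_ij - (C V)_ij)^2."""
    M, W, C, V = (np.asarray(a, dtype=float) for a in (M, W, C, V))
    if M.shape != W.shape:
        raise ValueError(f"M shape {M.shape} != W shape {W.shape}")
    if C.shape[1] != V.shape[0] or C.shape[0] != M.shape[0] or V.shape[1] != M.shape[1]:
        raise ValueError(
            f"non-conformable factors C {C.shape}, V {V.shape} for M {M.shape}"
        )
    resid = M - C @ V
    return float(np.sum(W * resid * resid))


def solve_weighted_nnls(A: np.ndarray, b: np.ndarray, w: np.ndarray) -> np.ndarray:
    """argmin_{x >= 0} sum_t w_t (b_t - (A x)_t)^2.

    Rows of A and b are scaled by sqrt(w_t) and handed to an exact
    non-negative least-squares solver. All-zero weights return the zero
    vector.
    """
    A, b, w = np.asarray(A, float), np.asarray(b, float), np.asarray(w, float)
    if len(w) != len(b) or A.shape[0] != len(b):
        raise ValueError("A, b, w must agree on the number of rows")
    if (w < 0).any():
        raise ValueError("negative weights")
    keep = w > 0
    if not keep.any():
        return np.zeros(A.shape[1])
    s = np.sqrt(w[keep])
    x, _ = scipy.optimize.nnls(A[keep] * s[:, None], b[keep] * s)
    return x


def _candidate_supports(K: int) -> list[tuple[int, ...]]:
    sets = []
    for r in range(1, K + 1):
        sets.extend(combinations(range(K), r))
    return sets


def _batched_gram_nnls(G: np.ndarray, H: np.ndarray, X0: np.ndarray | None = None) -> np.ndarray:
    """Solve min_{x>=0} x'Gx - 2 h'x for a batch of small quadratic programs.

    G: (n, K, K) PSD Gram matrices, H: (n, K). The exact optimum's active
    set is one of the 2^K - 1 non-empty supports, so every support's
    stationary point is computed (batched) and the best feasible candidate
    kept; the zero vector and the optional warm start X0 are always
    candidates, which guarantees the result never exceeds their objective.
    """
    n, K = H.shape
    best_x = np.zeros((n, K))
    best_f = np.zeros(n)  # objective of the zero vector
    if X0 is not None:
        x0 = np.maximum(np.asarray(X0, float), 0.0)
        f0 = np.einsum("nk,nkl,nl->n", x0, G, x0) - 2 * np.einsum("nk,nk->n", x0, H)
        better = f0 < best_f
        best_x[better] = x0[better]
        best_f = np.minimum(best_f, f0)
    for support in _candidate_supports(K):
        s = list(support)
        Gs = G[:, s][:, :, s]
        Hs = H[:, s]
        try:
            xs = np.linalg.solve(Gs, Hs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            xs = np.einsum("nkl,nl->nk", np.linalg.pinv(Gs), Hs)
        if not np.isfinite(xs).all():
            xs = np.einsum("nkl,nl->nk", np.linalg.pinv(Gs), Hs)
        feasible = (xs >= -_FEAS_TOL).all(axis=1)
        if not feasible.any():
            continue
        xs = np.maximum(xs, 0.0)
        x_full = np.zeros((n, K))
        x_full[:, s] = xs
        f = np.einsum("nk,nkl,nl->n", x_full, G, x_full) - 2 * np.einsum(
            "nk,nk->n", x_full, H
        )
        better = feasible & (f < best_f)
        best_x[better] = x_full[better]
        best_f = np.where(better, f, best_f)
    return best_x


def _update_V(M, W, C, V_prev):
    # per-variant j: G_j = C' diag(W_:j) C,  h_j = C' (W_:j * M_:j)
    G = np.einsum("ij,ik,il->jkl", W, C, C, optimize=True)
    H = (W * M).T @ C
    return _batched_gram_nnls(G, H, X0=V_prev.T).T


def _update_C(M, W, C_prev, V):
    G = np.einsum("ij,kj,lj->ikl", W, V, V, optimize=True)
    H = (W * M) @ V.T
    return _batched_gram_nnls(G, H, X0=C_prev)


def fit_wnmf(
    M: np.ndarray,
    W: np.ndarray,
    K: int,
    n_iter: int = 100,
    seed: int | None = None,
    tol: float = 1e-6,
    patience: int = 5,
) -> FactorModel:
    """Fit the weighted NMF M ~ C V by alternating exact weighted NNLS.

    C is initialized i.i.d. uniform(0, 1) from ``seed``; the fit runs at most
    ``n_iter`` EM iterations with early stop once the relative cost decrease
    over ``patience`` iterations falls below ``tol``. Cells and variants
    whose weights are entirely zero are dropped before fitting and reinserted
    as zero rows/columns afterwards. A factor column of C that collapses to
    zero is re-randomized once; if that does not improve the cost the
    collapse is kept and the model flagged ``degenerate``. Deterministic
    given the seed.
    """
    M = np.asarray(M, dtype=float)
    W = np.asarray(W, dtype=float)
    if M.size == 0:
        raise ValueError("empty observation matrix")
    if M.shape != W.shape:
        raise ValueError(f"M shape {M.shape} != W shape {W.shape}")
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    if K > min(M.shape):
        raise ValueError(f"K={K} exceeds min(n_cells, n_vars)={min(M.shape)}")

    row_keep = np.flatnonzero(W.sum(axis=1) > 0)
    col_keep = np.flatnonzero(W.sum(axis=0) > 0)
    Mf, Wf = M[np.ix_(row_keep, col_keep)], W[np.ix_(row_keep, col_keep)]

    rng = np.random.default_rng(seed)
    C = rng.uniform(0.0, 1.0, size=(len(row_keep), K))
    V = np.zeros((K, len(col_keep)))

    trace = [weighted_cost(Mf, Wf, C, V)]
    retried = np.zeros(K, dtype=bool)
    degenerate = False
    rollback: tuple[np.ndarray, np.ndarray, float] | None = None
    it = 0
    for it in range(1, n_iter + 1):
        V = _update_V(Mf, Wf, C, V)
        C = _update_C(Mf, Wf, C, V)
        cost = weighted_cost(Mf, Wf, C, V)
        if rollback is not None:
            C_old, V_old, cost_old = rollback
            if cost > cost_old:
                # re-randomization did not help: restore and flag
                C, V, cost = C_old, V_old, cost_old
                degenerate = True
            rollback = None
        trace.append(cost)
        if len(trace) > patience:
            ref = trace[-1 - patience]
            if ref - trace[-1] <= tol * max(ref, 1e-30):
                break
        collapsed = np.flatnonzero((C.max(axis=0) == 0) & ~retried)
        if collapsed.size:
            rollback = (C.copy(), V.copy(), cost)
            for k in collapsed:
                C[:, k] = rng.uniform(0.0, 1.0, size=len(row_keep))
                retried[k] = True
    if (C.max(axis=0) == 0).any():
        degenerate = True

    C_full = np.zeros((M.shape[0], K))
    C_full[row_keep] = C
    V_full = np.zeros((K, M.shape[1]))
    V_full[:, col_keep] = V
    return FactorModel(
        C=C_full,
        V=V_full,
        K=K,
        E=weighted_cost(M, W, C_full, V_full),
        n_iter=it,
        seed=seed,
        cost_trace=np.asarray(trace),
        degenerate=degenerate,
    )
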