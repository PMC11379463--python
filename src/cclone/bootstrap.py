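"""Bootstrap aggregation of wNMF fits and orthogonality-based selection.

The alternating fit only finds a local optimum, and the factors vary with
the random initialization and with noise in the variant calls. Robustness
is assessed by refitting on random 90% subsamples of the variants (50
replicates by default), aligning each replicate's factors to the first
replicate by bipartite matching on cosine similarity, and aggregating the
aligned factors entrywise: the means give the final assignment, the
variances report its stability.

Candidate results (one per variant subset and factor count K) are ranked by
the orthogonality score of the mean cell factors,

    s = -(1 / C(K,2)) * sum_{i<j} cos(C_:i, C_:j) ,

which lies in [-1, 0] for non-negative C; cleanly separated clones have
nearly disjoint factor supports and a score close to 0, so the candidate
with the largest s wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.optimize

from .wnmf import FactorModel, fit_wnmf

LOW_CONFIDENCE_MIN_REPLICATES = 5


@dataclass
class BootstrapResult:
    """Aligned entrywise mean and variance of the factors over replicates."""

    mean_C: np.ndarray
    var_C: np.ndarray
    mean_V: np.ndarray
    var_V: np.ndarray
    n_bootstrap: int
    subsample_fraction: float
    replicate_seeds: list[int]
    permutations: list[np.ndarray]       # per replicate, invertible
    n_sampled: np.ndarray                # per variant, replicates that drew it
    low_confidence: np.ndarray           # variants drawn in < 5 replicates
    degenerate: bool = False             # any replicate flagged degenerate

    @property
    def K(self) -> int:
        return self.mean_C.shape[1]


@dataclass
class SelectionResult:
    """Score table over (subset, K) candidates and the winning result."""

    scores: dict
    best: tuple
    chosen: BootstrapResult

    def score_table(self) -> pd.DataFrame:
        rows = [
            {"subset": k[0], "K": k[1], "orthogonality_score": v}
            for k, v in self.scores.items()
        ]
        return pd.DataFrame(rows)


def _cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    sim = A.T @ B
    denom = np.outer(na, nb)
    # zero-norm columns have similarity 0 to everything
    return np.divide(sim, denom, out=np.zeros_like(sim), where=denom > 0)


def align_factors(reference_C: np.ndarray, candidate_C: np.ndarray) -> np.ndarray:
    """Column permutation aligning candidate factors to the reference.

    Returns ``perm`` such that ``candidate_C[:, perm]`` maximizes the summed
    cosine similarity to the reference columns (optimal bipartite matching).
    """
    if reference_C.shape != candidate_C.shape:
        raise ValueError(
            f"shape mismatch: {reference_C.shape} vs {candidate_C.shape}"
        )
    sim = _cosine_matrix(reference_C, candidate_C)
    rows, cols = scipy.optimize.linear_sum_assignment(-sim)
    perm = np.empty(len(cols), dtype=int)
    perm[rows] = cols
    return perm


def orthogonality_score(C: np.ndarray) -> float:
    """Negative mean pairwise cosine similarity between factor columns.

    In [-1, 0] for non-negative C: 0 for mutually orthogonal (disjoint
    support) factors, -1 for collinear ones. Zero-norm columns contribute 0
    to their pairs.
    """
    C = np.asarray(C, dtype=float)
    K = C.shape[1]
    if K < 2:
        raise ValueError(f"orthogonality score needs >= 2 factors, got {K}")
    sim = _cosine_matrix(C, C)
    iu = np.triu_indices(K, k=1)
    return float(-sim[iu].mean())


def _replicate_seeds(seed: int | None, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s % (2**31)) for s in ss.generate_state(n, dtype=np.uint64)]


def bootstrap_wnmf(
    M: np.ndarray,
    W: np.ndarray,
    K: int,
    n_bootstrap: int = 50,
    fraction: float = 0.9,
    seed: int | None = None,
    n_iter: int = 100,
) -> BootstrapResult:
    """Refit the wNMF on variant subsamples and aggregate aligned factors.

    Each replicate draws ``fraction`` of the variant columns uniformly
    without replacement, fits, and is aligned to the first replicate.
    mean/var of C are over all replicates; mean/var of each V column use
    only the replicates in which that variant was drawn (zero, and flagged,
    where it never was). Deterministic given the master seed.
    """
    M = np.asarray(M, dtype=float)
    W = np.asarray(W, dtype=float)
    n_cells, n_vars = M.shape
    if n_vars < 10:
        raise ValueError(f"need >= 10 variants to subsample, got {n_vars}")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n_draw = max(1, int(round(fraction * n_vars)))
    seeds = _replicate_seeds(seed, n_bootstrap)

    Cs = np.empty((n_bootstrap, n_cells, K))
    V_sum = np.zeros((K, n_vars))
    V_sumsq = np.zeros((K, n_vars))
    n_sampled = np.zeros(n_vars, dtype=int)
    permutations: list[np.ndarray] = []
    reference_C: np.ndarray | None = None
    degenerate = False

    for r, rep_seed in enumerate(seeds):
        rng = np.random.default_rng(rep_seed)
        cols = np.sort(rng.choice(n_vars, size=n_draw, replace=False))
        model = fit_wnmf(M[:, cols], W[:, cols], K, n_iter=n_iter, seed=rep_seed)
        degenerate = degenerate or model.degenerate
        # fix the scale gauge before aggregating: unit-norm C columns,
        # magnitudes absorbed into V (factorizations are scale-indeterminate)
        norms = np.linalg.norm(model.C, axis=0)
        safe = np.where(norms > 0, norms, 1.0)
        C_rep = model.C / safe
        V_rep = model.V * safe[:, None]
        if reference_C is None:
            reference_C = C_rep
            perm = np.arange(K)
        else:
            perm = align_factors(reference_C, C_rep)
        permutations.append(perm)
        Cs[r] = C_rep[:, perm]
        V_aligned = V_rep[perm]
        V_sum[:, cols] += V_aligned
        V_sumsq[:, cols] += V_aligned**2
        n_sampled[cols] += 1

    mean_C = Cs.mean(axis=0)
    var_C = Cs.var(axis=0)
    denom = np.maximum(n_sampled, 1)
    mean_V = V_sum / denom
    var_V = np.maximum(V_sumsq / denom - mean_V**2, 0.0)
    never = n_sampled == 0
    mean_V[:, never] = 0.0
    var_V[:, never] = 0.0
    return BootstrapResult(
        mean_C=mean_C,
        var_C=var_C,
        mean_V=mean_V,
        var_V=var_V,
        n_bootstrap=n_bootstrap,
        subsample_fraction=fraction,
        replicate_seeds=seeds,
        permutations=permutations,
        n_sampled=n_sampled,
        low_confidence=n_sampled < LOW_CONFIDENCE_MIN_REPLICATES,
        degenerate=degenerate,
    )


def select_best(results: Mapping[tuple, BootstrapResult]) -> SelectionResult:
    """Pick the (subset, K) candidate with the largest orthogonality score.

    Ties are broken by smaller K, then by fewer variants (stricter
    filtering). Candidates whose mean cell factors contain an all-zero
    column are degenerate; if every candidate is degenerate, an error is
    raised instead of silently returning a meaningless winner.
    """
    if not results:
        raise ValueError("no candidate results to select from")
    scores: dict = {}
    usable: dict = {}
    for key, res in results.items():
        s = orthogonality_score(res.mean_C)
        scores[key] = s
        if not (res.mean_C.max(axis=0) == 0).any():
            usable[key] = s
    if not usable:
        raise ValueError(
            "all candidate results have a collapsed (all-zero) factor; "
            "inspect the input data and filtering"
        )

    def rank(key):
        # maximize s; tie-break: smaller K, then fewer variants, then name
        return (-usable[key], key[1], results[key].mean_V.shape[1], str(key[0]))

    best = min(usable, key=rank)
    return SelectionResult(scores=scores, best=best, chosen=results[best])
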