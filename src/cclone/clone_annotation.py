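"""Turn fitted factors into clone assignments and clone-associated variants.

Cells are assigned to the factor with the largest row-normalized weight;
cells whose top two normalized weights differ by less than 0.3 are left
"undetermined" (row normalization is required because NMF factors carry an
arbitrary per-column scale). Factors are then labelled healthy/cancer from
prior cell-type knowledge: a factor containing no cells of a known healthy
type (e.g. T cells in AML) is cancer, the others healthy; when too few
known-healthy cells exist, the same logic runs inverted on known cancer
types (e.g. blasts). A model is successful only when both a healthy and a
cancer factor emerge. Finally, clone-associated variants are those whose
column-normalized factor weights differ by more than 0.3 between factors
and which are covered in at least 20% of each clone's cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

UNDETERMINED = "undetermined"
UNDETERMINED_THRESHOLD = 0.3
VARIANT_DIFF_THRESHOLD = 0.3
MIN_CLONE_COVERAGE = 0.2


@dataclass
class CloneAssignment:
    """Per-cell clone labels and per-factor healthy/cancer labels."""

    cell_clone: np.ndarray        # object array: factor index or "undetermined"
    normalized_C: np.ndarray      # row-normalized cell factors
    factor_label: list[str]       # "healthy" / "cancer" / "unlabelled" per factor
    success: bool | None = None   # None until label_factors has run

    @property
    def K(self) -> int:
        return self.normalized_C.shape[1]

    def clone_members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.cell_clone == k)

    @property
    def determined(self) -> np.ndarray:
        return self.cell_clone != UNDETERMINED

    def cell_label(self) -> np.ndarray:
        """Per-cell healthy/cancer/undetermined label via the factor labels."""
        out = np.empty(len(self.cell_clone), dtype=object)
        for i, c in enumerate(self.cell_clone):
            out[i] = c if c == UNDETERMINED else self.factor_label[int(c)]
        return out


def assign_cells(
    mean_C: np.ndarray, threshold: float = UNDETERMINED_THRESHOLD
) -> CloneAssignment:
    """Assign each cell to its dominant factor, or "undetermined".

    Rows of ``mean_C`` are normalized to sum 1 (all-zero rows stay zero and
    are undetermined); a cell is assigned to its argmax factor unless the
    top two normalized weights differ by less than ``threshold``.
    """
    C = np.asarray(mean_C, dtype=float)
    if (C < 0).any():
        raise ValueError("cell factors must be non-negative")
    row_sum = C.sum(axis=1, keepdims=True)
    normalized = np.divide(C, row_sum, out=np.zeros_like(C), where=row_sum > 0)
    order = np.sort(normalized, axis=1)
    top1 = order[:, -1]
    top2 = order[:, -2] if C.shape[1] >= 2 else np.zeros(len(C))
    labels = np.empty(len(C), dtype=object)
    argmax = normalized.argmax(axis=1)
    for i in range(len(C)):
        if row_sum[i, 0] == 0 or top1[i] - top2[i] < threshold:
            labels[i] = UNDETERMINED
        else:
            labels[i] = int(argmax[i])
    return CloneAssignment(
        cell_clone=labels,
        normalized_C=normalized,
        factor_label=["unlabelled"] * C.shape[1],
    )


def label_factors(
    assignment: CloneAssignment,
    cell_types: Sequence[str],
    healthy_types: Sequence[str],
    cancer_types: Sequence[str] = (),
    contamination_tolerance: float = 0.01,
    min_prior_cells: int = 20,
) -> CloneAssignment:
    """Label factors healthy/cancer from known cell types.

    ``cell_types`` is aligned with the cell axis of the assignment. A factor
    "contains" a type group when more than ``contamination_tolerance`` of
    its assigned cells carry such a type (0 reproduces the literal
    any-cell rule). Factors containing no known-healthy cells are cancer,
    the rest healthy; with fewer than ``min_prior_cells`` known-healthy
    cells dataset-wide the rule runs inverted on known cancer types.
    success is True only if both labels occur.
    """
    types = np.asarray(list(cell_types), dtype=object)
    if len(types) != len(assignment.cell_clone):
        raise ValueError("cell_types length does not match the assignment")
    is_healthy = np.isin(types, list(healthy_types))
    is_cancer = np.isin(types, list(cancer_types))
    n_healthy, n_cancer = int(is_healthy.sum()), int(is_cancer.sum())
    if n_healthy == 0 and n_cancer == 0:
        raise ValueError(
            "no known healthy or cancer cell types present; label factors manually"
        )
    use_healthy = n_healthy >= min_prior_cells or n_cancer < min_prior_cells

    labels = []
    for k in range(assignment.K):
        members = assignment.clone_members(k)
        if use_healthy:
            frac = is_healthy[members].mean() if len(members) else 0.0
            labels.append("healthy" if frac > contamination_tolerance else "cancer")
        else:
            frac = is_cancer[members].mean() if len(members) else 0.0
            labels.append("cancer" if frac > contamination_tolerance else "healthy")
    success = "healthy" in labels and "cancer" in labels
    return CloneAssignment(
        cell_clone=assignment.cell_clone,
        normalized_C=assignment.normalized_C,
        factor_label=labels,
        success=success,
    )


def select_clone_variants(
    mean_V: np.ndarray,
    M: np.ndarray,
    W: np.ndarray,
    assignment: CloneAssignment,
    diff_threshold: float = VARIANT_DIFF_THRESHOLD,
    min_coverage: float = MIN_CLONE_COVERAGE,
    variant_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Extract clone-associated variants from the variant factors.

    Each V column is normalized to sum 1 across factors; a variant is
    selected iff its max-minus-min normalized weight exceeds
    ``diff_threshold`` and, in every non-empty clone, at least
    ``min_coverage`` of the clone's cells cover it (W > 0). Returns a table
    sorted by weight difference, with per-clone coverage and per-clone mean
    discretized VAF over covered cells.
    """
    V = np.asarray(mean_V, dtype=float)
    K, n_vars = V.shape
    clones = [k for k in range(K) if len(assignment.clone_members(k))]
    if len(clones) < 2:
        raise ValueError("need at least two non-empty clones to contrast variants")

    col_sum = V.sum(axis=0, keepdims=True)
    Vn = np.divide(V, col_sum, out=np.zeros_like(V), where=col_sum > 0)
    diff = Vn.max(axis=0) - Vn.min(axis=0)
    direction = Vn.argmax(axis=0)

    covered = np.asarray(W) > 0
    table = pd.DataFrame(
        {
            "variant": list(variant_names) if variant_names is not None
            else [str(j) for j in range(n_vars)],
            "weight_diff": diff,
            "direction": direction,
        }
    )
    for k in range(K):
        table[f"weight_factor{k}"] = Vn[k]
    cov_ok = np.ones(n_vars, dtype=bool)
    for k in clones:
        members = assignment.clone_members(k)
        cov = covered[members].mean(axis=0)
        table[f"coverage_clone{k}"] = cov
        cov_ok &= cov >= min_coverage
        Mm = np.asarray(M)[members]
        n_cov = covered[members].sum(axis=0)
        mean_vaf = np.divide(
            (Mm * covered[members]).sum(axis=0),
            n_cov,
            out=np.zeros(n_vars),
            where=n_cov > 0,
        )
        table[f"mean_vaf_clone{k}"] = mean_vaf
    table["selected"] = (diff > diff_threshold) & cov_ok
    return table.sort_values("weight_diff", ascending=False).reset_index(drop=True)
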