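"""Discretized VAF observation matrix M and confidence weight matrix W.

Allele counts are turned into a three-valued genotype estimate per cell and
variant: M = 0 (homozygous reference), 0.5 (heterozygous), 1 (homozygous
alternative). The companion weight W encodes how much each entry should be
trusted: 1 when both alleles were observed, 0.5 when only one was (the other
may have dropped out), 0 when the position has no usable coverage — such
entries carry no information and are excluded from the factorization cost.

An allele counts as observed when at least one read/UMI supports it and its
within-cell allelic frequency is >= 0.05; the frequency floor discards
single stray reads at well-covered sites (e.g. 1 alt read out of 31 is
treated as sequencing error, not as evidence of the alt allele).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .variant_filtering import VariantSubset
    from .variant_io import AlleleCounts

MIN_ALLELE_FREQ = 0.05


def observed_alleles(ad: int, dp: int) -> tuple[bool, bool]:
    """Whether (ref, alt) each count as observed for one cell-variant pair.

    An allele is observed iff it has >= 1 supporting read and allelic
    frequency >= 0.05. With dp = 0 neither allele is observed.
    """
    if ad > dp:
        raise ValueError(f"AD ({ad}) exceeds DP ({dp})")
    if ad < 0:
        raise ValueError("negative AD")
    if dp == 0:
        return (False, False)
    rd = dp - ad
    alt = ad >= 1 and ad / dp >= MIN_ALLELE_FREQ
    ref = rd >= 1 and rd / dp >= MIN_ALLELE_FREQ
    return (ref, alt)


def observed_allele_matrices(counts: "AlleleCounts") -> tuple[np.ndarray, np.ndarray]:
    """Vectorized allele-observed rule over the full counts.

    Returns dense boolean (ref_observed, alt_observed), cells x variants.
    """
    ad = np.asarray(counts.AD.todense(), dtype=np.float64)
    dp = np.asarray(counts.DP.todense(), dtype=np.float64)
    rd = dp - ad
    with np.errstate(divide="ignore", invalid="ignore"):
        alt = (ad >= 1) & (np.where(dp > 0, ad / np.maximum(dp, 1), 0.0) >= MIN_ALLELE_FREQ)
        ref = (rd >= 1) & (np.where(dp > 0, rd / np.maximum(dp, 1), 0.0) >= MIN_ALLELE_FREQ)
    return ref, alt


@dataclass
class ObservationMatrices:
    """The (M, W) pair for one variant subset, cells x subset-variants."""

    M: np.ndarray
    W: np.ndarray
    subset: "VariantSubset | None" = None
    variant_indices: np.ndarray | None = None  # columns of the parent counts

    def __post_init__(self) -> None:
        if self.M.shape != self.W.shape:
            raise ValueError(f"M shape {self.M.shape} != W shape {self.W.shape}")


def _discretize(ref_obs: np.ndarray, alt_obs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    both = ref_obs & alt_obs
    only_alt = alt_obs & ~ref_obs
    only_ref = ref_obs & ~alt_obs
    M = np.where(only_alt, 1.0, np.where(both, 0.5, 0.0))
    W = np.where(both, 1.0, np.where(only_alt | only_ref, 0.5, 0.0))
    return M, W


def build_M(counts: "AlleleCounts", subset: "VariantSubset | None" = None) -> np.ndarray:
    """Discretized VAF matrix: 1 only-ALT, 0.5 both, 0 only-REF or uncovered."""
    ref, alt = observed_allele_matrices(counts)
    M, _ = _discretize(ref, alt)
    if subset is not None:
        M = M[:, subset.indices]
    return M


def build_W(counts: "AlleleCounts", subset: "VariantSubset | None" = None) -> np.ndarray:
    """Confidence weights: 1 both alleles seen, 0.5 exactly one, 0 neither."""
    ref, alt = observed_allele_matrices(counts)
    _, W = _discretize(ref, alt)
    if subset is not None:
        W = W[:, subset.indices]
    return W


def build_observation_matrices(
    counts: "AlleleCounts", subset: "VariantSubset | None" = None
) -> ObservationMatrices:
    """Build M and W together (one pass over the counts)."""
    ref, alt = observed_allele_matrices(counts)
    M, W = _discretize(ref, alt)
    idx = None
    if subset is not None:
        idx = subset.indices
        M, W = M[:, idx], W[:, idx]
    return ObservationMatrices(M=M, W=W, subset=subset, variant_indices=idx)
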