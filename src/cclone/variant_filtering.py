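"""Fixed variant filters and the six-subset filtering grid.

Most variants called from scRNA-seq reads are not somatic: they are germline
SNPs, RNA-editing sites, alignment artefacts in repeat regions, or sporadic
errors. Three fixed filters remove known artefact classes (RepeatMasker
repeats, REDIdb RNA edits, variants covered with DP >= 2 in fewer than 10%
of cells). On top of that, six candidate subsets are generated from the grid

    {germline included, germline excluded} x {MAF > 2%, > 5%, > 10%}

where MAF is the fraction of covered cells in which the variant's minor
allele is observed. Germline variants are kept in half the grid on purpose:
if a germline SNP sits in a region lost (deletion/LOH) or fixated in the
cancer clone, its occurrence pattern is clone-informative. The downstream
model selection picks the subset that yields the cleanest clonal separation.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .observation_matrices import observed_allele_matrices
from .variant_io import AlleleCounts, VariantRecord

logger = logging.getLogger(__name__)

MAF_THRESHOLDS = (0.02, 0.05, 0.10)
MIN_COVERED_DP = 2         # a cell "covers" a variant if DP >= 2
MIN_COVERED_CELL_FRAC = 0.10


@dataclass
class VariantSubset:
    """One candidate variant subset out of the filtering grid."""

    mask: np.ndarray                 # boolean over all variants of the parent counts
    include_germline: bool
    maf_threshold: float
    name: str

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    @property
    def n_variants(self) -> int:
        return int(self.mask.sum())


def flag_repeat_regions(
    variants: Sequence[VariantRecord], bed_path: str | os.PathLike
) -> list[VariantRecord]:
    """Set ``in_repeat_region`` from a BED file (0-based half-open intervals).

    A variant is flagged when its 1-based position overlaps any interval.
    """
    trees: dict[str, IntervalTree] = {}
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            trees.setdefault(chrom, IntervalTree()).addi(int(start), int(end))
    out = []
    for v in variants:
        tree = trees.get(v.chrom)
        hit = bool(tree is not None and tree.overlaps(v.pos - 1))  # BED is 0-based
        out.append(
            VariantRecord(
                v.chrom, v.pos, v.ref_allele, v.alt_allele,
                is_germline_common=v.is_germline_common, is_rna_edit=v.is_rna_edit,
                in_repeat_region=hit, consequence=v.consequence,
            )
        )
    return out


def coverage_fraction(counts: AlleleCounts) -> np.ndarray:
    """Per-variant fraction of cells with DP >= 2."""
    covered = counts.DP >= MIN_COVERED_DP
    return np.asarray(covered.mean(axis=0)).ravel()


def _n_covered_cells(counts: AlleleCounts) -> np.ndarray:
    return np.asarray((counts.DP >= MIN_COVERED_DP).sum(axis=0)).ravel()


def apply_fixed_filters(counts: AlleleCounts) -> np.ndarray:
    """Boolean mask of variants passing the fixed filters.

    Excluded: repeat-region variants, RNA edits, and low-coverage variants
    (DP >= 2 in fewer than 10% of cells; exactly 10% passes).
    """
    repeat = np.array([v.in_repeat_region for v in counts.variants], dtype=bool)
    edit = np.array([v.is_rna_edit for v in counts.variants], dtype=bool)
    # integer counts with an epsilon guard so the exact-10% boundary passes
    n_cov = _n_covered_cells(counts)
    low_cov = n_cov < MIN_COVERED_CELL_FRAC * counts.n_cells - 1e-9
    mask = ~repeat & ~edit & ~low_cov
    if mask.sum() < 10:
        logger.warning("only %d variants survive the fixed filters", int(mask.sum()))
    return mask


def compute_variant_mafs(counts: AlleleCounts) -> np.ndarray:
    """Minor-allele frequency per variant.

    Among cells covering the variant (DP >= 2), the minor allele is the one
    observed (per the allele-observed rule) in fewer cells; the MAF is the
    fraction of covered cells observing it. Variants with no covered cell
    get 0.
    """
    ref_obs, alt_obs = observed_allele_matrices(counts)
    covered = np.asarray((counts.DP >= MIN_COVERED_DP).todense())
    n_cov = covered.sum(axis=0)
    n_ref = (ref_obs & covered).sum(axis=0)
    n_alt = (alt_obs & covered).sum(axis=0)
    minor = np.minimum(n_ref, n_alt)
    with np.errstate(divide="ignore", invalid="ignore"):
        maf = np.where(n_cov > 0, minor / np.maximum(n_cov, 1), 0.0)
    return maf


def compute_variant_maf(counts: AlleleCounts, variant_index: int) -> float:
    """MAF of a single variant (see :func:`compute_variant_mafs`)."""
    return float(compute_variant_mafs(counts)[variant_index])


def make_subsets(
    counts: AlleleCounts,
    maf_thresholds: Sequence[float] = MAF_THRESHOLDS,
    fixed_mask: np.ndarray | None = None,
) -> list[VariantSubset]:
    """Generate the candidate subsets over the germline x MAF grid.

    With the default three MAF thresholds this returns exactly six subsets.
    The MAF comparison is strict (> threshold). "Germline excluded" removes
    variants flagged dbSNP-common; "germline included" keeps them so that
    LOH / allelic-imbalance signals remain discoverable.
    """
    if fixed_mask is None:
        fixed_mask = apply_fixed_filters(counts)
    maf = compute_variant_mafs(counts)
    germline = np.array([v.is_germline_common for v in counts.variants], dtype=bool)
    subsets = []
    for maf_t in maf_thresholds:
        for include_germline in (True, False):
            mask = fixed_mask & (maf > maf_t)
            if not include_germline:
                mask = mask & ~germline
            tag = "germline-in" if include_germline else "germline-out"
            subsets.append(
                VariantSubset(
                    mask=mask,
                    include_germline=include_germline,
                    maf_threshold=float(maf_t),
                    name=f"{tag}_maf>{maf_t:g}",
                )
            )
    return subsets


def subset_table(counts: AlleleCounts, subsets: Sequence[VariantSubset]) -> pd.DataFrame:
    """Per-variant membership flags across subsets, for TSV export."""
    table = pd.DataFrame({"variant": [str(v) for v in counts.variants]})
    for s in subsets:
        table[s.name] = s.mask
    return table
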