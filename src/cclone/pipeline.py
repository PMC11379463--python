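"""End-to-end workflow: filter -> subset grid -> wNMF bootstrap -> select -> annotate.

The run is fully deterministic: the master seed deterministically derives an
independent seed for each (subset, K) candidate, so adding K values or
subsets to the grid never perturbs the seeds (and thus the results) of the
existing candidates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import variant_filtering, variant_io
from .bootstrap import BootstrapResult, SelectionResult, bootstrap_wnmf, select_best
from .clone_annotation import (
    UNDETERMINED,
    CloneAssignment,
    assign_cells,
    label_factors,
    select_clone_variants,
)
from .observation_matrices import build_observation_matrices
from .synthetic_data import SimulationConfig, generate_clonal_dataset
from .variant_filtering import VariantSubset, make_subsets
from .variant_io import AlleleCounts

logger = logging.getLogger(__name__)

MIN_HEALTHY_FRACTION = 0.03  # below this, the sample is flagged as underpowered


@dataclass
class RunConfig:
    """All knobs of one pipeline run (paths, grid, thresholds, master seed)."""

    base_vcf: str | None = None
    ad_mtx: str | None = None
    dp_mtx: str | None = None
    barcodes: str | None = None
    annotations: str | None = None
    cell_types: str | None = None
    repeat_bed: str | None = None
    outdir: str = "cclone_out"

    k_grid: tuple[int, ...] = (2, 3, 4)
    n_iter: int = 100
    n_bootstrap: int = 50
    bootstrap_fraction: float = 0.9
    maf_thresholds: tuple[float, ...] = (0.02, 0.05, 0.10)
    healthy_types: tuple[str, ...] = ("T_cell",)
    cancer_types: tuple[str, ...] = ("blast",)
    undetermined_threshold: float = 0.3
    variant_diff_threshold: float = 0.3
    coverage_threshold: float = 0.2
    contamination_tolerance: float = 0.01
    min_prior_cells: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("undetermined_threshold", "variant_diff_threshold",
                     "coverage_threshold", "contamination_tolerance",
                     "bootstrap_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(k < 2 for k in self.k_grid):
            raise ValueError("all K grid values must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("k_grid", "maf_thresholds", "healthy_types", "cancer_types"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class PipelineResult:
    selection: SelectionResult
    assignment: CloneAssignment
    clone_variants: pd.DataFrame | None
    subsets: list[VariantSubset]
    counts: AlleleCounts
    warnings: list[str] = field(default_factory=list)


def candidate_seed(master_seed: int, subset_index: int, K: int) -> int:
    """Independent per-(subset, K) seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(subset_index), int(K)])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


def run_cclone_counts(counts: AlleleCounts, config: RunConfig) -> PipelineResult:
    """Run the workflow on in-memory counts (the library surface of `run`)."""
    warnings: list[str] = []
    n_cells = counts.n_cells
    if n_cells < 2:
        raise ValueError("need at least 2 cells")

    cell_type_list: list[str] | None = None
    if counts.cell_types is not None:
        cell_type_list = [counts.cell_types.get(bc, "unknown") for bc in counts.cells]
        n_known_healthy = sum(t in config.healthy_types for t in cell_type_list)
        if n_known_healthy < MIN_HEALTHY_FRACTION * n_cells:
            msg = (
                f"only {n_known_healthy}/{n_cells} cells carry a known healthy type "
                f"(< {MIN_HEALTHY_FRACTION:.0%}); sample is below the analysis "
                "inclusion threshold and results may be unreliable"
            )
            warnings.append(msg)
            logger.warning(msg)

    fixed_mask = variant_filtering.apply_fixed_filters(counts)
    logger.info("fixed filters: %d/%d variants retained", int(fixed_mask.sum()), counts.n_vars)
    if fixed_mask.sum() < 10:
        raise ValueError(
            f"only {int(fixed_mask.sum())} variants survive the fixed filters (need >= 10)"
        )
    subsets = make_subsets(counts, config.maf_thresholds, fixed_mask=fixed_mask)

    results: dict[tuple, BootstrapResult] = {}
    obs_cache: dict[str, object] = {}
    for si, subset in enumerate(subsets):
        if subset.n_variants < 10 or subset.n_variants < max(config.k_grid):
            logger.info("subset %s skipped (%d variants)", subset.name, subset.n_variants)
            continue
        obs = build_observation_matrices(counts, subset)
        obs_cache[subset.name] = obs
        for K in config.k_grid:
            seed = candidate_seed(config.seed, si, K)
            logger.info(
                "bootstrapping subset=%s (%d variants) K=%d seed=%d",
                subset.name, subset.n_variants, K, seed,
            )
            results[(subset.name, K)] = bootstrap_wnmf(
                obs.M, obs.W, K,
                n_bootstrap=config.n_bootstrap,
                fraction=config.bootstrap_fraction,
                seed=seed,
                n_iter=config.n_iter,
            )
    if not results:
        raise ValueError("no (subset, K) candidate could be fitted; too few variants")

    selection = select_best(results)
    best_subset_name, best_K = selection.best
    logger.info(
        "selected subset=%s K=%d (s=%.4f)",
        best_subset_name, best_K, selection.scores[selection.best],
    )

    assignment = assign_cells(selection.chosen.mean_C, config.undetermined_threshold)
    if cell_type_list is not None:
        try:
            assignment = label_factors(
                assignment, cell_type_list,
                config.healthy_types, config.cancer_types,
                contamination_tolerance=config.contamination_tolerance,
                min_prior_cells=config.min_prior_cells,
            )
        except ValueError as exc:
            warnings.append(str(exc))
            logger.warning("factor labelling skipped: %s", exc)

    best_obs = obs_cache[best_subset_name]
    subset_obj = next(s for s in subsets if s.name == best_subset_name)
    clone_variants: pd.DataFrame | None = None
    try:
        clone_variants = select_clone_variants(
            selection.chosen.mean_V, best_obs.M, best_obs.W, assignment,
            diff_threshold=config.variant_diff_threshold,
            min_coverage=config.coverage_threshold,
            variant_names=[str(counts.variants[j]) for j in subset_obj.indices],
        )
    except ValueError as exc:
        warnings.append(str(exc))
        logger.warning("clone-variant extraction skipped: %s", exc)

    return PipelineResult(
        selection=selection,
        assignment=assignment,
        clone_variants=clone_variants,
        subsets=subsets,
        counts=counts,
        warnings=warnings,
    )


def _write_outputs(result: PipelineResult, config: RunConfig) -> None:
    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)

    result.selection.score_table().to_csv(out("scores.tsv"), sep="\t", index=False)
    variant_filtering.subset_table(result.counts, result.subsets).to_csv(
        out("subsets.tsv"), sep="\t", index=False
    )
    a = result.assignment
    cell_table = pd.DataFrame(
        {
            "barcode": result.counts.cells,
            "clone": [str(c) for c in a.cell_clone],
            "label": a.cell_label(),
        }
    )
    for k in range(a.K):
        cell_table[f"weight_factor{k}"] = a.normalized_C[:, k]
    cell_table.to_csv(out("cells.tsv"), sep="\t", index=False)
    if result.clone_variants is not None:
        result.clone_variants.to_csv(out("clone_variants.tsv"), sep="\t", index=False)

    best_subset, best_K = result.selection.best
    chosen = result.selection.chosen
    np.savetxt(out("mean_C.tsv"), chosen.mean_C, delimiter="\t")
    np.savetxt(out("mean_V.tsv"), chosen.mean_V, delimiter="\t")
    report = {
        "best_subset": best_subset,
        "best_K": int(best_K),
        "orthogonality_score": float(result.selection.scores[result.selection.best]),
        "factor_labels": a.factor_label,
        "success": a.success,
        "n_undetermined": int((a.cell_clone == UNDETERMINED).sum()),
        "n_cells": result.counts.n_cells,
        "n_variants": result.counts.n_vars,
        "seed": config.seed,
        "n_bootstrap": config.n_bootstrap,
        "warnings": result.warnings,
    }
    with open(out("report.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    config.to_yaml(out("config.yaml"))


def run_cclone(config: RunConfig) -> PipelineResult:
    """Full workflow from files on disk; writes all exports to ``outdir``."""
    for name in ("base_vcf", "ad_mtx", "dp_mtx", "barcodes"):
        if getattr(config, name) is None:
            raise ValueError(f"config is missing required input path {name!r}")
    counts = variant_io.read_cellsnp(
        config.base_vcf, config.ad_mtx, config.dp_mtx, config.barcodes
    )
    if config.annotations:
        counts.variants = variant_io.read_annotations(config.annotations, counts.variants)
    if config.repeat_bed:
        counts.variants = variant_filtering.flag_repeat_regions(
            counts.variants, config.repeat_bed
        )
    if config.cell_types:
        counts.cell_types = variant_io.read_cell_types(config.cell_types, counts.cells)
    result = run_cclone_counts(counts, config)
    _write_outputs(result, config)
    return result
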