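"""Synthetic cellsnp-lite-style datasets with planted clonal structure.

The generator emulates the variant-call signal a tumour scRNA-seq sample
produces, at the level of per-cell AD/DP counts:

* clone-private somatic SNVs, heterozygous (true VAF 0.5) in the cancer
  clone and absent (VAF 0) in healthy cells;
* ubiquitous germline heterozygous SNPs (VAF 0.5 in every cell), flagged
  dbSNP-common in the emitted annotation table;
* LOH/fixation events: germline hets whose alt allele is lost (VAF 0) or
  fixated (VAF 1) in the cancer clone;
* sporadic noise variants with no clonal structure (rare per-cell ALT
  observations imitating sequencing/processing errors);
* coverage sparsity (each cell x variant site expressed with probability
  p_expr; unexpressed sites have DP 0), allelic dropout at heterozygous
  sites, and per-read error flips.

Ground truth (clone labels, variant classes) and a cell-type table (a
fraction of healthy cells named as a known-healthy type, of cancer cells
as a known-cancer type) are returned alongside the counts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .variant_io import AlleleCounts, VariantRecord, write_cellsnp

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for one simulated sample.

    Defaults model a 10X-like AML sample: 500 cells split 60/40 into a
    healthy and a cancer clone, 30 clone-private somatic SNVs, 50 germline
    hets, 10 LOH events, 200 structureless noise variants, 30% site
    expression probability, mean depth 4 at expressed sites, 20% allelic
    dropout and 1% per-read error.
    """

    n_cells: int = 500
    clone_fractions: tuple[float, float] = (0.6, 0.4)  # (healthy, cancer)
    n_somatic_variants: int = 30
    n_germline_variants: int = 50
    n_loh_variants: int = 10
    n_noise_variants: int = 200
    p_expr: float = 0.3
    mean_depth: float = 4.0
    dropout: float = 0.2
    error_rate: float = 0.01
    noise_rate: float = 0.05          # per-covered-cell ALT event at noise variants
    healthy_type_fraction: float = 0.3
    cancer_type_fraction: float = 0.3
    healthy_type_name: str = "T_cell"
    cancer_type_name: str = "blast"
    other_type_name: str = "HSC"
    seed: int | None = 0

    def __post_init__(self) -> None:
        if abs(sum(self.clone_fractions) - 1.0) > 1e-9:
            raise ValueError("clone fractions must sum to 1")
        for name in ("p_expr", "dropout", "error_rate", "noise_rate",
                     "healthy_type_fraction", "cancer_type_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.clone_fractions) < 0:
            raise ValueError("negative clone fraction")
        if self.n_cells < 2 or self.mean_depth < 1:
            raise ValueError("need >= 2 cells and mean depth >= 1")
        n_vars = (self.n_somatic_variants + self.n_germline_variants
                  + self.n_loh_variants + self.n_noise_variants)
        if n_vars * self.n_cells * self.p_expr < 1:
            raise ValueError("configuration implies zero covered entries")


@dataclass
class SimulatedDataset:
    counts: AlleleCounts
    clone_labels: np.ndarray          # "healthy" / "cancer" per cell
    variant_classes: np.ndarray       # "somatic"/"germline"/"loh_loss"/"loh_fix"/"noise"
    cell_types: dict[str, str]
    true_vaf: np.ndarray              # planted genotype VAF, cells x variants
    config: SimulationConfig


def _random_variants(rng: np.random.Generator, n: int) -> list[VariantRecord]:
    variants = []
    positions = rng.choice(np.arange(1, 10 * n + 1), size=n, replace=False)
    for pos in np.sort(positions):
        ref, alt = rng.choice(4, size=2, replace=False)
        variants.append(VariantRecord("chr1", int(pos), str(_BASES[ref]), str(_BASES[alt])))
    return variants


def generate_clonal_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset under the configured study conditions.

    Per cell x variant: the site is expressed with probability ``p_expr``;
    if expressed, depth is 1 + Poisson(mean_depth - 1); at heterozygous
    sites each allele independently drops out with probability ``dropout``
    (both dropping leaves the site unobserved); reads are then drawn
    binomially from the effective VAF and flipped independently at the
    per-read error rate. Noise variants additionally receive a spurious ALT
    read in a random ``noise_rate`` fraction of their covered cells.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    n_som, n_germ = config.n_somatic_variants, config.n_germline_variants
    n_loh, n_noise = config.n_loh_variants, config.n_noise_variants
    m = n_som + n_germ + n_loh + n_noise

    n_healthy = int(round(config.clone_fractions[0] * n))
    clone = np.array(["healthy"] * n_healthy + ["cancer"] * (n - n_healthy), dtype=object)
    is_cancer = clone == "cancer"

    classes = np.array(
        ["somatic"] * n_som + ["germline"] * n_germ
        + ["loh_loss"] * (n_loh // 2) + ["loh_fix"] * (n_loh - n_loh // 2)
        + ["noise"] * n_noise,
        dtype=object,
    )

    # planted genotype VAF per cell x variant
    vaf = np.zeros((n, m))
    vaf[:, classes == "germline"] = 0.5
    vaf[np.ix_(is_cancer, classes == "somatic")] = 0.5
    vaf[np.ix_(~is_cancer, (classes == "loh_loss") | (classes == "loh_fix"))] = 0.5
    vaf[np.ix_(is_cancer, classes == "loh_loss")] = 0.0
    vaf[np.ix_(is_cancer, classes == "loh_fix")] = 1.0

    expressed = rng.random((n, m)) < config.p_expr
    depth = np.where(expressed, 1 + rng.poisson(config.mean_depth - 1, size=(n, m)), 0)

    het = vaf == 0.5
    drop_alt = het & (rng.random((n, m)) < config.dropout)
    drop_ref = het & (rng.random((n, m)) < config.dropout)
    v_eff = vaf.copy()
    v_eff[drop_alt & ~drop_ref] = 0.0
    v_eff[drop_ref & ~drop_alt] = 1.0
    depth = np.where(drop_alt & drop_ref, 0, depth)  # full dropout: site unobserved

    ad = rng.binomial(depth, v_eff)
    # per-read error flips, independently per read
    e = config.error_rate
    ad = ad - rng.binomial(ad, e) + rng.binomial(depth - ad, e)

    # sporadic ALT observations at noise variants
    noise_cols = classes == "noise"
    spurious = noise_cols[None, :] & (depth > 0) & (rng.random((n, m)) < config.noise_rate)
    ad = np.where(spurious, np.maximum(ad, 1), ad)
    ad = np.minimum(ad, depth)

    barcodes = [f"CELL{i:05d}" for i in range(n)]
    variants = _random_variants(rng, m)
    counts = AlleleCounts(
        AD=sp.csr_matrix(ad), DP=sp.csr_matrix(depth), cells=barcodes, variants=variants
    )

    cell_types: dict[str, str] = {}
    for i, bc in enumerate(barcodes):
        if is_cancer[i]:
            known = rng.random() < config.cancer_type_fraction
            cell_types[bc] = config.cancer_type_name if known else config.other_type_name
        else:
            known = rng.random() < config.healthy_type_fraction
            cell_types[bc] = config.healthy_type_name if known else config.other_type_name
    counts.cell_types = cell_types

    return SimulatedDataset(
        counts=counts,
        clone_labels=clone,
        variant_classes=classes,
        cell_types=cell_types,
        true_vaf=vaf,
        config=config,
    )


def annotation_table(dataset: SimulatedDataset) -> pd.DataFrame:
    """Annotation TSV content: planted germline/LOH variants are dbSNP-common."""
    germline_like = np.isin(dataset.variant_classes, ["germline", "loh_loss", "loh_fix"])
    return pd.DataFrame(
        {
            "chrom": [v.chrom for v in dataset.counts.variants],
            "pos": [v.pos for v in dataset.counts.variants],
            "ref": [v.ref_allele for v in dataset.counts.variants],
            "alt": [v.alt_allele for v in dataset.counts.variants],
            "is_germline_common": germline_like,
            "is_rna_edit": False,
            "in_repeat_region": False,
        }
    )


def apply_truth_annotations(dataset: SimulatedDataset) -> None:
    """Set the germline-common flag on the in-memory variants (no file I/O)."""
    germline_like = np.isin(dataset.variant_classes, ["germline", "loh_loss", "loh_fix"])
    dataset.counts.variants = [
        replace(v, is_germline_common=bool(g))
        for v, g in zip(dataset.counts.variants, germline_like)
    ]


def write_dataset(dataset: SimulatedDataset, outdir: str | os.PathLike) -> dict[str, str]:
    """Write the cellsnp trio plus annotation, truth and cell-type TSVs."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "cellSNP.base.vcf"),
        "ad": os.path.join(outdir, "cellSNP.tag.AD.mtx"),
        "dp": os.path.join(outdir, "cellSNP.tag.DP.mtx"),
        "barcodes": os.path.join(outdir, "cellSNP.samples.tsv"),
        "annotations": os.path.join(outdir, "annotations.tsv"),
        "cell_types": os.path.join(outdir, "cell_types.tsv"),
        "truth_cells": os.path.join(outdir, "truth.cells.tsv"),
        "truth_variants": os.path.join(outdir, "truth.variants.tsv"),
    }
    write_cellsnp(dataset.counts, paths["vcf"], paths["ad"], paths["dp"], paths["barcodes"])
    annotation_table(dataset).to_csv(paths["annotations"], sep="\t", index=False)
    pd.DataFrame(
        {"barcode": dataset.counts.cells,
         "type": [dataset.cell_types[bc] for bc in dataset.counts.cells]}
    ).to_csv(paths["cell_types"], sep="\t", index=False, header=False)
    pd.DataFrame(
        {"barcode": dataset.counts.cells, "clone": dataset.clone_labels}
    ).to_csv(paths["truth_cells"], sep="\t", index=False)
    pd.DataFrame(
        {"variant": [str(v) for v in dataset.counts.variants],
         "class": dataset.variant_classes}
    ).to_csv(paths["truth_variants"], sep="\t", index=False)
    return paths


def subsample_counts(counts: AlleleCounts, fraction: float, seed: int | None = None) -> AlleleCounts:
    """Binomially thin ALT and REF counts independently at ``fraction``.

    DP is recomputed as the sum of the thinned counts, so AD <= DP always
    holds and total counts have expectation fraction x original. Emulates
    reduced sequencing depth.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1:
        return AlleleCounts(
            AD=counts.AD.copy(), DP=counts.DP.copy(),
            cells=list(counts.cells), variants=list(counts.variants),
            cell_types=dict(counts.cell_types) if counts.cell_types else None,
        )
    rng = np.random.default_rng(seed)
    ad = counts.AD.tocoo()
    dp = counts.DP.tocoo()
    rd = (counts.DP - counts.AD).tocoo()
    new_ad_data = rng.binomial(ad.data, fraction)
    new_rd_data = rng.binomial(rd.data, fraction)
    shape = counts.AD.shape
    new_ad = sp.coo_matrix((new_ad_data, (ad.row, ad.col)), shape=shape).tocsr()
    new_rd = sp.coo_matrix((new_rd_data, (rd.row, rd.col)), shape=shape).tocsr()
    new_dp = (new_ad + new_rd).tocsr()
    new_ad.eliminate_zeros()
    new_dp.eliminate_zeros()
    return AlleleCounts(
        AD=new_ad, DP=new_dp,
        cells=list(counts.cells), variants=list(counts.variants),
        cell_types=dict(counts.cell_types) if counts.cell_types else None,
    )
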