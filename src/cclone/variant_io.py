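"""Readers and writers for cellsnp-lite-style per-cell variant call data.

The on-disk layout mirrors what cellsnp-lite emits: a base VCF listing the
called variants, two sparse Matrix Market files with the per-cell
alternative-allele (AD) and total-depth (DP) counts, and a barcode list.
cellsnp-lite stores the matrices as variants x cells; internally everything
is cells x variants, matching the (n_cells, n_vars) convention used by the
factorization downstream.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


@dataclass
class VariantRecord:
    """One called single-nucleotide variant with its annotation flags.

    ``is_germline_common`` marks dbSNP-common germline variants (MAF >= 0.01
    in at least one major population), ``is_rna_edit`` marks known RNA-editing
    sites (REDIdb), ``in_repeat_region`` marks RepeatMasker overlap.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    is_germline_common: bool = False
    is_rna_edit: bool = False
    in_repeat_region: bool = False
    consequence: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref_allele), ("alt", self.alt_allele)):
            if not allele or not set(allele) <= _VALID_BASES:
                raise ValueError(f"invalid {name} allele {allele!r} at {self.chrom}:{self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}{self.ref_allele}>{self.alt_allele}"


@dataclass
class AlleleCounts:
    """Per-cell allele counts: AD (alt) and DP (total) as cells x variants.

    Invariants enforced at construction: matching dimensions, non-negative
    integer counts, and AD <= DP everywhere (the reference count is DP - AD).
    """

    AD: sp.csr_matrix
    DP: sp.csr_matrix
    cells: list[str]
    variants: list[VariantRecord]
    cell_types: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.AD = sp.csr_matrix(self.AD, dtype=np.int64)
        self.DP = sp.csr_matrix(self.DP, dtype=np.int64)
        n_cells, n_vars = len(self.cells), len(self.variants)
        if self.AD.shape != (n_cells, n_vars) or self.DP.shape != (n_cells, n_vars):
            raise ValueError(
                f"count matrix shapes {self.AD.shape}/{self.DP.shape} do not match "
                f"{n_cells} cells x {n_vars} variants"
            )
        if self.AD.nnz and self.AD.data.min() < 0:
            raise ValueError("negative AD count")
        if self.DP.nnz and self.DP.data.min() < 0:
            raise ValueError("negative DP count")
        excess = (self.AD - self.DP).tocoo()
        bad = excess.data > 0
        if bad.any():
            i, j = excess.row[bad][0], excess.col[bad][0]
            raise ValueError(
                f"AD exceeds DP at cell {self.cells[i]!r} (row {i}), "
                f"variant {self.variants[j]} (col {j})"
            )
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom, pos, ref, alt) keys in variant list")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_vars(self) -> int:
        return len(self.variants)

    def variant_flags(self) -> pd.DataFrame:
        """Annotation flags as a DataFrame indexed like the variant axis."""
        return pd.DataFrame(
            {
                "is_germline_common": [v.is_germline_common for v in self.variants],
                "is_rna_edit": [v.is_rna_edit for v in self.variants],
                "in_repeat_region": [v.in_repeat_region for v in self.variants],
            },
            index=[str(v) for v in self.variants],
        )


def _open_text(path: str | os.PathLike):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _read_lines(path: str | os.PathLike) -> list[str]:
    with _open_text(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_cellsnp(
    base_vcf_path: str | os.PathLike,
    ad_mtx_path: str | os.PathLike,
    dp_mtx_path: str | os.PathLike,
    barcodes_path: str | os.PathLike,
) -> AlleleCounts:
    """Assemble a cellsnp-lite output trio into an :class:`AlleleCounts`.

    The Matrix Market files are variants x cells on disk and transposed on
    read. Counts are preserved exactly; dimension mismatches between the VCF,
    the matrices and the barcode list raise naming the offending file.
    """
    variants = []
    for rec in VCF(os.fspath(base_vcf_path)):
        alt = rec.ALT[0] if rec.ALT else "N"
        variants.append(VariantRecord(str(rec.CHROM), int(rec.POS), str(rec.REF), str(alt)))
    barcodes = _read_lines(barcodes_path)

    ad = sp.csr_matrix(scipy.io.mmread(os.fspath(ad_mtx_path)).T)
    dp = sp.csr_matrix(scipy.io.mmread(os.fspath(dp_mtx_path)).T)

    n_cells, n_vars = len(barcodes), len(variants)
    for name, mat in (("AD", ad), ("DP", dp)):
        path = ad_mtx_path if name == "AD" else dp_mtx_path
        if mat.shape[1] != n_vars:
            raise ValueError(
                f"{path}: matrix has {mat.shape[1]} variants but VCF {base_vcf_path} lists {n_vars}"
            )
        if mat.shape[0] != n_cells:
            raise ValueError(
                f"{path}: matrix has {mat.shape[0]} cells but {barcodes_path} lists {n_cells}"
            )
    return AlleleCounts(AD=ad, DP=dp, cells=barcodes, variants=variants)


def write_cellsnp(
    counts: AlleleCounts,
    base_vcf_path: str | os.PathLike,
    ad_mtx_path: str | os.PathLike,
    dp_mtx_path: str | os.PathLike,
    barcodes_path: str | os.PathLike,
) -> None:
    """Write the cellsnp-lite-compatible trio (VCF + AD/DP .mtx + barcodes)."""
    with open(base_vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cclone\n")
        for chrom in dict.fromkeys(v.chrom for v in counts.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in counts.variants:
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\tPASS\t.\n")
    scipy.io.mmwrite(os.fspath(ad_mtx_path), counts.AD.T.tocoo(), field="integer")
    scipy.io.mmwrite(os.fspath(dp_mtx_path), counts.DP.T.tocoo(), field="integer")
    with open(barcodes_path, "w") as fh:
        fh.write("\n".join(counts.cells) + ("\n" if counts.cells else ""))


_TRUTHY = {"1", "true", "yes", "t", "y"}
_FALSY = {"0", "false", "no", "f", "n", ""}


def _parse_flag(value) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY or s == "nan":
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean flag")


def read_annotations(
    annotation_table_path: str | os.PathLike,
    variants: Sequence[VariantRecord],
) -> list[VariantRecord]:
    """Attach germline-common / RNA-edit / repeat flags from a local TSV.

    The table is keyed by (chrom, pos, ref, alt) with columns
    ``is_germline_common``, ``is_rna_edit``, ``in_repeat_region`` and an
    optional ``consequence``. Variants absent from the table keep all flags
    False. Unparseable rows are skipped with a warning; duplicate keys with
    conflicting flags are an error.
    """
    table = pd.read_csv(annotation_table_path, sep="\t", dtype=str)
    required = {"chrom", "pos", "ref", "alt"}
    if not required <= set(table.columns):
        raise ValueError(f"annotation table must have columns {sorted(required)}")

    flags: dict[tuple, tuple[bool, bool, bool, str | None]] = {}
    for row in table.itertuples(index=False):
        try:
            pos = int(row.pos)
            entry = (
                _parse_flag(getattr(row, "is_germline_common", False)),
                _parse_flag(getattr(row, "is_rna_edit", False)),
                _parse_flag(getattr(row, "in_repeat_region", False)),
                getattr(row, "consequence", None),
            )
        except (ValueError, TypeError) as exc:
            logger.warning("skipping unparseable annotation row %s: %s", tuple(row), exc)
            continue
        key = (str(row.chrom), pos, str(row.ref), str(row.alt))
        if key in flags and flags[key][:3] != entry[:3]:
            raise ValueError(f"conflicting annotation flags for variant {key}")
        flags[key] = entry

    updated = []
    for v in variants:
        if v.key in flags:
            g, e, r, cons = flags[v.key]
            updated.append(
                VariantRecord(
                    v.chrom, v.pos, v.ref_allele, v.alt_allele,
                    is_germline_common=g, is_rna_edit=e, in_repeat_region=r,
                    consequence=cons if isinstance(cons, str) else v.consequence,
                )
            )
        else:
            updated.append(v)
    return updated


def read_cell_types(tsv_path: str | os.PathLike, cells: Sequence[str]) -> dict[str, str]:
    """Read a two-column barcode -> cell-type table, restricted to ``cells``.

    Barcodes absent from the table map to ``"unknown"``. Zero overlap between
    the table and the dataset is a hard error (almost certainly a wrong file).
    """
    table = pd.read_csv(tsv_path, sep="\t", header=None, names=["barcode", "type"], dtype=str)
    # tolerate a header row
    if len(table) and table.iloc[0, 0] in ("barcode", "cell", "cell_barcode"):
        table = table.iloc[1:]
    mapping: dict[str, str] = {}
    for bc, ct in zip(table["barcode"], table["type"]):
        bc, ct = str(bc), str(ct)
        if bc in mapping and mapping[bc] != ct:
            raise ValueError(f"barcode {bc!r} listed with conflicting cell types")
        mapping[bc] = ct
    cell_set = set(cells)
    overlap = cell_set & mapping.keys()
    if not overlap:
        raise ValueError(
            f"{tsv_path}: no barcode overlaps the dataset ({len(mapping)} table barcodes, "
            f"{len(cell_set)} dataset barcodes) — wrong file?"
        )
    return {bc: mapping.get(bc, "unknown") for bc in cells}


def write_cell_table(path: str | os.PathLike, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)
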