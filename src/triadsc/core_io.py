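"""Domain types, analysis thresholds, and 10x-style triplet file I/O.

The in-memory container is a :class:`Dataset`: a sparse genes x cells
expression matrix plus cell and gene annotation tables and the syntelog
(homoeolog-group) table for the triplicated genome. Genes carry a subgenome
label — LF, MF1, MF2 (least/medium/most fractionated) or UG (ungrouped,
no syntenic Arabidopsis ortholog) — and, for syntenic genes, a syntelog
group of 1–3 retained copies, at most one per subgenome.

On disk a dataset is a MatrixMarket triplet file with aligned features /
barcodes tables plus two TSV annotation tables. File order is canonical:
nothing is re-sorted on load or write.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "SUBGENOMES",
    "CELL_TYPES",
    "TISSUES",
    "CONDITIONS",
    "AnalysisThresholds",
    "ExpressionMatrix",
    "CellRecord",
    "GeneRecord",
    "SyntelogGroup",
    "Dataset",
    "DatasetError",
    "load_dataset",
    "write_dataset",
    "build_syntelog_table",
]

SUBGENOMES = ("LF", "MF1", "MF2", "UG")
CELL_TYPES = (
    "meristem",
    "mesophyll",
    "proliferating",
    "epidermal",
    "guard",
    "vascular",
    "unknown",
)
TISSUES = ("shoot", "leaf")
CONDITIONS = ("control", "heat")

RAW_LAYER = "raw_counts"
LOGNORM_LAYER = "lognorm"


class DatasetError(ValueError):
    """Raised for malformed input files or invariant violations."""


@dataclass(frozen=True)
class AnalysisThresholds:
    """All analysis cutoffs in one place.

    QC bounds are inclusive (a cell at exactly 500 UMIs survives). The
    log2 fold-change thresholds correspond to 1.28-fold (0.36) and
    1.41-fold (0.5) ratios; ``composition_scale`` is the per-sample cell
    total used for composition bar charts.
    """

    qc_umi_min: int = 500
    qc_umi_max: int = 50_000
    qc_genes_min: int = 200
    qc_genes_max: int = 10_000
    lognorm_scale: float = 10_000.0
    cluster_enriched_min_frac: float = 0.25
    cluster_enriched_log2fc: float = 0.36
    cluster_enriched_q: float = 0.01
    marker_log2fc: float = 0.5
    marker_p: float = 0.01
    marker_target_frac: float = 0.25
    marker_other_frac: float = 0.25
    expressed_cell_frac: float = 0.05
    dominance_log2fc: float = 0.36
    dominance_p: float = 0.05
    heat_log2fc: float = 0.36
    heat_p: float = 0.05
    heat_target_frac: float = 0.25
    composition_scale: float = 10_000.0

    def __post_init__(self):
        if not self.qc_umi_min < self.qc_umi_max:
            raise ValueError("qc_umi_min must be below qc_umi_max")
        if not self.qc_genes_min < self.qc_genes_max:
            raise ValueError("qc_genes_min must be below qc_genes_max")
        for name in (
            "cluster_enriched_min_frac",
            "cluster_enriched_q",
            "marker_p",
            "marker_target_frac",
            "marker_other_frac",
            "expressed_cell_frac",
            "dominance_p",
            "heat_p",
            "heat_target_frac",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass
class ExpressionMatrix:
    """Sparse genes x cells expression values with axis labels.

    ``layer`` is ``"raw_counts"`` (integer UMI counts) or ``"lognorm"``.
    """

    values: sp.spmatrix
    gene_ids: np.ndarray
    cell_barcodes: np.ndarray
    layer: str = RAW_LAYER

    def __post_init__(self):
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_barcodes = np.asarray(self.cell_barcodes, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.cell_barcodes)):
            raise DatasetError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_barcodes)} barcodes"
            )
        if len(set(self.cell_barcodes)) != len(self.cell_barcodes):
            raise DatasetError("duplicate cell barcodes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DatasetError("duplicate gene ids")
        if self.layer not in (RAW_LAYER, LOGNORM_LAYER):
            raise DatasetError(f"unknown layer {self.layer!r}")
        if self.values.nnz and self.values.data.min() < 0:
            raise DatasetError("negative expression values")
        if self.layer == RAW_LAYER and self.values.nnz:
            data = self.values.data
            if not np.allclose(data, np.rint(data)):
                raise DatasetError("raw_counts layer contains non-integer values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CellRecord:
    barcode: str
    sample_id: str
    tissue: str
    condition: str = "control"
    cluster_id: int | None = None
    cell_type: str | None = None

    def __post_init__(self):
        if self.tissue not in TISSUES:
            raise DatasetError(f"unknown tissue {self.tissue!r}")
        if self.condition not in CONDITIONS:
            raise DatasetError(f"unknown condition {self.condition!r}")
        if self.condition == "heat" and self.tissue != "leaf":
            raise DatasetError("heat condition only occurs in leaf tissue")
        if self.cell_type is not None and self.cell_type not in CELL_TYPES:
            raise DatasetError(f"unknown cell type {self.cell_type!r}")


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    subgenome: str
    syntelog_group: str | None = None
    at_ortholog: str | None = None
    family: str | None = None

    def __post_init__(self):
        if self.subgenome not in SUBGENOMES:
            raise DatasetError(f"unknown subgenome {self.subgenome!r}")
        if (self.subgenome == "UG") != (self.syntelog_group is None):
            raise DatasetError(
                f"gene {self.gene_id}: UG genes and only UG genes lack a "
                "syntelog group"
            )


@dataclass(frozen=True)
class SyntelogGroup:
    """A set of 1–3 homoeologous copies syntenic to one Arabidopsis gene."""

    group_id: str
    at_gene: str
    copies: tuple  # of (gene_id, subgenome)
    copy_class: int

    def __post_init__(self):
        if self.copy_class != len(self.copies):
            raise DatasetError(
                f"group {self.group_id}: copy_class must equal copy count"
            )
        if not 1 <= self.copy_class <= 3:
            raise DatasetError(f"group {self.group_id}: 1–3 copies required")
        subs = [s for _, s in self.copies]
        if len(set(subs)) != len(subs):
            raise DatasetError(
                f"group {self.group_id}: at most one copy per subgenome"
            )
        if "UG" in subs:
            raise DatasetError(f"group {self.group_id}: UG genes cannot be members")


@dataclass
class Dataset:
    """Expression matrix plus cell/gene annotation and syntelog tables.

    ``cells`` is indexed by barcode with columns (sample_id, tissue,
    condition, cluster_id, cell_type); ``genes`` is indexed by gene_id with
    columns (subgenome, syntelog_group, at_ortholog, family). Missing
    optional annotation is NA, never an empty-string sentinel. ``lognorm``
    holds the normalized layer once computed; the raw matrix is retained.
    """

    matrix: ExpressionMatrix
    cells: pd.DataFrame
    genes: pd.DataFrame
    syntelogs: list = field(default_factory=list)
    thresholds: AnalysisThresholds = field(default_factory=AnalysisThresholds)
    lognorm: ExpressionMatrix | None = None

    def __post_init__(self):
        if not self.cells.index.equals(pd.Index(self.matrix.cell_barcodes)):
            raise DatasetError("cell table index must match matrix barcodes")
        if not self.genes.index.equals(pd.Index(self.matrix.gene_ids)):
            raise DatasetError("gene table index must match matrix gene ids")
        gene_set = set(self.genes.index)
        for g in self.syntelogs:
            for gid, _ in g.copies:
                if gid not in gene_set:
                    raise DatasetError(
                        f"syntelog group {g.group_id} references unknown gene {gid}"
                    )

    @property
    def n_genes(self) -> int:
        return self.matrix.n_genes

    @property
    def n_cells(self) -> int:
        return self.matrix.n_cells

    def subset_cells(self, keep) -> "Dataset":
        """Restrict the dataset to a boolean mask / barcode list of cells."""
        keep = np.asarray(keep)
        if keep.dtype != bool:
            keep = np.isin(self.matrix.cell_barcodes, keep)
        mat = ExpressionMatrix(
            self.matrix.values[:, keep],
            self.matrix.gene_ids,
            self.matrix.cell_barcodes[keep],
            layer=self.matrix.layer,
        )
        ln = None
        if self.lognorm is not None:
            ln = ExpressionMatrix(
                self.lognorm.values[:, keep],
                self.lognorm.gene_ids,
                self.lognorm.cell_barcodes[keep],
                layer=LOGNORM_LAYER,
            )
        return Dataset(
            matrix=mat,
            cells=self.cells.loc[keep].copy(),
            genes=self.genes,
            syntelogs=self.syntelogs,
            thresholds=self.thresholds,
            lognorm=ln,
        )

    def with_thresholds(self, thresholds: AnalysisThresholds) -> "Dataset":
        return replace(self, thresholds=thresholds)

    def cell_type_mask(self, cell_type: str) -> np.ndarray:
        return (self.cells["cell_type"] == cell_type).to_numpy()


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _open_text(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _read_lines(path):
    with _open_text(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


_CELL_COLUMNS = ["sample_id", "tissue", "condition", "cluster_id", "cell_type"]
_GENE_COLUMNS = ["subgenome", "syntelog_group", "at_ortholog", "family"]


def _normalize_cells(df: pd.DataFrame, barcodes) -> pd.DataFrame:
    df = df.set_index("barcode") if "barcode" in df.columns else df
    for col in _CELL_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df = df[_CELL_COLUMNS]
    missing = [b for b in barcodes if b not in df.index]
    if missing:
        raise DatasetError(f"cell metadata missing barcodes, e.g. {missing[0]!r}")
    df = df.loc[list(barcodes)]
    df["cluster_id"] = df["cluster_id"].astype("Int64")
    for row in df.itertuples():
        CellRecord(
            barcode=row.Index,
            sample_id=str(row.sample_id),
            tissue=str(row.tissue),
            condition=str(row.condition),
        )
    return df


def _normalize_genes(df: pd.DataFrame, gene_ids) -> pd.DataFrame:
    df = df.set_index("gene_id") if "gene_id" in df.columns else df
    for col in _GENE_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df = df[_GENE_COLUMNS]
    missing = [g for g in gene_ids if g not in df.index]
    if missing:
        raise DatasetError(f"gene annotation missing ids, e.g. {missing[0]!r}")
    df = df.loc[list(gene_ids)]
    bad = df["subgenome"].notna() & ~df["subgenome"].isin(SUBGENOMES)
    if bad.any():
        raise DatasetError(
            f"unknown subgenome label {df.loc[bad, 'subgenome'].iloc[0]!r}"
        )
    ug = df["subgenome"] == "UG"
    if (ug & df["syntelog_group"].notna()).any():
        offender = df.index[ug & df["syntelog_group"].notna()][0]
        raise DatasetError(f"UG gene {offender} carries a syntelog group")
    if (~ug & df["subgenome"].notna() & df["syntelog_group"].isna()).any():
        offender = df.index[
            ~ug & df["subgenome"].notna() & df["syntelog_group"].isna()
        ][0]
        raise DatasetError(f"syntenic gene {offender} lacks a syntelog group")
    return df


def load_dataset(
    mtx_path,
    features_path,
    barcodes_path,
    cell_meta_path=None,
    gene_anno_path=None,
    thresholds: AnalysisThresholds | None = None,
) -> Dataset:
    """Load a 10x-style triplet dataset plus annotation tables.

    The matrix axes follow the features/barcodes files; annotation tables
    are TSV with headers. Raises :class:`DatasetError` on dimension
    mismatches, duplicate barcodes, or negative/non-integer raw counts.
    """
    try:
        mat = scipy.io.mmread(str(mtx_path))  # handles .gz by extension
    except Exception as exc:
        raise DatasetError(f"cannot parse MatrixMarket file {mtx_path}: {exc}")
    mat = sp.csr_matrix(mat)
    gene_ids = _read_lines(features_path)
    barcodes = _read_lines(barcodes_path)
    if mat.shape[0] != len(gene_ids):
        raise DatasetError(
            f"{features_path}: {len(gene_ids)} features but matrix declares "
            f"{mat.shape[0]} rows"
        )
    if mat.shape[1] != len(barcodes):
        raise DatasetError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrix declares "
            f"{mat.shape[1]} columns"
        )
    if mat.nnz:
        if mat.data.min() < 0:
            raise DatasetError(f"{mtx_path}: negative raw count")
        if not np.allclose(mat.data, np.rint(mat.data)):
            raise DatasetError(f"{mtx_path}: non-integer raw count")
    mat = mat.astype(np.int64)

    matrix = ExpressionMatrix(mat, gene_ids, barcodes, layer=RAW_LAYER)

    if cell_meta_path is not None:
        cells = pd.read_csv(cell_meta_path, sep="\t", dtype={"barcode": str})
        cells = _normalize_cells(cells, barcodes)
    else:
        cells = pd.DataFrame(
            {c: pd.NA for c in _CELL_COLUMNS}, index=pd.Index(barcodes, name="barcode")
        )
        cells["cluster_id"] = cells["cluster_id"].astype("Int64")

    if gene_anno_path is not None:
        genes = pd.read_csv(gene_anno_path, sep="\t", dtype=str)
        genes = _normalize_genes(genes, gene_ids)
    else:
        genes = pd.DataFrame(
            {c: pd.NA for c in _GENE_COLUMNS}, index=pd.Index(gene_ids, name="gene_id")
        )

    syntelogs = []
    if gene_anno_path is not None and genes["syntelog_group"].notna().any():
        syntelogs = build_syntelog_table(genes)

    return Dataset(
        matrix=matrix,
        cells=cells,
        genes=genes,
        syntelogs=syntelogs,
        thresholds=thresholds or AnalysisThresholds(),
    )


def write_dataset(ds: Dataset, out_dir) -> dict:
    """Write the triplet file set; deterministic bytes for a fixed dataset.

    Emits matrix.mtx, features.tsv, barcodes.tsv, cells.tsv, genes.tsv and
    returns their paths. Refuses to write a dataset with no cells.
    """
    if ds.n_cells == 0:
        raise DatasetError("refusing to write a dataset with zero cells")
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "mtx": os.path.join(out_dir, "matrix.mtx"),
        "features": os.path.join(out_dir, "features.tsv"),
        "barcodes": os.path.join(out_dir, "barcodes.tsv"),
        "cells": os.path.join(out_dir, "cells.tsv"),
        "genes": os.path.join(out_dir, "genes.tsv"),
    }
    field_kind = "integer" if ds.matrix.layer == RAW_LAYER else "real"
    coo = ds.matrix.values.tocoo()
    # COO in deterministic (row-major) order
    order = np.lexsort((coo.col, coo.row))
    coo = sp.coo_matrix(
        (coo.data[order], (coo.row[order], coo.col[order])), shape=coo.shape
    )
    scipy.io.mmwrite(paths["mtx"], coo, field=field_kind)
    with open(paths["features"], "w") as fh:
        fh.write("\n".join(map(str, ds.matrix.gene_ids)) + "\n")
    with open(paths["barcodes"], "w") as fh:
        fh.write("\n".join(map(str, ds.matrix.cell_barcodes)) + "\n")
    ds.cells.to_csv(paths["cells"], sep="\t", index_label="barcode")
    ds.genes.to_csv(paths["genes"], sep="\t", index_label="gene_id")
    return paths


# ---------------------------------------------------------------------------
# syntelog table
# ---------------------------------------------------------------------------

def build_syntelog_table(genes: pd.DataFrame) -> list:
    """Group syntenic genes into syntelog groups and validate copy structure.

    ``genes`` is the annotation table (index gene_id, columns subgenome /
    syntelog_group / at_ortholog). Groups partition the non-UG genes; a
    group with two copies in one subgenome or more than three copies is
    rejected.
    """
    ug = genes["subgenome"] == "UG"
    if (ug & genes["syntelog_group"].notna()).any():
        offender = genes.index[ug & genes["syntelog_group"].notna()][0]
        raise DatasetError(f"UG gene {offender} carries a syntelog group")
    syn = genes[genes["subgenome"].isin(("LF", "MF1", "MF2"))]
    if syn["syntelog_group"].isna().any():
        offender = syn.index[syn["syntelog_group"].isna()][0]
        raise DatasetError(f"syntenic gene {offender} lacks a syntelog group")
    groups = []
    for group_id, members in syn.groupby("syntelog_group", sort=True):
        copies = tuple(zip(members.index, members["subgenome"]))
        if len(copies) > 3:
            raise DatasetError(f"group {group_id} has more than three copies")
        at = members["at_ortholog"].dropna()
        at_gene = str(at.iloc[0]) if len(at) else ""
        groups.append(
            SyntelogGroup(
                group_id=str(group_id),
                at_gene=at_gene,
                copies=copies,
                copy_class=len(copies),
            )
        )
    return groups
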