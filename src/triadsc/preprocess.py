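"""QC filtering, LogNormalize, cluster composition/correlation, annotation.

Cell-level QC keeps cells whose total UMI count lies in [500, 50000] and
whose detected-gene count lies in [200, 10000], both bounds inclusive.
Normalization is the LogNormalize convention: per-cell scaling to a fixed
total (default 10,000) followed by the natural log of 1 + x.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import fisher_exact

from .core_io import (
    LOGNORM_LAYER,
    RAW_LAYER,
    Dataset,
    DatasetError,
    ExpressionMatrix,
)
from .de_stats import bh_adjust

__all__ = [
    "qc_filter_cells",
    "log_normalize",
    "cluster_composition",
    "cluster_correlation",
    "annotate_clusters",
]


def _require_layer(matrix: ExpressionMatrix, layer: str, op: str):
    if matrix.layer != layer:
        raise DatasetError(f"{op} requires the {layer} layer, got {matrix.layer}")


def qc_filter_cells(ds: Dataset):
    """Apply the UMI-total and detected-gene cell filters.

    Returns ``(filtered_dataset, report)`` where the report lists each
    removed barcode with its reason (umi_low / umi_high / genes_low /
    genes_high). Idempotent: filtering a filtered dataset removes nothing.
    """
    _require_layer(ds.matrix, RAW_LAYER, "qc_filter_cells")
    th = ds.thresholds
    X = ds.matrix.values.tocsc()
    totals = np.asarray(X.sum(axis=0)).ravel()
    n_detected = np.diff(X.indptr)

    reasons = np.full(ds.n_cells, "", dtype=object)
    reasons[totals < th.qc_umi_min] = "umi_low"
    reasons[totals > th.qc_umi_max] = "umi_high"
    low_g = (reasons == "") & (n_detected < th.qc_genes_min)
    reasons[low_g] = "genes_low"
    high_g = (reasons == "") & (n_detected > th.qc_genes_max)
    reasons[high_g] = "genes_high"
    keep = reasons == ""

    report = pd.DataFrame(
        {
            "barcode": ds.matrix.cell_barcodes[~keep],
            "total_umi": totals[~keep].astype(int),
            "n_genes": n_detected[~keep].astype(int),
            "reason": reasons[~keep],
        }
    ).reset_index(drop=True)
    return ds.subset_cells(keep), report


def log_normalize(ds: Dataset, scale: float | None = None) -> Dataset:
    """Attach the LogNormalize layer: ``ln(1 + count * scale / cell_total)``.

    The raw layer is retained alongside. Zero-total cells are an error
    (they cannot be scaled); run :func:`qc_filter_cells` first.
    """
    _require_layer(ds.matrix, RAW_LAYER, "log_normalize")
    if scale is None:
        scale = ds.thresholds.lognorm_scale
    X = ds.matrix.values.tocsc().astype(float)
    totals = np.asarray(X.sum(axis=0)).ravel()
    if np.any(totals == 0):
        bad = ds.matrix.cell_barcodes[totals == 0][0]
        raise DatasetError(f"cell {bad} has zero total count; cannot normalize")
    X = (X @ sp.diags(scale / totals)).tocsr()
    X.data = np.log1p(X.data)
    ln = ExpressionMatrix(
        X, ds.matrix.gene_ids, ds.matrix.cell_barcodes, layer=LOGNORM_LAYER
    )
    return replace(ds, lognorm=ln)


def cluster_composition(ds: Dataset) -> pd.DataFrame:
    """Per-cluster sample composition with shoot/leaf enrichment tests.

    Raw per-sample cell counts are rescaled so every sample totals
    ``composition_scale`` cells. With both tissues present, each cluster
    gets a 2x2 Fisher exact test of (in-cluster vs not) x (shoot vs leaf)
    on raw counts, BH-adjusted across clusters; with a single tissue the
    p-value columns are NA.
    """
    cells = ds.cells
    if cells["cluster_id"].isna().any():
        raise DatasetError("cluster_composition requires cluster_id on every cell")
    scale = ds.thresholds.composition_scale
    counts = (
        cells.groupby(["cluster_id", "sample_id"], observed=True)
        .size()
        .unstack(fill_value=0)
        .sort_index()
    )
    sample_totals = counts.sum(axis=0)
    normalized = counts * scale / sample_totals

    rows = pd.DataFrame(index=counts.index)
    for s in counts.columns:
        rows[f"n_{s}"] = counts[s]
        rows[f"norm_{s}"] = normalized[s]

    tissues = cells["tissue"].dropna().unique()
    if len(tissues) >= 2:
        shoot = cells["tissue"] == "shoot"
        n_shoot, n_leaf = int(shoot.sum()), int((~shoot).sum())
        ps, ors = [], []
        for cl in counts.index:
            in_cl = cells["cluster_id"] == cl
            a = int((in_cl & shoot).sum())
            b = int((in_cl & ~shoot).sum())
            table = [[a, b], [n_shoot - a, n_leaf - b]]
            odds, p = fisher_exact(table)
            ps.append(p)
            ors.append(odds)
        qs = bh_adjust(ps)
        rows["odds_ratio"] = ors
        rows["fisher_p"] = ps
        rows["bh_q"] = qs
        direction = np.where(
            (qs <= 0.05) & (np.array(ors) > 1),
            "shoot",
            np.where((qs <= 0.05) & (np.array(ors) < 1), "leaf", "none"),
        )
        rows["enriched"] = direction
    else:
        rows["odds_ratio"] = pd.NA
        rows["fisher_p"] = pd.NA
        rows["bh_q"] = pd.NA
        rows["enriched"] = "none"
    return rows


def _cluster_mean_profiles(ds: Dataset) -> pd.DataFrame:
    if ds.lognorm is None:
        raise DatasetError("cluster profiles require the lognorm layer")
    clusters = ds.cells["cluster_id"]
    if clusters.isna().any():
        raise DatasetError("every cell needs a cluster_id")
    X = ds.lognorm.values
    profiles = {}
    for cl in sorted(clusters.dropna().unique()):
        mask = (clusters == cl).to_numpy()
        if mask.sum() == 0:
            raise DatasetError(f"cluster {cl} has no cells")
        profiles[cl] = np.asarray(X[:, mask].mean(axis=1)).ravel()
    return pd.DataFrame(profiles, index=ds.matrix.gene_ids)


def cluster_correlation(ds: Dataset) -> pd.DataFrame:
    """Pearson correlation between per-cluster mean expression profiles."""
    profiles = _cluster_mean_profiles(ds)
    if profiles.shape[1] < 2:
        raise DatasetError("cluster_correlation requires at least two clusters")
    corr = np.corrcoef(profiles.to_numpy().T)
    return pd.DataFrame(corr, index=profiles.columns, columns=profiles.columns)


def annotate_clusters(ds: Dataset, marker_table) -> tuple:
    """Assign a cell type to every cluster from known marker genes.

    ``marker_table`` maps cell types to marker gene lists (dict or a
    DataFrame with cell_type / gene_id columns). Each cluster scores each
    cell type as the mean, over that type's markers, of the cluster's
    z-scored (across clusters) mean expression; the argmax is assigned if
    its score is positive, otherwise the cluster stays unknown. Ties go to
    the lexicographically first type and are recorded.

    Returns ``(assignment, dotplot, report)``: a cluster -> cell-type dict,
    the per (marker, cluster) dot-plot statistics, and a report listing
    skipped markers / ties / unscorable types.
    """
    if isinstance(marker_table, pd.DataFrame):
        marker_map = {
            t: list(g["gene_id"]) for t, g in marker_table.groupby("cell_type")
        }
    else:
        marker_map = {t: list(gs) for t, gs in marker_table.items()}

    profiles = _cluster_mean_profiles(ds)
    clusters = list(profiles.columns)
    gene_index = pd.Index(ds.matrix.gene_ids)
    report = {"skipped_markers": [], "unscorable_types": [], "ties": []}

    present_map = {}
    for t, gs in sorted(marker_map.items()):
        present = [g for g in gs if g in gene_index]
        report["skipped_markers"].extend(sorted(set(gs) - set(present)))
        if not present:
            report["unscorable_types"].append(t)
        else:
            present_map[t] = present

    # z-score cluster means across clusters, per gene
    P = profiles.to_numpy()
    mu = P.mean(axis=1, keepdims=True)
    sd = P.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        Z = np.where(sd > 0, (P - mu) / sd, 0.0)
    Z = pd.DataFrame(Z, index=profiles.index, columns=clusters)

    assignment = {}
    for ci, cl in enumerate(clusters):
        scores = {
            t: float(Z.loc[genes, cl].mean()) for t, genes in present_map.items()
        }
        if not scores:
            assignment[cl] = "unknown"
            continue
        best = max(scores.values())
        winners = sorted(t for t, s in scores.items() if s == best)
        if len(winners) > 1:
            report["ties"].append({"cluster": int(cl), "types": winners})
        assignment[cl] = winners[0] if best > 0 else "unknown"

    # dot-plot statistics: mean lognorm expression and detection fraction
    X = ds.lognorm.values
    rows = []
    all_markers = sorted({g for gs in present_map.values() for g in gs})
    cl_series = ds.cells["cluster_id"]
    for g in all_markers:
        gi = gene_index.get_loc(g)
        row = np.asarray(X[gi].todense()).ravel()
        for cl in clusters:
            mask = (cl_series == cl).to_numpy()
            vals = row[mask]
            rows.append(
                {
                    "gene_id": g,
                    "cluster_id": cl,
                    "mean_expr": float(vals.mean()),
                    "frac_expressing": float((vals > 0).mean()),
                }
            )
    dotplot = pd.DataFrame(rows)
    return assignment, dotplot, report
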