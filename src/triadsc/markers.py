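"""Cluster-enriched gene calling and novel cell-type marker identification.

Two related rules, matching how the study states them:

* cluster-enriched genes — tested cluster-vs-rest with the hurdle test,
  BH-adjusted within the cluster; called when detected in >= 25% of the
  cluster's cells, log2FC > 0.36 (enriched means higher in the cluster)
  and q <= 0.01;
* cell-type markers — log2FC > 0.5 against all other cells, raw p <= 0.01,
  detected in >= 25% of the target type's cells and in < 25% of the cells
  of every other type individually (a pooled-rest variant is available).

The q-vs-raw-p asymmetry between the two callers is deliberate; pass
``use_adjusted`` to harmonize.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core_io import Dataset, DatasetError
from . import de_stats

__all__ = ["cluster_enriched_genes", "cell_type_markers", "top_markers"]


def _de_scan(X, mask_a, mask_b):
    """Per-gene hurdle p, log2FC and detection stats for group A vs B."""
    ka, na, ma, va, ea = de_stats.group_summaries(X, mask_a)
    kb, nb, mb, vb, eb = de_stats.group_summaries(X, mask_b)
    p = de_stats.hurdle_test_arrays(ka, na, kb, nb, ma, va, mb, vb)
    log2fc = de_stats.fold_change_arrays(ea, eb)
    return {
        "p": p,
        "log2fc": log2fc,
        "pct_a": ka / max(na, 1),
        "pct_b": kb / max(nb, 1),
        "mean_a": ea,
    }


def cluster_enriched_genes(ds: Dataset, min_cells: int = 3) -> dict:
    """Genes enriched in each cluster versus all other cells.

    Returns a mapping cluster_id -> DataFrame of calls (gene_id, log2fc,
    p, q, pct_target, pct_rest, mean_target), sorted by q then gene_id.
    Clusters with fewer than ``min_cells`` cells are skipped with a warning.
    """
    if ds.lognorm is None:
        raise DatasetError("cluster_enriched_genes requires the lognorm layer")
    th = ds.thresholds
    clusters = ds.cells["cluster_id"]
    if clusters.isna().any():
        raise DatasetError("every cell needs a cluster_id")
    X = ds.lognorm.values
    out = {}
    for cl in sorted(clusters.dropna().unique()):
        mask = (clusters == cl).to_numpy()
        if mask.sum() < min_cells:
            warnings.warn(f"cluster {cl} has <{min_cells} cells; skipped")
            continue
        scan = _de_scan(X, mask, ~mask)
        q = de_stats.bh_adjust(scan["p"])
        called = (
            (scan["pct_a"] >= th.cluster_enriched_min_frac)
            & (scan["log2fc"] > th.cluster_enriched_log2fc)
            & (q <= th.cluster_enriched_q)
        )
        table = pd.DataFrame(
            {
                "gene_id": ds.matrix.gene_ids[called],
                "target": cl,
                "log2fc": scan["log2fc"][called],
                "p": scan["p"][called],
                "q": q[called],
                "pct_target": scan["pct_a"][called],
                "pct_rest": scan["pct_b"][called],
                "mean_target": scan["mean_a"][called],
            }
        ).sort_values(["q", "gene_id"], kind="stable").reset_index(drop=True)
        out[cl] = table
    return out


def cell_type_markers(
    ds: Dataset,
    exclusivity: str = "per_type",
    use_adjusted: bool = False,
) -> dict:
    """Novel cell-type markers under the exclusive-detection rule.

    ``exclusivity`` is ``"per_type"`` (the detection fraction must be below
    the cutoff in every other type separately) or ``"pooled"`` (below the
    cutoff in the pooled rest). Requires >= 2 labeled (non-unknown) types.
    """
    if ds.lognorm is None:
        raise DatasetError("cell_type_markers requires the lognorm layer")
    if exclusivity not in ("per_type", "pooled"):
        raise ValueError(f"unknown exclusivity mode {exclusivity!r}")
    th = ds.thresholds
    labels = ds.cells["cell_type"]
    labeled = labels.notna() & (labels != "unknown")
    types = sorted(labels[labeled].unique())
    if len(types) < 2:
        raise DatasetError("cell_type_markers requires >= 2 labeled cell types")
    X = ds.lognorm.values

    # per-type detection fractions, for the exclusivity rule
    pct_by_type = {}
    for t in types:
        mask = (labels == t).to_numpy()
        k, n, *_ = de_stats.group_summaries(X, mask)
        pct_by_type[t] = k / max(n, 1)

    out = {}
    for t in types:
        mask_t = (labels == t).to_numpy()
        mask_rest = labeled.to_numpy() & ~mask_t
        scan = _de_scan(X, mask_t, mask_rest)
        p_used = de_stats.bh_adjust(scan["p"]) if use_adjusted else scan["p"]
        if exclusivity == "per_type":
            others_ok = np.all(
                [pct_by_type[o] < th.marker_other_frac for o in types if o != t],
                axis=0,
            )
        else:
            others_ok = scan["pct_b"] < th.marker_other_frac
        called = (
            (scan["pct_a"] >= th.marker_target_frac)
            & others_ok
            & (scan["log2fc"] > th.marker_log2fc)
            & (p_used <= th.marker_p)
        )
        table = pd.DataFrame(
            {
                "gene_id": ds.matrix.gene_ids[called],
                "target": t,
                "log2fc": scan["log2fc"][called],
                "p": scan["p"][called],
                "q": de_stats.bh_adjust(scan["p"])[called],
                "pct_target": scan["pct_a"][called],
                "pct_rest": scan["pct_b"][called],
                "mean_target": scan["mean_a"][called],
            }
        )
        for o in types:
            if o != t:
                table[f"pct_{o}"] = pct_by_type[o][called]
        out[t] = table.sort_values(
            ["p", "gene_id"], kind="stable"
        ).reset_index(drop=True)
    return out


def top_markers(calls: pd.DataFrame, n: int = 20) -> pd.DataFrame:
    """The ``n`` highest-expressed calls, by mean expression in the target.

    Ties break lexicographically on gene_id; ``n=0`` returns an empty list.
    """
    if "mean_target" not in calls.columns:
        raise ValueError("calls table lacks a mean_target column")
    ranked = calls.sort_values(
        ["mean_target", "gene_id"], ascending=[False, True], kind="stable"
    )
    return ranked.head(n).reset_index(drop=True)
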