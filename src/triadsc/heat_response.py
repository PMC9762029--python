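"""Control-vs-heat differential expression per cell type and derived views.

A gene is a heat DEG in a cell type when the hurdle test gives p < 0.05,
|log2FC| >= 0.36 (heat minus control), and the gene is detected in more
than 25% of the type's cells (pooled across conditions). P-values are
used raw, matching the stated rule; ``adjust=True`` switches to BH
q-values. Derived analyses: the exact subset partition of DEGs across
cell types per direction, single-cell-type heat markers, opposite-pattern
genes, the per-cell UMI shift, reference-gene stability, subgenome DEG
counts, and per-family direction matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .core_io import SUBGENOMES, Dataset, DatasetError
from . import de_stats

__all__ = [
    "condition_degs",
    "heat_deg_table",
    "PatternPartition",
    "deg_partition",
    "heat_marker_genes",
    "opposite_pattern_genes",
    "umi_shift_test",
    "reference_gene_check",
    "subgenome_deg_counts",
    "family_summary",
]


def condition_degs(
    ds: Dataset, cell_type: str, adjust: bool = False
) -> pd.DataFrame:
    """Heat-vs-control DEGs within one cell type.

    Returns a DataFrame with columns gene_id, log2fc, p, q, pct_heat,
    pct_control, pct_type and direction (up/down, heat relative to
    control). Requires >= 3 cells of the type in each condition.
    """
    if ds.lognorm is None:
        raise DatasetError("condition_degs requires the lognorm layer")
    th = ds.thresholds
    mask_type = (ds.cells["cell_type"] == cell_type).to_numpy()
    cond = ds.cells["condition"]
    mask_heat = mask_type & (cond == "heat").to_numpy()
    mask_ctrl = mask_type & (cond == "control").to_numpy()
    for name, m in (("heat", mask_heat), ("control", mask_ctrl)):
        if m.sum() < 3:
            raise DatasetError(
                f"cell type {cell_type!r} has {int(m.sum())} {name} cells (<3)"
            )
    X = ds.lognorm.values
    ka, na, ma, va, ea = de_stats.group_summaries(X, mask_heat)
    kb, nb, mb, vb, eb = de_stats.group_summaries(X, mask_ctrl)
    p = de_stats.hurdle_test_arrays(ka, na, kb, nb, ma, va, mb, vb)
    log2fc = de_stats.fold_change_arrays(ea, eb)
    q = de_stats.bh_adjust(p)
    p_used = q if adjust else p

    raw = ds.matrix.values[:, mask_type]
    pct_type = np.asarray((raw > 0).sum(axis=1)).ravel() / mask_type.sum()

    called = (
        (np.abs(log2fc) >= th.heat_log2fc)
        & (p_used < th.heat_p)
        & (pct_type > th.heat_target_frac)
    )
    table = pd.DataFrame(
        {
            "gene_id": ds.matrix.gene_ids[called],
            "cell_type": cell_type,
            "log2fc": log2fc[called],
            "p": p[called],
            "q": q[called],
            "pct_heat": ka[called] / max(na, 1),
            "pct_control": kb[called] / max(nb, 1),
            "pct_type": pct_type[called],
            "direction": np.where(log2fc[called] > 0, "up", "down"),
        }
    ).sort_values(["p", "gene_id"], kind="stable").reset_index(drop=True)
    return table


def heat_deg_table(ds: Dataset, cell_types=None, adjust: bool = False) -> dict:
    """``condition_degs`` for every (labeled) cell type: type -> DataFrame."""
    if cell_types is None:
        cell_types = sorted(
            t for t in ds.cells["cell_type"].dropna().unique() if t != "unknown"
        )
    return {t: condition_degs(ds, t, adjust=adjust) for t in cell_types}


@dataclass
class PatternPartition:
    """Exact subset partition of DEGs across cell types, per direction."""

    up: dict  # frozenset of cell types -> set of gene_ids
    down: dict
    shared_all_up: set = field(default_factory=set)
    shared_all_down: set = field(default_factory=set)
    specific_up: dict = field(default_factory=dict)  # cell_type -> set
    specific_down: dict = field(default_factory=dict)
    opposite: dict = field(default_factory=dict)  # gene -> {type: +1/-1}
    cell_types: tuple = ()
    membership: dict = field(default_factory=dict)  # gene -> {type: dir}


def deg_partition(heat_table: dict) -> PatternPartition:
    """Partition per-type DEG sets by the exact subset of types involved."""
    types = tuple(sorted(heat_table))
    if len(types) < 2:
        raise DatasetError("deg_partition requires DEGs for >= 2 cell types")
    sets = {"up": {}, "down": {}}
    membership = {}
    for t, table in heat_table.items():
        for direction in ("up", "down"):
            genes = set(table.loc[table["direction"] == direction, "gene_id"])
            sets[direction][t] = genes
            for g in genes:
                membership.setdefault(g, {})[t] = direction

    def partition(per_type: dict) -> dict:
        union = set().union(*per_type.values()) if per_type else set()
        out = {}
        for g in union:
            key = frozenset(t for t in types if g in per_type[t])
            out.setdefault(key, set()).add(g)
        return out

    up_part = partition(sets["up"])
    down_part = partition(sets["down"])
    all_types = frozenset(types)
    opposite = {
        g: dict((t, 1 if d == "up" else -1) for t, d in per.items())
        for g, per in membership.items()
        if {"up", "down"} <= set(per.values())
    }
    return PatternPartition(
        up=up_part,
        down=down_part,
        shared_all_up=set(up_part.get(all_types, set())),
        shared_all_down=set(down_part.get(all_types, set())),
        specific_up={
            t: set(up_part.get(frozenset([t]), set())) for t in types
        },
        specific_down={
            t: set(down_part.get(frozenset([t]), set())) for t in types
        },
        opposite=opposite,
        cell_types=types,
        membership=membership,
    )


def heat_marker_genes(partition: PatternPartition) -> dict:
    """Genes that are a DEG (either direction) in exactly one cell type."""
    out = {t: set() for t in partition.cell_types}
    for g, per in partition.membership.items():
        if len(per) == 1:
            (t,) = per
            out[t].add(g)
    return out


def opposite_pattern_genes(heat_table: dict) -> dict:
    """Per-type lists of genes that flip direction across cell types.

    Returns cell_type -> DataFrame (gene_id, sign) for every type where an
    opposite-pattern gene is a DEG, sign +1 for up, -1 for down.
    """
    part = deg_partition(heat_table)
    rows = {t: [] for t in part.cell_types}
    for g, per in sorted(part.opposite.items()):
        for t, s in per.items():
            rows[t].append({"gene_id": g, "sign": s})
    return {
        t: pd.DataFrame(r, columns=["gene_id", "sign"]) for t, r in rows.items()
    }


def umi_shift_test(ds: Dataset, cell_type: str) -> dict:
    """Heat-vs-control shift of per-cell total UMIs within one type.

    Two-sided Wilcoxon rank-sum on per-cell totals; reports both medians
    and the p-value.
    """
    mask_type = (ds.cells["cell_type"] == cell_type).to_numpy()
    cond = ds.cells["condition"]
    totals = np.asarray(ds.matrix.values.sum(axis=0)).ravel()
    heat = totals[mask_type & (cond == "heat").to_numpy()]
    ctrl = totals[mask_type & (cond == "control").to_numpy()]
    if heat.size == 0 or ctrl.size == 0:
        raise DatasetError(
            f"cell type {cell_type!r} lacks cells in one condition"
        )
    stat, p = mannwhitneyu(heat, ctrl, alternative="two-sided")
    return {
        "cell_type": cell_type,
        "median_control": float(np.median(ctrl)),
        "median_heat": float(np.median(heat)),
        "p": float(p),
    }


def reference_gene_check(
    heat_table: dict, reference_ids, all_gene_ids
) -> pd.DataFrame:
    """Flag reference genes that appear in any DEG table.

    Genes absent from the matrix are recorded as untestable rather than
    failed; an empty reference list yields a vacuous (empty) report.
    """
    known = set(all_gene_ids)
    rows = []
    for g in reference_ids:
        if g not in known:
            for t in heat_table:
                rows.append({"gene_id": g, "cell_type": t, "status": "untestable"})
            continue
        for t, table in heat_table.items():
            hit = g in set(table["gene_id"])
            rows.append(
                {"gene_id": g, "cell_type": t, "status": "fail" if hit else "pass"}
            )
    return pd.DataFrame(rows, columns=["gene_id", "cell_type", "status"])


def subgenome_deg_counts(heat_table: dict, genes: pd.DataFrame) -> pd.DataFrame:
    """DEG counts per cell type x subgenome, total and split by direction."""
    rows = []
    for t, table in sorted(heat_table.items()):
        subs = genes.loc[table["gene_id"], "subgenome"].to_numpy()
        for sub in SUBGENOMES:
            in_sub = subs == sub
            rows.append(
                {
                    "cell_type": t,
                    "subgenome": sub,
                    "n_deg": int(in_sub.sum()),
                    "n_up": int(
                        (in_sub & (table["direction"] == "up").to_numpy()).sum()
                    ),
                    "n_down": int(
                        (in_sub & (table["direction"] == "down").to_numpy()).sum()
                    ),
                }
            )
    return pd.DataFrame(rows)


def family_summary(
    heat_table: dict, genes: pd.DataFrame, family_tag: str
) -> pd.DataFrame:
    """Direction matrix (up/down/ns) for a gene family across cell types.

    Rows carry the syntelog group and subgenome so copy-divergent
    responses within a family are visible side by side.
    """
    fams = genes["family"].dropna().unique()
    members = genes.index[genes["family"] == family_tag]
    if len(members) == 0:
        raise DatasetError(
            f"no genes tagged {family_tag!r}; available tags: {sorted(fams)}"
        )
    types = sorted(heat_table)
    direction = {
        t: dict(zip(table["gene_id"], table["direction"]))
        for t, table in heat_table.items()
    }
    rows = []
    for g in members:
        row = {
            "gene_id": g,
            "subgenome": genes.at[g, "subgenome"],
            "syntelog_group": genes.at[g, "syntelog_group"],
        }
        for t in types:
            row[t] = direction[t].get(g, "ns")
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(["syntelog_group", "gene_id"], kind="stable").reset_index(
        drop=True
    )
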