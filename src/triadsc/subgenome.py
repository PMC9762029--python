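"""Subgenome expression analyses over syntelog groups.

Covers the per-cell-type expressed-gene sets (detected in >= 5% of the
type's cells), expressed-gene proportions and mean expression per
subgenome, expressed fractions per syntelog copy class, and the
predominant-expression (dominance) calls: within a syntelog group and
cell type, a copy is dominant when it is expressed in >= 5% of the type's
cells and beats every other copy with log2FC >= 0.36 at p <= 0.05.

The dominance test is a paired Wilcoxon signed-rank over the same cells —
the homoeologous copies are measured in identical cells, so pairing is
the natural design. The hurdle test is available as an alternative via
``test="hurdle"``. P-values are reported raw (the stated rule); pass
``adjust=True`` to BH-correct within each cell type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import SUBGENOMES, Dataset, DatasetError, SyntelogGroup
from . import de_stats

__all__ = [
    "expressed_genes",
    "subgenome_proportions",
    "copy_class_expression",
    "DominanceCall",
    "dominance_call",
    "dominance_calls",
    "dominance_counts",
]


def _type_mask(ds: Dataset, cell_type: str) -> np.ndarray:
    mask = (ds.cells["cell_type"] == cell_type).to_numpy()
    if mask.sum() == 0:
        raise DatasetError(f"no cells of type {cell_type!r}")
    return mask


def expressed_genes(ds: Dataset, cell_type: str) -> set:
    """Genes with nonzero raw counts in >= 5% of the type's cells.

    The boundary is inclusive: 5 detected cells out of 100 qualifies.
    """
    mask = _type_mask(ds, cell_type)
    X = ds.matrix.values[:, mask]
    frac = np.asarray((X > 0).sum(axis=1)).ravel() / mask.sum()
    keep = frac >= ds.thresholds.expressed_cell_frac
    return set(ds.matrix.gene_ids[keep])


def subgenome_proportions(ds: Dataset, expressed: dict) -> pd.DataFrame:
    """Counts, proportions and mean expression of expressed genes per subgenome.

    ``expressed`` maps cell_type -> expressed gene set (from
    :func:`expressed_genes`). Mean expression is the average lognorm value
    over the type's cells and the subgenome's expressed genes.
    """
    if ds.lognorm is None:
        raise DatasetError("subgenome_proportions requires the lognorm layer")
    sub_of = ds.genes["subgenome"]
    gene_index = pd.Index(ds.matrix.gene_ids)
    rows = []
    for cell_type, gene_set in sorted(expressed.items()):
        if not gene_set:
            raise DatasetError(f"empty expressed set for {cell_type!r}")
        mask = _type_mask(ds, cell_type)
        total = len(gene_set)
        for sub in SUBGENOMES:
            genes_sub = [g for g in gene_set if sub_of.get(g) == sub]
            if genes_sub:
                gi = gene_index.get_indexer(genes_sub)
                mean_expr = float(ds.lognorm.values[gi][:, mask].mean())
            else:
                mean_expr = np.nan
            rows.append(
                {
                    "cell_type": cell_type,
                    "subgenome": sub,
                    "n_expressed": len(genes_sub),
                    "proportion": len(genes_sub) / total,
                    "mean_expression": mean_expr,
                }
            )
    return pd.DataFrame(rows)


def copy_class_expression(expressed: dict, syntelogs: list) -> pd.DataFrame:
    """Fraction of genes expressed within each syntelog copy class per type.

    Empty classes yield NA fractions rather than zero.
    """
    by_class = {1: set(), 2: set(), 3: set()}
    for g in syntelogs:
        for gid, _ in g.copies:
            by_class[g.copy_class].add(gid)
    rows = []
    for cell_type, gene_set in sorted(expressed.items()):
        for cls in (1, 2, 3):
            members = by_class[cls]
            frac = len(gene_set & members) / len(members) if members else pd.NA
            rows.append(
                {
                    "cell_type": cell_type,
                    "copy_class": cls,
                    "n_genes": len(members),
                    "frac_expressed": frac,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class DominanceCall:
    """Outcome of the predominant-expression test for one group and type."""

    group_id: str
    cell_type: str
    dominant: str | None  # subgenome label, or None
    dominant_gene: str | None
    pairwise: list  # of (gene_i, gene_j, log2fc, p)


def _gene_rows(ds: Dataset, gene_ids, mask):
    gi = pd.Index(ds.matrix.gene_ids).get_indexer(gene_ids)
    if (gi < 0).any():
        missing = [g for g, i in zip(gene_ids, gi) if i < 0]
        raise DatasetError(f"genes absent from matrix: {missing}")
    ln = np.asarray(ds.lognorm.values[gi][:, mask].todense())
    raw = np.asarray(ds.matrix.values[gi][:, mask].todense())
    return ln, raw


def dominance_call(
    ds: Dataset,
    group: SyntelogGroup,
    cell_type: str,
    test: str = "signed_rank",
    adjust: bool = False,
) -> DominanceCall:
    """Test whether one copy of a syntelog group dominates in a cell type.

    A copy is dominant iff it is detected in >= 5% of the type's cells and
    for every other copy both log2FC >= 0.36 and p <= 0.05 hold. At most
    one copy can win (the fold-change requirement is antisymmetric).
    """
    if group.copy_class < 2:
        raise DatasetError(f"group {group.group_id} has a single copy")
    if ds.lognorm is None:
        raise DatasetError("dominance_call requires the lognorm layer")
    mask = _type_mask(ds, cell_type)
    th = ds.thresholds
    gene_ids = [gid for gid, _ in group.copies]
    subs = {gid: sub for gid, sub in group.copies}
    ln, raw = _gene_rows(ds, gene_ids, mask)
    n = mask.sum()
    pct = (raw > 0).sum(axis=1) / n
    means = np.expm1(ln).mean(axis=1)

    pairwise = []
    wins = {g: 0 for g in gene_ids}
    for i in range(len(gene_ids)):
        for j in range(i + 1, len(gene_ids)):
            fc = float(
                np.log2(means[i] + 1.0) - np.log2(means[j] + 1.0)
            )
            if test == "signed_rank":
                p = de_stats.paired_signed_rank(ln[i], ln[j])
            elif test == "hurdle":
                p = de_stats.hurdle_test(ln[i], ln[j])
            else:
                raise ValueError(f"unknown dominance test {test!r}")
            pairwise.append((gene_ids[i], gene_ids[j], fc, p))
            if p <= th.dominance_p:
                if fc >= th.dominance_log2fc:
                    wins[gene_ids[i]] += 1
                if -fc >= th.dominance_log2fc:
                    wins[gene_ids[j]] += 1

    dominant_gene = None
    for k, g in enumerate(gene_ids):
        if wins[g] == len(gene_ids) - 1 and pct[k] >= th.expressed_cell_frac:
            dominant_gene = g
            break
    return DominanceCall(
        group_id=group.group_id,
        cell_type=cell_type,
        dominant=subs[dominant_gene] if dominant_gene else None,
        dominant_gene=dominant_gene,
        pairwise=pairwise,
    )


def dominance_calls(
    ds: Dataset,
    cell_types=None,
    test: str = "signed_rank",
    adjust: bool = False,
) -> list:
    """Dominance calls for every multi-copy group in the given cell types.

    With ``adjust=True`` the pairwise p-values are BH-corrected within each
    cell type before the decision rule is applied.
    """
    if cell_types is None:
        cell_types = sorted(
            t
            for t in ds.cells["cell_type"].dropna().unique()
            if t != "unknown"
        )
    groups = [g for g in ds.syntelogs if g.copy_class >= 2]
    calls = []
    for cell_type in cell_types:
        type_calls = [
            dominance_call(ds, g, cell_type, test=test) for g in groups
        ]
        if adjust:
            type_calls = _readjust(ds, type_calls)
        calls.extend(type_calls)
    return calls


def _readjust(ds: Dataset, type_calls: list) -> list:
    """Re-apply the decision rule with BH-adjusted pairwise p-values."""
    th = ds.thresholds
    ps = [p for c in type_calls for (_, _, _, p) in c.pairwise]
    qs = iter(de_stats.bh_adjust(ps))
    out = []
    gene_sub = dict(
        pair for g in ds.syntelogs for pair in g.copies
    )
    for c in type_calls:
        new_pairs = [(a, b, fc, next(qs)) for (a, b, fc, _) in c.pairwise]
        wins = {}
        genes = sorted({g for pair in new_pairs for g in pair[:2]})
        for g in genes:
            wins[g] = 0
        for a, b, fc, q in new_pairs:
            if q <= th.dominance_p:
                if fc >= th.dominance_log2fc:
                    wins[a] += 1
                if -fc >= th.dominance_log2fc:
                    wins[b] += 1
        # q >= p elementwise, so adjustment can only revoke a win: the only
        # possible winner is the raw-p winner, whose detection gate already
        # passed in the first pass.
        dominant_gene = None
        if c.dominant_gene is not None and wins[c.dominant_gene] == len(genes) - 1:
            dominant_gene = c.dominant_gene
        out.append(
            DominanceCall(
                group_id=c.group_id,
                cell_type=c.cell_type,
                dominant=gene_sub.get(dominant_gene) if dominant_gene else None,
                dominant_gene=dominant_gene,
                pairwise=new_pairs,
            )
        )
    return out


def dominance_counts(calls: list) -> pd.DataFrame:
    """Count dominant groups per cell type x subgenome (one event per group)."""
    types = sorted({c.cell_type for c in calls})
    table = pd.DataFrame(
        0, index=pd.Index(types, name="cell_type"), columns=["LF", "MF1", "MF2"]
    )
    for c in calls:
        if c.dominant is not None:
            table.loc[c.cell_type, c.dominant] += 1
    return table
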