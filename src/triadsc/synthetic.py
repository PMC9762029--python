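"""Seeded generator of synthetic triplicated-genome scRNA-seq datasets.

The generator emulates the structure the downstream analyses assume: a
gene catalog of 1:1 / 1:2 / 1:3 syntelog groups with LF-biased subgenome
retention plus a large, mostly silent ungrouped (UG) gene set; per-type
cell-identity marker genes; a planted dominant homoeolog copy in a
fraction of multi-copy groups; and a heat condition whose effects are
partly shared across cell types, partly type-specific, partly
opposite-signed, together with a depressed per-cell UMI target in all
cell types except proliferating cells. Counts are negative binomial with
mean mu and variance mu + phi*mu^2 (Poisson at phi = 0); per-gene rates
are renormalized within each cell so the drawn library size, not the gene
catalog, sets sequencing depth.

A single RNG stream is consumed in the documented step order: catalog,
baseline rates, dominance, markers, heat sets, library sizes, counts.
Summary statistics are therefore portable across runs with one seed;
bit-exactness is only promised within one implementation.

The :class:`GroundTruth` object records every planted set for recovery
testing. Planted marker and heat-response genes are drawn from genes whose
baseline rate is at least ``planted_min_rate``: the study's marker/DEG
definitions only apply to expressed genes, so signal planted on silent or
near-silent genes would be undetectable by construction. The default floor
is set by the binding detection gate — a down-regulated heat gene must
still be detected in >25% of the type's cells pooled across conditions,
which at the default library size and dispersion requires a baseline rate
of roughly 0.2 per 10k; 0.25 adds margin. Markers are placed outside
multi-copy syntelog groups so the two planted axes of variation — cell
identity and homoeolog dominance — remain orthogonal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import (
    AnalysisThresholds,
    Dataset,
    ExpressionMatrix,
    SyntelogGroup,
    build_syntelog_table,
)

__all__ = ["SimulationConfig", "GroundTruth", "simulate_dataset"]

LEAF_CELL_TYPES = ("mesophyll", "epidermal", "guard", "vascular", "proliferating")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _check_probs(name, probs):
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-12:
        raise ConfigError(f"{name} probabilities sum to {total}, expected 1")


@dataclass
class SimulationConfig:
    """All knobs of the generative model, with study-scale defaults.

    Rates are on an expected-counts-per-10k scale before the per-cell
    renormalization; effect sizes are log2 multipliers.
    """

    seed: int = 0
    cell_types: tuple = LEAF_CELL_TYPES
    cells_per_type_per_condition: int = 200
    n11: int = 300
    n12: int = 300
    n13: int = 200
    n_ug: int = 400
    baseline_log_mean: float = float(np.log(0.5))
    baseline_log_sd: float = 1.0
    ug_silent_fraction: float = 0.8
    ug_silent_factor: float = 0.01
    retention_probs_pair: dict = field(
        default_factory=lambda: {
            ("LF", "MF1"): 0.45,
            ("LF", "MF2"): 0.35,
            ("MF1", "MF2"): 0.20,
        }
    )
    retention_probs_single: dict = field(
        default_factory=lambda: {"LF": 0.5, "MF1": 0.3, "MF2": 0.2}
    )
    f_dom: float = 0.3
    dom_subgenome_probs: dict = field(
        default_factory=lambda: {"LF": 0.6, "MF1": 0.25, "MF2": 0.15}
    )
    delta_dom: float = 1.0
    m_markers_per_type: int = 30
    beta_marker: float = 2.0
    n_shared_up: int = 150
    n_shared_down: int = 92
    n_specific_per_type: int = 50
    n_opposite: int = 20
    gamma_heat: float = 1.0
    heat_umi_factor: dict | None = None
    libsize_log_mean: float = float(np.log(5000.0))
    libsize_log_sd: float = 0.4
    libsize_min: float = 500.0
    libsize_max: float = 50_000.0
    nb_dispersion: float = 0.5
    planted_min_rate: float = 0.25
    tissue: str = "leaf"
    conditions: tuple = ("control", "heat")
    n_replicates: int = 2

    def __post_init__(self):
        if self.heat_umi_factor is None:
            self.heat_umi_factor = {
                t: (1.0 if t == "proliferating" else 0.8) for t in self.cell_types
            }
        _check_probs("retention_probs_pair", self.retention_probs_pair)
        _check_probs("retention_probs_single", self.retention_probs_single)
        _check_probs("dom_subgenome_probs", self.dom_subgenome_probs)
        for name in ("n11", "n12", "n13", "n_ug", "cells_per_type_per_condition"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("delta_dom", "beta_marker", "gamma_heat"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if "heat" in self.conditions and self.tissue != "leaf":
            raise ConfigError("heat condition requires leaf tissue")


@dataclass
class GroundTruth:
    """Planted signals of one simulated dataset, for recovery testing."""

    marker_genes: dict  # cell_type -> set of gene_ids
    dominant_copy: dict  # group_id -> (gene_id, subgenome)
    heat_up: dict  # cell_type -> set of gene_ids
    heat_down: dict  # cell_type -> set of gene_ids
    opposite_genes: dict  # gene_id -> {cell_type: +1 | -1}

    def to_json(self) -> str:
        def enc(obj):
            if isinstance(obj, (set, frozenset)):
                return sorted(obj)
            if isinstance(obj, tuple):
                return list(obj)
            raise TypeError(type(obj))

        return json.dumps(asdict(self), default=enc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        return cls(
            marker_genes={k: set(v) for k, v in raw["marker_genes"].items()},
            dominant_copy={k: tuple(v) for k, v in raw["dominant_copy"].items()},
            heat_up={k: set(v) for k, v in raw["heat_up"].items()},
            heat_down={k: set(v) for k, v in raw["heat_down"].items()},
            opposite_genes={
                k: {t: int(s) for t, s in v.items()}
                for k, v in raw["opposite_genes"].items()
            },
        )


# ---------------------------------------------------------------------------
# catalog construction
# ---------------------------------------------------------------------------

def _build_catalog(cfg: SimulationConfig, rng: np.random.Generator):
    """Gene ids, subgenome labels and syntelog group assignments."""
    gene_ids, subgenomes, groups, at_orth = [], [], [], []
    gid = 0

    def new_gene(sub, grp, at):
        nonlocal gid
        gene_ids.append(f"BAA{(gid % 10) + 1:02d}g{10 * gid + 10:05d}")
        subgenomes.append(sub)
        groups.append(grp)
        at_orth.append(at)
        gid += 1

    singles = list(cfg.retention_probs_single)
    p_single = [cfg.retention_probs_single[s] for s in singles]
    pairs = list(cfg.retention_probs_pair)
    p_pair = [cfg.retention_probs_pair[p] for p in pairs]

    grp_idx = 0
    pick1 = rng.choice(len(singles), size=cfg.n11, p=p_single)
    for i in range(cfg.n11):
        grp, at = f"SG{grp_idx:05d}", f"AT{grp_idx % 5 + 1}G{grp_idx:05d}"
        new_gene(singles[pick1[i]], grp, at)
        grp_idx += 1
    pick2 = rng.choice(len(pairs), size=cfg.n12, p=p_pair)
    for i in range(cfg.n12):
        grp, at = f"SG{grp_idx:05d}", f"AT{grp_idx % 5 + 1}G{grp_idx:05d}"
        for sub in pairs[pick2[i]]:
            new_gene(sub, grp, at)
        grp_idx += 1
    for _ in range(cfg.n13):
        grp, at = f"SG{grp_idx:05d}", f"AT{grp_idx % 5 + 1}G{grp_idx:05d}"
        for sub in ("LF", "MF1", "MF2"):
            new_gene(sub, grp, at)
        grp_idx += 1
    for _ in range(cfg.n_ug):
        new_gene("UG", None, None)

    genes = pd.DataFrame(
        {
            "subgenome": subgenomes,
            "syntelog_group": groups,
            "at_ortholog": at_orth,
            "family": pd.NA,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return genes


# ---------------------------------------------------------------------------
# main entry point
# ---------------------------------------------------------------------------

def simulate_dataset(cfg: SimulationConfig):
    """Generate a raw-counts :class:`Dataset` and its :class:`GroundTruth`."""
    rng = np.random.default_rng(cfg.seed)
    types = list(cfg.cell_types)
    conditions = list(cfg.conditions)

    # (1) gene catalog
    genes = _build_catalog(cfg, rng)
    n_genes = len(genes)
    gene_ids = genes.index.to_numpy()
    is_ug = (genes["subgenome"] == "UG").to_numpy()
    group_of = genes["syntelog_group"]
    group_sizes = group_of.value_counts()
    multi_copy_groups = sorted(group_sizes.index[group_sizes >= 2])
    in_multi = group_of.isin(set(multi_copy_groups)).to_numpy()

    # (2) baseline rates + UG silencing. Copies of one syntelog group share
    # their baseline rate: homoeologs inherit one ancestral regulatory
    # context, and planted dominance is the deviation from it. Without the
    # sharing, iid per-copy rates would make most unplanted groups genuinely
    # imbalanced and "dominance" would be unrecoverable by construction.
    n_groups = cfg.n11 + cfg.n12 + cfg.n13
    group_rate = rng.lognormal(
        cfg.baseline_log_mean, cfg.baseline_log_sd, size=n_groups
    )
    rate_of_group = dict(zip(sorted(group_sizes.index), group_rate[: len(group_sizes)]))
    ug_rate = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=cfg.n_ug)
    lam = np.empty(n_genes)
    ug_pos = np.where(is_ug)[0]
    lam[ug_pos] = ug_rate
    syn_pos = np.where(~is_ug)[0]
    lam[syn_pos] = [rate_of_group[group_of.iloc[i]] for i in syn_pos]
    silent = is_ug & (rng.random(n_genes) < cfg.ug_silent_fraction)
    lam = np.where(silent, lam * cfg.ug_silent_factor, lam)
    if not np.all(np.isfinite(lam)):
        raise RuntimeError("non-finite baseline rate")

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    eligible = (lam >= cfg.planted_min_rate) & ~silent

    # (3) planted dominant copies in a fraction of multi-copy groups
    dom_mult = np.ones(n_genes)
    dominant_copy = {}
    n_dom = int(round(cfg.f_dom * len(multi_copy_groups)))
    dom_groups = rng.choice(len(multi_copy_groups), size=n_dom, replace=False)
    members_of = {
        g: list(genes.index[group_of == g]) for g in multi_copy_groups
    }
    for gi in sorted(dom_groups):
        grp = multi_copy_groups[gi]
        members = members_of[grp]
        subs = [genes.at[m, "subgenome"] for m in members]
        w = np.array([cfg.dom_subgenome_probs.get(s, 0.0) for s in subs])
        if w.sum() <= 0:
            w = np.ones(len(subs))
        w = w / w.sum()
        pick = rng.choice(len(members), p=w)
        gidx = gene_pos[members[pick]]
        dom_mult[gidx] *= 2.0**cfg.delta_dom
        dominant_copy[grp] = (members[pick], subs[pick])

    # (4) cell-identity markers, outside multi-copy groups
    marker_pool = np.where(eligible & ~in_multi)[0]
    need = cfg.m_markers_per_type * len(types)
    if need > len(marker_pool):
        raise ConfigError(
            f"need {need} marker genes but only {len(marker_pool)} eligible"
        )
    picked = rng.choice(marker_pool, size=need, replace=False)
    marker_mult = {t: np.ones(n_genes) for t in types}
    marker_genes = {}
    for i, t in enumerate(types):
        idx = picked[i * cfg.m_markers_per_type : (i + 1) * cfg.m_markers_per_type]
        marker_mult[t][idx] *= 2.0**cfg.beta_marker
        marker_genes[t] = set(gene_ids[idx])

    # (5) heat effect sets (disjoint from markers and from each other).
    # Each component is allocated across subgenomes in proportion to the
    # eligible pool sizes (largest-remainder rounding), so the catalog's
    # LF-biased retention is mirrored in the planted heat sets by
    # construction, as it is in the study system.
    heat_up = {t: set() for t in types}
    heat_down = {t: set() for t in types}
    opposite_genes = {}
    heat_sign = {t: np.zeros(n_genes) for t in types}  # log2 multiplier sign
    if "heat" in conditions:
        sub_labels = genes["subgenome"].to_numpy()
        pool_by_sub = {
            s: list(np.where(eligible & (sub_labels == s) & ~np.isin(np.arange(n_genes), picked))[0])
            for s in ("LF", "MF1", "MF2", "UG")
        }
        n_heat = (
            cfg.n_shared_up
            + cfg.n_shared_down
            + cfg.n_specific_per_type * len(types)
            + cfg.n_opposite
        )
        if n_heat > sum(len(v) for v in pool_by_sub.values()):
            raise ConfigError(
                f"need {n_heat} heat-response genes but only "
                f"{sum(len(v) for v in pool_by_sub.values())} eligible"
            )

        def stratified(n):
            sizes = {s: len(v) for s, v in pool_by_sub.items()}
            total = sum(sizes.values())
            exact = {s: n * sizes[s] / total for s in sizes}
            alloc = {s: int(np.floor(exact[s])) for s in sizes}
            remainder = sorted(
                sizes, key=lambda s: (exact[s] - alloc[s], s), reverse=True
            )
            i = 0
            while sum(alloc.values()) < n:
                alloc[remainder[i % len(remainder)]] += 1
                i += 1
            out = []
            for s in ("LF", "MF1", "MF2", "UG"):
                take = min(alloc[s], len(pool_by_sub[s]))
                idx = rng.choice(len(pool_by_sub[s]), size=take, replace=False)
                chosen = [pool_by_sub[s][j] for j in idx]
                for g in sorted(chosen, reverse=True):
                    pool_by_sub[s].remove(g)
                out.extend(chosen)
            return np.array(sorted(out))

        shared_up_idx = stratified(cfg.n_shared_up)
        shared_down_idx = stratified(cfg.n_shared_down)
        for t in types:
            heat_sign[t][shared_up_idx] = 1.0
            heat_sign[t][shared_down_idx] = -1.0
            heat_up[t].update(gene_ids[shared_up_idx])
            heat_down[t].update(gene_ids[shared_down_idx])

        for t in types:
            idx = stratified(cfg.n_specific_per_type)
            signs = rng.choice([1.0, -1.0], size=len(idx))
            heat_sign[t][idx] = signs
            heat_up[t].update(gene_ids[idx[signs > 0]])
            heat_down[t].update(gene_ids[idx[signs < 0]])

        opp_idx = stratified(cfg.n_opposite)
        for gidx in opp_idx:
            t_up, t_dn = rng.choice(len(types), size=2, replace=False)
            heat_sign[types[t_up]][gidx] = 1.0
            heat_sign[types[t_dn]][gidx] = -1.0
            heat_up[types[t_up]].add(gene_ids[gidx])
            heat_down[types[t_dn]].add(gene_ids[gidx])
            opposite_genes[gene_ids[gidx]] = {
                types[t_up]: 1,
                types[t_dn]: -1,
            }

    # cell bookkeeping (type-major, condition-minor, replicates alternating)
    n_per = cfg.cells_per_type_per_condition
    cell_type_col, condition_col, sample_col = [], [], []
    for t in types:
        for cond in conditions:
            tag = "C" if cond == "control" else "H"
            for j in range(n_per):
                cell_type_col.append(t)
                condition_col.append(cond)
                rep = j % cfg.n_replicates + 1
                prefix = cfg.tissue[0].upper()
                sample_col.append(f"{prefix}{rep}-{tag}")
    n_cells = len(cell_type_col)
    barcodes = np.array([f"BC{i:06d}" for i in range(n_cells)], dtype=object)

    # (6) library sizes, clipped, heat cells scaled by the per-type factor
    libsize = rng.lognormal(cfg.libsize_log_mean, cfg.libsize_log_sd, size=n_cells)
    libsize = np.clip(libsize, cfg.libsize_min, cfg.libsize_max)
    umi_factor = np.array(
        [
            cfg.heat_umi_factor.get(t, 1.0) if c == "heat" else 1.0
            for t, c in zip(cell_type_col, condition_col)
        ]
    )
    libsize = libsize * umi_factor

    # (7) counts per (type, condition) block, NB with dispersion phi
    blocks = []
    phi = cfg.nb_dispersion
    start = 0
    for t in types:
        for cond in conditions:
            lam_block = lam * dom_mult * marker_mult[t]
            if cond == "heat":
                lam_block = lam_block * 2.0 ** (cfg.gamma_heat * heat_sign[t])
            p_gene = lam_block / lam_block.sum()
            L = libsize[start : start + n_per]
            mu = np.outer(p_gene, L)
            if phi > 0:
                r = 1.0 / phi
                counts = rng.negative_binomial(r, r / (r + mu))
            else:
                counts = rng.poisson(mu)
            blocks.append(sp.csr_matrix(counts))
            start += n_per
    values = sp.hstack(blocks, format="csr").astype(np.int64)

    matrix = ExpressionMatrix(values, gene_ids, barcodes, layer="raw_counts")
    cells = pd.DataFrame(
        {
            "sample_id": sample_col,
            "tissue": cfg.tissue,
            "condition": condition_col,
            "cluster_id": pd.array(
                [types.index(t) for t in cell_type_col], dtype="Int64"
            ),
            "cell_type": cell_type_col,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    ds = Dataset(
        matrix=matrix,
        cells=cells,
        genes=genes,
        syntelogs=build_syntelog_table(genes),
        thresholds=AnalysisThresholds(),
    )
    truth = GroundTruth(
        marker_genes=marker_genes,
        dominant_copy=dominant_copy,
        heat_up=heat_up,
        heat_down=heat_down,
        opposite_genes=opposite_genes,
    )
    return ds, truth
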