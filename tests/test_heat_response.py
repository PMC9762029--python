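import numpy as np
import pandas as pd
import pytest

from triadsc import heat_response, preprocess
from triadsc.core_io import DatasetError

from conftest import make_toy_dataset


def _toy_heat_table():
    """Hand-built DEG tables for the set-algebra operations."""

    def table(t, genes_up, genes_down):
        rows = [
            {"gene_id": g, "cell_type": t, "direction": "up"} for g in genes_up
        ] + [
            {"gene_id": g, "cell_type": t, "direction": "down"} for g in genes_down
        ]
        return pd.DataFrame(rows, columns=["gene_id", "cell_type", "direction"])

    return {
        "guard": table("guard", ["a", "b"], ["x"]),
        "mesophyll": table("mesophyll", ["b", "c"], ["a"]),
    }


class TestConditionDegs:
    def _ds(self, effect=2.0, n=150, seed=20):
        rng = np.random.default_rng(seed)
        base = np.full(40, 3.0)
        ctrl = rng.poisson(base[:, None], size=(40, n))
        heat = rng.poisson(base[:, None], size=(40, n))
        heat[0] = rng.poisson(3.0 * effect, size=n)  # planted up gene
        counts = np.hstack([ctrl, heat])
        ds = make_toy_dataset(
            counts,
            cell_types=["guard"] * (2 * n),
            conditions=["control"] * n + ["heat"] * n,
        )
        return preprocess.log_normalize(ds)

    def test_planted_gene_called_up(self):
        degs = heat_response.condition_degs(self._ds(), "guard")
        assert "g0" in set(degs["gene_id"])
        assert degs.set_index("gene_id").loc["g0", "direction"] == "up"

    def test_effect_gate(self):
        # 1.2-fold shift is below the 1.28-fold threshold
        degs = heat_response.condition_degs(self._ds(effect=1.2, n=2000), "guard")
        assert "g0" not in set(degs["gene_id"])

    def test_fraction_gate(self):
        rng = np.random.default_rng(21)
        n = 200
        counts = np.vstack(
            [
                np.concatenate([rng.poisson(0.08, n), rng.poisson(0.4, n)]),
                np.full(2 * n, 4),
            ]
        )
        ds = make_toy_dataset(
            counts,
            cell_types=["guard"] * (2 * n),
            conditions=["control"] * n + ["heat"] * n,
        )
        ds = preprocess.log_normalize(ds)
        degs = heat_response.condition_degs(ds, "guard")
        # pooled detection ~22% < 25%: excluded despite a strong effect
        assert "g0" not in set(degs["gene_id"])

    def test_too_few_cells_errors(self):
        counts = np.ones((10, 5), dtype=int) * 3
        ds = make_toy_dataset(
            counts,
            cell_types=["guard"] * 5,
            conditions=["control"] * 3 + ["heat"] * 2,
        )
        ds = preprocess.log_normalize(ds)
        with pytest.raises(DatasetError, match="heat"):
            heat_response.condition_degs(ds, "guard")

    def test_planted_recovery(self, heat_table):
        """>=85% of planted per-type heat genes recovered with the right
        direction."""
        table, truth = heat_table
        for t, degs in table.items():
            up = set(degs.loc[degs["direction"] == "up", "gene_id"])
            down = set(degs.loc[degs["direction"] == "down", "gene_id"])
            rec_up = len(up & truth.heat_up[t]) / len(truth.heat_up[t])
            rec_down = len(down & truth.heat_down[t]) / len(truth.heat_down[t])
            assert rec_up >= 0.85, (t, rec_up)
            assert rec_down >= 0.85, (t, rec_down)


class TestPartition:
    def test_set_algebra(self):
        part = heat_response.deg_partition(_toy_heat_table())
        assert part.up[frozenset(["guard", "mesophyll"])] == {"b"}
        assert part.specific_up["guard"] == {"a"}
        assert part.specific_up["mesophyll"] == {"c"}
        assert part.shared_all_up == {"b"}
        # 'a' flips direction across types
        assert part.opposite == {"a": {"guard": 1, "mesophyll": -1}}

    def test_disjoint_subsets_cover_union(self, heat_table):
        table, _ = heat_table
        part = heat_response.deg_partition(table)
        for direction in ("up", "down"):
            subsets = getattr(part, direction)
            union_from_parts = set()
            for key, genes in subsets.items():
                assert genes, key
                assert not (union_from_parts & genes)
                union_from_parts |= genes
            direct_union = set()
            for t, degs in table.items():
                direct_union |= set(
                    degs.loc[degs["direction"] == direction, "gene_id"]
                )
            assert union_from_parts == direct_union

    def test_disjoint_up_sets_have_empty_shared(self):
        ht = _toy_heat_table()
        ht["mesophyll"] = ht["mesophyll"][ht["mesophyll"]["gene_id"] != "b"]
        part = heat_response.deg_partition(ht)
        assert part.shared_all_up == set()


class TestHeatMarkers:
    def test_only_one_type_rule(self):
        part = heat_response.deg_partition(_toy_heat_table())
        hm = heat_response.heat_marker_genes(part)
        assert hm["guard"] == {"x"}  # down only in guard
        assert hm["mesophyll"] == {"c"}
        # 'a' is up in guard and down in mesophyll: involved in two types
        assert "a" not in hm["guard"] and "a" not in hm["mesophyll"]

    def test_specific_gene_recovery(self, heat_table):
        table, truth = heat_table
        part = heat_response.deg_partition(table)
        hm = heat_response.heat_marker_genes(part)
        types = list(table)
        tp = n = 0
        for t in types:
            others = set().union(
                *[truth.heat_up[o] | truth.heat_down[o] for o in types if o != t]
            )
            planted = (truth.heat_up[t] | truth.heat_down[t]) - others
            n += len(planted)
            tp += len(planted & hm[t])
        assert tp / n >= 0.80

    def test_marker_sets_disjoint_and_complement_shared(self, heat_table):
        table, _ = heat_table
        part = heat_response.deg_partition(table)
        hm = heat_response.heat_marker_genes(part)
        all_markers = set()
        for t, genes in hm.items():
            assert not (all_markers & genes)
            all_markers |= genes
        all_degs = set(part.membership)
        multi = {g for g, per in part.membership.items() if len(per) > 1}
        assert all_markers | multi == all_degs


class TestOpposite:
    def test_toy_signs(self):
        opp = heat_response.opposite_pattern_genes(_toy_heat_table())
        guard = dict(zip(opp["guard"]["gene_id"], opp["guard"]["sign"]))
        meso = dict(zip(opp["mesophyll"]["gene_id"], opp["mesophyll"]["sign"]))
        assert guard["a"] == 1 and meso["a"] == -1

    def test_planted_opposite_recovery(self, heat_table):
        table, truth = heat_table
        part = heat_response.deg_partition(table)
        hit = 0
        for g, signs in truth.opposite_genes.items():
            got = part.opposite.get(g, {})
            if all(got.get(t) == s for t, s in signs.items()):
                hit += 1
        assert hit / len(truth.opposite_genes) >= 0.80


class TestUmiShift:
    def test_planted_depression_detected(self, sim_default):
        ds, _ = sim_default
        for t in ("mesophyll", "epidermal", "guard", "vascular"):
            r = heat_response.umi_shift_test(ds, t)
            assert r["p"] < 0.01
            assert r["median_heat"] < r["median_control"]
        spared = heat_response.umi_shift_test(ds, "proliferating")
        assert spared["p"] > 0.05

    def test_missing_condition_errors(self, control_ds):
        ds, _ = control_ds
        with pytest.raises(DatasetError):
            heat_response.umi_shift_test(ds, "guard")


class TestReferenceGenes:
    def test_null_genes_pass_planted_gene_fails(self, heat_table, sim_default):
        table, truth = heat_table
        ds, _ = sim_default
        planted = sorted(truth.heat_up["mesophyll"])[0]
        affected = set().union(*truth.heat_up.values(), *truth.heat_down.values())
        null_genes = [g for g in ds.genes.index[:50] if g not in affected][:5]
        report = heat_response.reference_gene_check(
            table, null_genes + [planted, "absent_gene"], ds.genes.index
        )
        by_gene = report.groupby("gene_id")["status"].agg(set)
        for g in null_genes:
            assert by_gene[g] == {"pass"}
        assert "fail" in by_gene[planted]
        assert by_gene["absent_gene"] == {"untestable"}

    def test_empty_reference_list_vacuous(self, heat_table):
        table, _ = heat_table
        report = heat_response.reference_gene_check(table, [], ["g1"])
        assert len(report) == 0


class TestSubgenomeDegCounts:
    def test_toy_counts(self):
        genes = pd.DataFrame(
            {"subgenome": ["LF", "LF", "MF2"]},
            index=pd.Index(["a", "b", "c"], name="gene_id"),
        )
        ht = {
            "guard": pd.DataFrame(
                {
                    "gene_id": ["a", "b", "c"],
                    "direction": ["up", "down", "up"],
                }
            )
        }
        table = heat_response.subgenome_deg_counts(ht, genes)
        row = table.set_index("subgenome")
        assert row.loc["LF", "n_deg"] == 2
        assert row.loc["MF2", "n_deg"] == 1
        assert row.loc["MF1", "n_deg"] == 0 and row.loc["UG", "n_deg"] == 0

    def test_lf_greatest_in_every_type(self, heat_table, sim_default):
        """Heat genes sampled across the LF-biased catalog give LF the
        largest DEG count per type."""
        table, _ = heat_table
        ds, _ = sim_default
        counts = heat_response.subgenome_deg_counts(table, ds.genes)
        for t, sub in counts.groupby("cell_type"):
            row = sub.set_index("subgenome")["n_deg"]
            assert row["LF"] > row["MF1"] and row["LF"] > row["MF2"]


class TestFamilySummary:
    def test_direction_matrix(self, sim_default, heat_table):
        ds, truth = sim_default
        table, _ = heat_table
        genes = ds.genes.copy()
        part = heat_response.deg_partition(table)
        shared_down = sorted(part.shared_all_down)[:2]
        fam_members = shared_down + [sorted(ds.genes.index)[0]]
        genes.loc[fam_members, "family"] = "HSP"
        out = heat_response.family_summary(table, genes, "HSP")
        out = out.set_index("gene_id")
        types = sorted(table)
        for g in shared_down:
            assert all(out.loc[g, t] == "down" for t in types)

    def test_member_without_degs_is_ns(self):
        genes = pd.DataFrame(
            {
                "subgenome": ["LF"],
                "syntelog_group": ["s1"],
                "family": ["HSP"],
            },
            index=pd.Index(["a"], name="gene_id"),
        )
        ht = {"guard": pd.DataFrame({"gene_id": [], "direction": []})}
        out = heat_response.family_summary(ht, genes, "HSP")
        assert out.loc[0, "guard"] == "ns"

    def test_unknown_tag_lists_available(self):
        genes = pd.DataFrame(
            {"subgenome": ["LF"], "syntelog_group": ["s1"], "family": ["HSP"]},
            index=pd.Index(["a"], name="gene_id"),
        )
        with pytest.raises(DatasetError, match="HSP"):
            heat_response.family_summary({}, genes, "LEA")
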