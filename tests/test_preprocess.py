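import numpy as np
import pandas as pd
import pytest

from triadsc import preprocess
from triadsc.core_io import DatasetError

from conftest import make_toy_dataset


def _qc_toy():
    # 4 cells: 499 total UMIs / boundary 500 / normal / too many genes
    n_genes = 300
    counts = np.zeros((n_genes, 4), dtype=int)
    counts[:250, 0] = 1
    counts[249, 0] += 249  # 499 total over 250 genes
    counts[:250, 1] = 2  # 500 total over 250 genes
    counts[:260, 2] = 4  # comfortable cell
    counts[:, 3] = 10  # 300 genes is fine; low gene case below
    return counts


class TestQC:
    def test_boundaries(self):
        ds = make_toy_dataset(_qc_toy())
        filtered, report = preprocess.qc_filter_cells(ds)
        removed = dict(zip(report["barcode"], report["reason"]))
        assert removed == {"c0": "umi_low"}
        assert "c1" in filtered.matrix.cell_barcodes  # 500 UMIs kept (inclusive)

    def test_gene_count_bounds(self):
        counts = np.zeros((30, 2), dtype=int)
        counts[:25, 0] = 40  # 25 genes < 200 -> genes_low
        counts[:30, 1] = 20
        ds = make_toy_dataset(counts)
        _, report = preprocess.qc_filter_cells(ds)
        reasons = set(report["reason"])
        assert "genes_low" in reasons

    def test_high_gene_count_removed(self):
        from triadsc.core_io import AnalysisThresholds

        th = AnalysisThresholds(qc_genes_max=20, qc_genes_min=2, qc_umi_min=5)
        counts = np.ones((25, 1), dtype=int) * 2  # 25 detected genes > 20
        ds = make_toy_dataset(counts, thresholds=th)
        _, report = preprocess.qc_filter_cells(ds)
        assert list(report["reason"]) == ["genes_high"]

    def test_idempotent(self):
        ds = make_toy_dataset(_qc_toy())
        once, _ = preprocess.qc_filter_cells(ds)
        twice, report = preprocess.qc_filter_cells(once)
        assert len(report) == 0
        assert list(once.matrix.cell_barcodes) == list(twice.matrix.cell_barcodes)

    def test_rejects_normalized_layer(self):
        ds = make_toy_dataset(np.ones((300, 2), dtype=int) * 3)
        ds = preprocess.log_normalize(ds)
        import dataclasses

        norm_only = dataclasses.replace(ds, matrix=ds.lognorm, lognorm=None)
        with pytest.raises(DatasetError, match="raw"):
            preprocess.qc_filter_cells(norm_only)


class TestLogNormalize:
    def test_closed_form(self):
        counts = np.array([[2], [2]])
        ds = make_toy_dataset(counts)
        out = preprocess.log_normalize(ds, scale=10)
        # count 2, total 4, scale 10 -> ln(1 + 5)
        assert out.lognorm.values[0, 0] == pytest.approx(np.log(6.0), abs=1e-12)

    def test_zeros_stay_zero_and_raw_retained(self):
        counts = np.array([[0, 3], [5, 0]])
        ds = make_toy_dataset(counts)
        out = preprocess.log_normalize(ds)
        dense = out.lognorm.values.toarray()
        assert dense[0, 0] == 0 and dense[1, 1] == 0
        assert (out.matrix.values != ds.matrix.values).nnz == 0

    def test_matches_scanpy_oracle(self):
        """Cross-check against scanpy normalize_total + log1p."""
        import anndata
        import scanpy as sc

        rng = np.random.default_rng(6)
        counts = rng.poisson(2.0, size=(50, 20))
        counts[:, 0] += 1  # no zero-total cells
        ds = make_toy_dataset(counts)
        ours = preprocess.log_normalize(ds, scale=10_000).lognorm.values.toarray()
        ad = anndata.AnnData(X=counts.T.astype(float))
        sc.pp.normalize_total(ad, target_sum=10_000)
        sc.pp.log1p(ad)
        assert np.allclose(ours, ad.X.T, atol=1e-9)

    def test_closed_form_inverse_recovers_proportions(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(3.0, size=(40, 10)) + (np.arange(40) == 0)[:, None]
        ds = make_toy_dataset(counts)
        out = preprocess.log_normalize(ds, scale=1000)
        back = np.expm1(out.lognorm.values.toarray()) / 1000
        props = counts / counts.sum(axis=0, keepdims=True)
        assert np.allclose(back, props, atol=1e-12)

    def test_zero_total_cell_names_barcode(self):
        counts = np.array([[1, 0], [1, 0]])
        ds = make_toy_dataset(counts)
        with pytest.raises(DatasetError, match="c1"):
            preprocess.log_normalize(ds)


class TestComposition:
    def _two_tissue_ds(self, shoot_in_cluster0=90, leaf_in_cluster0=10, total=1000):
        n = 2 * total
        clusters = (
            [0] * shoot_in_cluster0
            + [1] * (total - shoot_in_cluster0)
            + [0] * leaf_in_cluster0
            + [1] * (total - leaf_in_cluster0)
        )
        tissues = ["shoot"] * total + ["leaf"] * total
        samples = ["S1"] * total + ["L1"] * total
        counts = np.ones((1, n), dtype=int)
        return make_toy_dataset(
            counts, clusters=clusters, tissues=tissues, samples=samples
        )

    def test_normalized_counts_scale(self):
        ds = self._two_tissue_ds()
        comp = preprocess.cluster_composition(ds)
        # sample of 1000 cells with 90 in cluster 0 -> 900 of 10,000
        assert comp.loc[0, "norm_S1"] == pytest.approx(900.0)
        for s in ("S1", "L1"):
            assert comp[f"norm_{s}"].sum() == pytest.approx(10_000.0)

    def test_odds_ratio_and_direction(self):
        ds = self._two_tissue_ds()
        comp = preprocess.cluster_composition(ds)
        assert comp.loc[0, "odds_ratio"] == pytest.approx(
            (90 * 990) / (910 * 10), rel=1e-9
        )
        assert comp.loc[0, "enriched"] == "shoot"
        assert (comp["bh_q"] >= comp["fisher_p"] - 1e-15).all()

    def test_balanced_cluster_p_one(self):
        ds = self._two_tissue_ds(shoot_in_cluster0=50, leaf_in_cluster0=50)
        comp = preprocess.cluster_composition(ds)
        assert comp.loc[0, "fisher_p"] == pytest.approx(1.0)

    def test_single_tissue_has_no_p(self):
        counts = np.ones((1, 6), dtype=int)
        ds = make_toy_dataset(counts, clusters=[0, 0, 1, 1, 1, 0])
        comp = preprocess.cluster_composition(ds)
        assert comp["fisher_p"].isna().all()


class TestClusterCorrelation:
    def test_duplicate_cluster_and_symmetry(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(2, size=(60, 30)) + (np.arange(60) == 0)[:, None]
        clusters = ([0] * 10 + [1] * 10 + [2] * 10)
        ds = make_toy_dataset(counts, clusters=clusters)
        # make clusters 0 and 1 identical in the mean by mirroring columns
        counts[:, 10:20] = counts[:, :10]
        ds = make_toy_dataset(counts, clusters=clusters)
        ds = preprocess.log_normalize(ds)
        corr = preprocess.cluster_correlation(ds)
        assert corr.loc[0, 1] == pytest.approx(1.0)
        assert np.allclose(corr.values, corr.values.T, atol=1e-12)
        assert np.allclose(np.diag(corr.values), 1.0, atol=1e-12)

    def test_within_type_exceeds_between_type(self, control_ds):
        """Two clusters of one simulated cell type correlate more strongly
        with each other than with a different cell type's cluster."""
        ds, _ = control_ds
        ds2 = ds.subset_cells(
            ds.cells["cell_type"].isin(["mesophyll", "guard"]).to_numpy()
        )
        cells = ds2.cells.copy()
        meso = (cells["cell_type"] == "mesophyll").to_numpy()
        half = np.zeros(len(cells), dtype=bool)
        half[np.where(meso)[0][::2]] = True
        new_cluster = np.where(~meso, 2, np.where(half, 0, 1))
        cells["cluster_id"] = pd.array(new_cluster, dtype="Int64")
        ds2 = type(ds2)(
            matrix=ds2.matrix,
            cells=cells,
            genes=ds2.genes,
            syntelogs=ds2.syntelogs,
            thresholds=ds2.thresholds,
            lognorm=ds2.lognorm,
        )
        corr = preprocess.cluster_correlation(ds2)
        assert corr.loc[0, 1] > corr.loc[0, 2]
        assert corr.loc[0, 1] > corr.loc[1, 2]


class TestAnnotate:
    def test_recovers_simulated_types_and_dotplot(self, control_ds):
        ds, gt = control_ds
        marker_table = pd.DataFrame(
            [
                {"cell_type": t, "gene_id": g}
                for t, genes in gt.marker_genes.items()
                for g in sorted(genes)[:5]
            ]
        )
        assignment, dotplot, report = preprocess.annotate_clusters(ds, marker_table)
        types = list(np.array(sorted(gt.marker_genes)))
        cfg_types = ("mesophyll", "epidermal", "guard", "vascular", "proliferating")
        for cl, t in assignment.items():
            assert t == cfg_types[int(cl)]
        assert ((dotplot["frac_expressing"] >= 0) & (dotplot["frac_expressing"] <= 1)).all()

    def test_no_signal_is_unknown(self):
        counts = np.ones((5, 8), dtype=int) * 2
        ds = make_toy_dataset(counts, clusters=[0] * 4 + [1] * 4)
        ds = preprocess.log_normalize(ds)
        assignment, _, _ = preprocess.annotate_clusters(
            ds, {"mesophyll": ["g0"], "guard": ["g1"]}
        )
        # constant genes z-score to 0 everywhere -> no positive score
        assert set(assignment.values()) == {"unknown"}

    def test_tie_breaks_lexicographically_and_is_reported(self):
        counts = np.array([[5, 5, 1, 1]] * 2 + [[1, 1, 1, 1]])
        ds = make_toy_dataset(counts, clusters=[0, 0, 1, 1])
        ds = preprocess.log_normalize(ds)
        assignment, _, report = preprocess.annotate_clusters(
            ds, {"guard": ["g0"], "epidermal": ["g0"]}
        )
        assert assignment[0] == "epidermal"
        assert report["ties"] and report["ties"][0]["cluster"] == 0

    def test_absent_marker_skipped(self):
        counts = np.array([[4, 1], [1, 4]])
        ds = make_toy_dataset(counts, clusters=[0, 1])
        ds = preprocess.log_normalize(ds)
        _, _, report = preprocess.annotate_clusters(
            ds, {"guard": ["g0", "missing_gene"]}
        )
        assert "missing_gene" in report["skipped_markers"]
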