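"""Shared fixtures: simulated datasets (session-scoped, seeded) and a toy
dataset builder for closed-form examples."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from triadsc import preprocess
from triadsc.core_io import AnalysisThresholds, Dataset, ExpressionMatrix
from triadsc.synthetic import SimulationConfig, simulate_dataset


def make_toy_dataset(
    counts,
    gene_ids=None,
    barcodes=None,
    cell_types=None,
    conditions=None,
    clusters=None,
    samples=None,
    tissues=None,
    subgenomes=None,
    syntelog_groups=None,
    families=None,
    thresholds=None,
) -> Dataset:
    """Build a small Dataset from a dense genes x cells count array."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    barcodes = barcodes or [f"c{i}" for i in range(n_cells)]
    cells = pd.DataFrame(
        {
            "sample_id": samples or ["S1"] * n_cells,
            "tissue": tissues or ["leaf"] * n_cells,
            "condition": conditions or ["control"] * n_cells,
            "cluster_id": pd.array(
                clusters if clusters is not None else [0] * n_cells, dtype="Int64"
            ),
            "cell_type": cell_types if cell_types is not None else [None] * n_cells,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    genes = pd.DataFrame(
        {
            "subgenome": subgenomes if subgenomes is not None else [pd.NA] * n_genes,
            "syntelog_group": syntelog_groups
            if syntelog_groups is not None
            else [pd.NA] * n_genes,
            "at_ortholog": [pd.NA] * n_genes,
            "family": families if families is not None else [pd.NA] * n_genes,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return Dataset(
        matrix=ExpressionMatrix(sp.csr_matrix(counts), gene_ids, barcodes),
        cells=cells,
        genes=genes,
        thresholds=thresholds or AnalysisThresholds(),
    )


def _prep(cfg):
    ds, truth = simulate_dataset(cfg)
    ds, _ = preprocess.qc_filter_cells(ds)
    return preprocess.log_normalize(ds), truth


@pytest.fixture(scope="session")
def sim_default():
    """Default-condition simulation (both conditions), QC'd and normalized."""
    return _prep(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def control_ds(sim_default):
    """The control-condition atlas cells of the default simulation."""
    ds, truth = sim_default
    return ds.subset_cells((ds.cells["condition"] == "control").to_numpy()), truth


@pytest.fixture(scope="session")
def heat_table(sim_default):
    from triadsc import heat_response

    ds, truth = sim_default
    return heat_response.heat_deg_table(ds), truth


@pytest.fixture(scope="session")
def dominance_sim():
    """Simulation with a strong planted dominance effect, plus its calls."""
    from triadsc import subgenome

    ds, truth = _prep(SimulationConfig(seed=12, delta_dom=1.5))
    control = ds.subset_cells((ds.cells["condition"] == "control").to_numpy())
    calls = subgenome.dominance_calls(control)
    return control, truth, calls


@pytest.fixture(scope="session")
def marker_calls(control_ds):
    from triadsc import markers

    ds, truth = control_ds
    return markers.cluster_enriched_genes(ds), truth
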