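# triadsc

Single-cell expression analysis for a whole-genome-triplicated crop
genome (*Brassica rapa*-style): cell-type marker calling, subgenome
expression-dominance classification over syntelog groups, and
per-cell-type heat-stress differential expression — together with a
seeded synthetic-data generator that emulates the structure of a 10x
leaf/shoot scRNA-seq experiment and emits ground truth for recovery
testing.

## The scientific problem

*Brassica rapa* carries three homoeologous subgenomes from an ancestral
whole-genome triplication: the least, medium and most fractionated
subgenomes (LF, MF1, MF2), plus a large set of ungrouped genes (UG) with
no syntenic *Arabidopsis* ortholog. Each ancestral gene survives as a
syntelog group of 1–3 retained copies, at most one per subgenome. Two
questions drive the analyses here:

1. **Subgenome dominance at cellular resolution.** Within a cell type,
   is one homoeologous copy of a syntelog group expressed significantly
   above its partners? A copy *c* is called predominant in cell type *t*
   when it is detected in ≥ 5% of the type's cells and, against every
   other copy *o* of its group, log₂FC(*c*, *o*) ≥ 0.36 (1.28-fold) with
   p ≤ 0.05 (paired Wilcoxon signed-rank over the same cells — the
   copies are measured in identical cells, so pairing is the natural
   design).

2. **Cell-type-specific heat response.** Comparing heat-stressed to
   control cells within each cell type, a gene is a DEG when |log₂FC| ≥
   0.36, p < 0.05 and it is detected in > 25% of the type's cells. DEG
   sets are partitioned by the exact subset of cell types involved:
   genes shared by all types, genes specific to exactly one type (heat
   response markers), and genes with *opposite* directions in different
   types.

## The statistical core

Fold changes follow the Seurat convention on log-normalized values
`x = ln(1 + c·s/total)` with scale `s = 10⁴`:

    log2FC = log2(mean(expm1(x_a)) + 1) − log2(mean(expm1(x_b)) + 1)

Differential expression uses a two-part hurdle test in the spirit of
MAST: a G-test (likelihood ratio) on the 2×2 detection table
(expressed/not × group), plus a Welch t-test on the positive values
converted to a 1-df deviance through the normal-quantile transform of
its two-sided p. The two deviances add, and the total is referred to a
χ² with df equal to the number of parts the data support (detection
tables with a smallest expected cell count below 1 carry no usable
likelihood-ratio information and are treated as degenerate). On a
negative-binomial null (n = 100 per group, 2,000 replicates) the
empirical type-I error at α = 0.05 is ≈ 0.05; the combined p tracks a
10,000-permutation p within 0.02 at the package's operating scale.

Multiple testing uses Benjamini–Hochberg; the signed-rank test
enumerates its exact null (ties included, via midranks) for up to 25
nonzero differences.

## Worked example

```python
from triadsc import SimulationConfig, simulate_dataset
from triadsc import preprocess, subgenome, heat_response

ds, truth = simulate_dataset(SimulationConfig(seed=1))
ds, qc_report = preprocess.qc_filter_cells(ds)
ds = preprocess.log_normalize(ds)

control = ds.subset_cells((ds.cells["condition"] == "control").to_numpy())
expressed = {t: subgenome.expressed_genes(control, t)
             for t in ("mesophyll", "guard")}
props = subgenome.subgenome_proportions(control, expressed)

degs = heat_response.heat_deg_table(ds)
part = heat_response.deg_partition(degs)
shift = heat_response.umi_shift_test(ds, "mesophyll")
```

prints (via the accessors shown in `scripts/acceptance.py`):

```
1900 genes x 2000 cells after QC (0 cells removed)
mesophyll expressed-gene proportions: {'LF': 0.36, 'MF1': 0.3, 'MF2': 0.253, 'UG': 0.087}
heat DEGs per type: {'epidermal': 318, 'guard': 314, 'mesophyll': 323, 'proliferating': 325, 'vascular': 315}
shared across all 5 types: 148 up, 91 down
mesophyll UMI medians: control 4790 -> heat 3722 (p = 9.72e-10)
```

Reading the output: expressed-gene proportions recover the planted
LF > MF1 > MF2 > UG retention/silencing structure; the heat DEG tables
recover the planted shared sets (150 up / 92 down across all five cell
types); and the per-cell UMI shift shows the planted ~0.8× depression
of transcriptional output under heat, which spares proliferating cells.

A command-line interface mirrors the library
(`triadsc simulate|qc|normalize|composition|annotate|markers|dominance|heat|run`);
`triadsc run --config cfg.yaml` executes a configured end-to-end
pipeline and writes a machine-readable `report.json`.

## Layout

- `triadsc.core_io` — domain types, thresholds, MatrixMarket/TSV I/O
- `triadsc.synthetic` — the generative model and ground truth
- `triadsc.preprocess` — QC, LogNormalize, composition, correlation, annotation
- `triadsc.de_stats` — fold change, hurdle test, signed-rank, BH
- `triadsc.markers` — cluster-enriched genes and cell-type markers
- `triadsc.subgenome` — expressed sets, proportions, dominance calls
- `triadsc.heat_response` — per-type DEGs and derived partitions
- `triadsc.pipeline` / `triadsc.cli` — orchestration and CLI

See `docs/methods.md` for the model, its assumptions and limitations.
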