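# Methods

## Overview

`triadsc` implements three linked analyses of single-cell expression in
a whole-genome-triplicated (WGT) genome with subgenomes LF, MF1, MF2
(least/medium/most fractionated) and an ungrouped (UG) gene set:
cell-type marker calling, predominant-expression (dominance)
classification within syntelog groups, and per-cell-type heat-stress
differential expression. Because the analyses are threshold-driven, all
cutoffs live in one `AnalysisThresholds` object; every caller re-checks
its own gates, so a reported call always satisfies them.

## Preprocessing

Cells are kept when their total UMI count lies in [500, 50000] and
their detected-gene count in [200, 10000]. Both bounds are inclusive:
the removal rule is stated as strictly-greater / strictly-lower, so a
cell sitting exactly on a bound survives. QC is idempotent.

Normalization is LogNormalize: `x = ln(1 + c·s / total_cell)` with
scale s = 10,000 and the natural logarithm (the convention that the
method's name implies; exact inversion back to per-cell proportions is
a tested closed form). Cluster composition rescales each sample to
10,000 cells and tests shoot/leaf enrichment per cluster with a 2×2
Fisher exact test on raw counts, BH-adjusted across clusters (the
adjustment is our addition; raw p-values are also reported). Cluster
annotation scores each cell type as the mean over its known markers of
the cluster's z-scored mean expression and assigns the argmax when
positive — a deliberately simple mechanical stand-in for manual
annotation; ties break lexicographically and are recorded.

## The hurdle test

Single-cell expression is modelled in two parts: detection (is the gene
observed in a cell at all) and abundance given detection.

* Detection: G-statistic (likelihood ratio) on the 2×2 table of
  (value > 0) × group, 1 df.
* Continuous: Welch two-sample t on the positive values, converted to a
  1-df deviance as z² with z = Φ⁻¹(1 − p/2).

The deviances add and the total is referred to χ² with df equal to the
number of parts the data support. A part is unavailable when degenerate:
the continuous part needs at least two positive values per group; the
detection part needs a non-constant indicator *and* a table dense
enough for the chi-square reference (Cochran-style rule: smallest
expected cell count ≥ 1). With no usable part the p-value is 1.

Compared to a full MAST fit this omits the cellular-detection-rate
covariate and the GLM machinery; the deviance-additive combination with
adaptive df is dependency-free and its operating characteristics are
measured directly: on a negative-binomial null (mean 1.5, dispersion
0.5, n = 100 per group, 2,000 replicates) the empirical α at 0.05 is
≈ 0.05, and the combined p agrees with a 10,000-permutation p of the
same statistic to within 0.02 at that sample size. A known small-sample
limitation: with n ≈ 15 per group and a sparse detection table, the
permutation null of the combined statistic has discrete atoms of mass
0.1–0.3, so *any* continuous reference distribution deviates from the
exact conditional null by up to ~0.2 in the CDF mid-range. This is a
property of chi-square approximations on low-count tables, not of the
implementation; at the sample sizes the pipeline operates on (hundreds
of cells per group) the atoms are negligible.

Fold changes follow the Seurat convention
`log2(mean(expm1(x_a)) + 1) − log2(mean(expm1(x_b)) + 1)`, which is
antisymmetric and maps the 0.36 / 0.5 thresholds to 1.28-fold /
1.41-fold ratios.

The paired signed-rank test (used for dominance) drops zero
differences, enumerates the exact sign-flip null by dynamic programming
over doubled midranks (so ties are handled exactly) for up to 25
nonzero differences, and otherwise uses the normal approximation whose
variance term absorbs the tie correction via midranks. No continuity
correction is applied.

## Marker calling

Cluster-enriched genes: cluster vs all other cells, hurdle p BH-adjusted
within the cluster; called at pct_cluster ≥ 0.25, log2FC > 0.36
(one-sided — enrichment means higher in the cluster), q ≤ 0.01.
Cell-type markers: log2FC > 0.5 vs all other cells, raw p ≤ 0.01,
pct_target ≥ 0.25 and pct < 0.25 in *each* other type individually.
The q-vs-raw-p asymmetry between the two callers reproduces the two
stated rules verbatim; `use_adjusted` and a pooled-rest exclusivity
variant are available for harmonization. The per-type exclusivity
reading makes marker sets provably disjoint across types.

## Subgenome dominance

Expressed genes per cell type: nonzero raw counts in ≥ 5% of the type's
cells (boundary inclusive). Dominance within a multi-copy syntelog
group and cell type: copy c wins iff it is expressed (≥ 5%) and beats
every other copy with log2FC ≥ 0.36 at signed-rank p ≤ 0.05. The
fold-change requirement is antisymmetric, so at most one copy can win.
Design choices made where the procedure was genuinely open: the 5%
gate applies to the candidate winner only (the losing copy may be
rare); p-values are used raw (BH optional); the numeric 0.36 threshold
is used rather than a literal two-fold rule; counts are reported per
syntelog group (one event per group), not per gene. The hurdle test can
replace the signed-rank via `test="hurdle"`.

## Heat-stress differential expression

Within each cell type, heat vs control with the hurdle test; a DEG
requires |log2FC| ≥ 0.36, raw p < 0.05 and detection in > 25% of the
type's cells *pooled across conditions* (the expressed-fraction rule
names the type's cells without a condition split; pooling is the
neutral reading). Direction is the sign of log2FC (heat minus control).
Derived views are pure set algebra over the per-type DEG tables: the
exact subset partition per direction, shared-in-all sets, one-type-only
heat markers, and opposite-pattern genes (up in ≥ 1 type and down in
≥ 1 other). The per-cell UMI shift is a two-sided Wilcoxon rank-sum on
per-cell totals; reference-gene stability flags any reference gene
appearing in any DEG table (absent genes are untestable, not failed).

## The synthetic-data generator

The generator emulates the structure the analyses assume — it is the
package's stand-in for a real 10x leaf experiment, with ground truth
for every planted signal.

* **Catalog**: n11 = 300 single-copy groups, n12 = 300 pairs,
  n13 = 200 triplets, n_ug = 400 ungrouped genes. Subgenome assignment
  is LF-biased (singles 0.5/0.3/0.2; pairs {LF,MF1} 0.45, {LF,MF2}
  0.35, {MF1,MF2} 0.20), so LF holds the most genes, as fractionation
  left it in the real genome.
* **Rates**: one baseline rate per syntelog group, shared by its
  copies, LogNormal(ln 0.5, 1) on an expected-counts-per-10k scale
  (per-gene for UG). Sharing encodes the common regulatory heritage of
  homoeologs; planted dominance is the deviation from it. 80% of UG
  genes are silenced (×0.01), reproducing the observation that the
  ungrouped set is large but rarely expressed.
* **Dominance**: 30% of multi-copy groups get a dominant copy chosen
  LF-biased (0.6/0.25/0.15) and boosted 2^δ (δ = 1 by default).
* **Markers**: 30 genes per cell type boosted 2^β (β = 2) in that
  type's cells only. Markers are placed outside multi-copy groups so
  the two planted axes of variation (cell identity, homoeolog
  dominance) stay orthogonal.
* **Heat**: 150 shared-up and 92 shared-down genes across all types,
  50 type-specific genes per type (random sign), 20 opposite-pattern
  genes (up in one type, down in another), all scaled 2^±γ (γ = 1) in
  heat cells of the affected types. Heat also multiplies every cell's
  library-size target by 0.8 — except proliferating cells (1.0),
  reproducing the observed depression of transcriptional output that
  spares proliferating cells.
* **Counts**: library sizes LogNormal(ln 5000, 0.4) clipped to
  [500, 50000]; per-gene rates renormalized within each cell so the
  library size, not the catalog, sets depth; counts negative binomial
  with variance μ + φμ² (φ = 0.5; Poisson at φ = 0).

Planted marker and heat genes are drawn from genes whose baseline rate
is ≥ 0.25 per 10k. The floor is set by the binding detectability gate:
a *down*-regulated heat gene must still be detected in > 25% of the
type's cells pooled across conditions, which at the default library
size and dispersion requires a baseline rate of roughly 0.2; 0.25 adds
margin. Signal planted below this floor would be undetectable by
construction under the stated calling rules, making recovery metrics
meaningless. Heat-set components are allocated across subgenomes in
proportion to the eligible pool sizes (largest-remainder rounding), so
the catalog's LF bias is mirrored in the planted heat sets by
construction rather than only in expectation.

A single RNG stream is consumed in the documented step order (catalog,
rates, dominance, markers, heat sets, library sizes, counts); one seed
reproduces the dataset bit-exactly within this implementation.

**What the generator does not model**: doublets, ambient RNA, batch
effects, UMI collisions, gene–gene correlation beyond the shared group
rates, per-subgenome *expression-level* bias beyond dominance and
retention, and cluster-vs-cell-type mismatch (simulated cluster labels
are the true types). Passing recovery tests therefore demonstrates that
the calling rules recover the planted structure under idealized
labelling and noise — not that they would do so at the same rates on
real droplet data.

## Problem sizes and evaluation conditions

Analyses of the atlas kind (markers, dominance, subgenome proportions)
are evaluated on the control-condition cells of a default simulation,
mirroring the study design in which the cell atlas is built from
unstressed samples and the heat comparison is a separate contrast. The
default simulation is 1,900 genes × 2,000 cells (5 cell types × 2
conditions × 200 cells); dominance recovery is additionally run at
δ = 1.5 and at δ = 0 (null), marker calling at β = 0 (null). The full
test suite and the acceptance script each complete in well under two
minutes on one CPU at these sizes.

## Numerical notes

* BH adjustment is the textbook step-up with monotonicity enforcement,
  order-preserving, cross-checked against statsmodels.
* Welch p-values of exactly zero are clamped at 1e-300 before the
  quantile transform.
* MatrixMarket output is written in row-major nonzero order, so a fixed
  dataset produces byte-identical files; integer field for raw counts,
  real for normalized.
* Ties in `top_markers` and in annotation scores break
  lexicographically on gene_id / cell-type name; the tie is recorded.
* Degenerate inputs fail loudly: zero-total cells in normalization,
  empty groups in fold changes, single-copy groups in dominance,
  zero-cell datasets on write.
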