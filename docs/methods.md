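# Methods

This note documents the statistical procedures the package implements, the
defaults and why they were chosen, what the synthetic cohort generator does
and does not emulate, and the numerical conventions that matter for
reproducibility.

## Data model and preprocessing

`CellDataset` carries a sparse genes × cells integer count matrix, a per-cell
annotation table (donor, condition ∈ {Control, Diabetic, DPN}, major cell
type, neuronal subtype, optional Nageotte score and nodule-adjacency flag)
and a per-gene table. Mitochondrial genes are flagged by the case-sensitive
human symbol prefix `MT-`; duplicate gene symbols on load are suffixed
`.1`, `.2`, … with a warning, and symbols are the primary gene key because
the gene sets and the ligand–receptor database are symbol-based.

QC keeps nuclei with **more than 1,000 detected genes** and **less than 10%
mitochondrial reads** — both inequalities strict, matching the wording of the
filter they implement. A nucleus with zero total counts has an undefined
mitochondrial fraction and is removed under the gene-number criterion.
QC is applied before any other computation and is idempotent.

Log-normalization is `ln(1 + count / total · scale)` with `scale = 1e4`
(natural log; the convention of the standard single-cell toolkits). It is
exactly invariant to scaling a cell's counts by a positive constant.

## Module scoring and the apoptosis trigger score

Module scores use expression-binned control genes: all genes are ranked by
mean log-normalized expression across cells (stable sort) and cut into
`n_bins = 24` near-equal bins (`np.array_split` convention — earlier bins get
the extra gene). For each set gene, `n_ctrl = 100` control genes are drawn
from its bin excluding all set genes — without replacement when the bin pool
is large enough, with replacement otherwise (the binning scheme is
under-specified for small gene universes, and replacement keeps the control
pool size fixed). The score is the per-cell mean over set genes minus the
mean over the pooled control multiset. Defaults mirror the widely used
module-scoring implementation in the standard toolkits; both are exposed.
The draw is fully determined by a seed; set genes are processed in the order
given (deduplicated, absent genes dropped with a warning).

The composite per-nucleus score is

    trigger = apoptosis + p53 + dna_repair + upr − survival

computed elementwise from the five module scores; the identity holds to
1e-12 by construction and is asserted in the tests. The pro-survival module
uses the eleven canonical anti-apoptotic / inhibitor-of-apoptosis genes
(BCL2, BCL2L1, BCL2L2, BCL2A1, MCL1, XIAP, BIRC2, BIRC3, BIRC5, BIRC6,
CFLAR). NF-κB-linked regulators are sometimes grouped with these, but no
canonical printed list exists, so they are not added by default.

**ApopHigh classification.** The threshold is the 90th percentile (linear
interpolation between order statistics — percentile conventions differ, so
the choice is stated) of the trigger score pooled across *all* scored nuclei,
and a nucleus is ApopHigh when its score is **at or above** the threshold.
The pipeline scores neurons only, since apoptosis priming is assessed within
the neuronal compartment; a per-condition threshold is deliberately not
offered because it would silently break cross-condition comparability.
Donor-level ApopHigh proportions are compared across the three conditions
with Kruskal–Wallis, followed by pairwise Wilcoxon rank-sum tests with BH
adjustment; conditions with fewer than two donors are dropped from the
omnibus with a warning.

## Nonparametric kernels

The rank-sum test enumerates the exact permutation distribution of the
rank-sum (dynamic program over subset sums) when both groups have ≤ 10
observations and there are no ties; otherwise it uses the normal
approximation with tie-corrected variance and a 0.5 continuity correction.
Mid-ranks are used for ties everywhere. Degenerate inputs (all values equal)
give p = 1 at the null-mean statistic. Kruskal–Wallis uses the standard
tie-corrected H with a χ²(k−1) reference. Benjamini–Hochberg is the step-up
procedure; NaNs propagate and are excluded from the test count m. BH is
always applied within one analysis family (one DE comparison, one
proportion-test run) — never globally across families.

Dunn's post-hoc test is sometimes paired with Kruskal–Wallis; this package
implements pairwise Wilcoxon + BH as the post-hoc, the variant named in the
procedures it reproduces.

## Proportion testing

For two conditions, per-type composition shifts are measured as
`log2FD = log2((p_b + ε)/(p_a + ε))` with `ε = 1/(2·min(n_a, n_b))`, a
Haldane-style guard that keeps empty classes finite. The permutation test
shuffles condition labels over cells with totals fixed (`n_perm = 1000`) and
reports the add-one two-sided p-value `(1 + #{|perm| ≥ |obs|})/(1 + n_perm)`,
which is never exactly zero. A percentile bootstrap (cells resampled with
replacement within each condition, `n_boot = 1000`) gives the 95% interval.
Significance is the conjunction `p_adj < 0.05` and `|log2FD| > 0.585`; a
laxer magnitude threshold of 0.42 is exposed because both conventions are in
use for coarse vs fine cell-type comparisons.

Cells — not donors — are the permutation unit, matching the design of the
established single-cell proportion-test tool this reproduces. This means the
test treats cells as exchangeable and is anti-conservative with respect to
donor-level pseudo-replication; donor-level inference is provided separately
by the donor-resolved Kruskal–Wallis path in the scoring module. This
mismatch is intentional and should be kept in mind when interpreting
p-values.

The nodule-adjacency arithmetic computes, per neuron type, the mean
within-sample proportion (pooled proportion when no sample IDs exist) in
control, nodule-adjacent DPN, and non-adjacent DPN neurons, and reports fold
changes of the two DPN groups against control with the same ε guard.

## Differential expression

Two transparent engines share the output schema
`gene, log2FC, p, p_adj, pct_a, pct_b, class`:

* **Rank-sum engine** (per cell): p-values from the Wilcoxon rank-sum on
  log-normalized values (vectorized tie-corrected normal approximation;
  groups of ≤ 10 cells fall back to the scalar kernel with its exact path);
  `log2FC = log2((mean expm1 lognorm_b + pc)/(mean_a + pc))` with
  `pc = 1e-9`. Genes all-zero in both groups are retained with p = 1,
  log2FC = 0.
* **NB pseudobulk engine**: counts aggregated per (donor, condition),
  median-of-ratios size factors (rescaled to geometric mean 1; library-size
  fallback when no gene is expressed everywhere), gene dispersion by the
  method of moments from within-condition residuals with an n/(n−2) bias
  factor, shrunk toward the across-gene mean with weight n/(n+4), and a Wald
  test on the condition log-ratio with a delta-method variance.

The published heavyweight DE frameworks (hurdle models, full GLM machinery)
are deliberately not cloned: gene-level results are engine-dependent, every
downstream stage consumes only the schema, and both engines are calibrated in
the acceptance tests (rank-sum: sensitivity ≥ 0.9 and empirical FDR ≤ 0.10 on
planted 2-fold genes at 200 cells/group; NB Wald: type-I error within
[0.02, 0.09] on 6 vs 6 Poisson replicates). Neither engine includes donor as
a covariate at the per-cell level; donor structure enters through the
pseudobulk design instead.

Significance thresholds: `FDR < 0.05` and `|log2FC| > log2(1.33) ≈ 0.415`
(the fold-change threshold is stated as "log(1.33)" in the conventions this
follows without a printed base; base 2 is used so the threshold is
commensurate with log2 fold changes, and the 0.585 variant used for
proportion-style comparisons is exposed). Positive log2FC always means
higher in the second-named condition, and every output table carries its
comparison label to prevent sign drift.

## Interactome

Ligand→receptor records are evaluated per (pair, comparison) over the three
comparisons control↔diabetic, diabetic↔DPN, control↔DPN:

* **C1** ligand DE among non-neuronal DRG cells *or* receptor DE among
  neurons with p_adj < 0.05 in that comparison (a record is emitted for each
  comparison in which C1 holds — the per-comparison reading of "any of the
  three comparisons");
* **C2** ligand and receptor not both significant with opposite log2FC signs
  in that comparison;
* **C3a** receptor pseudobulk log-normalized expression ≥ 0.01 in at least
  one neuronal population (populations pseudobulked then normalized at
  scale 1e4);
* **C3b** receptor expressed in ≥ 5% of all neurons in some condition;
* **C3c** ligand expressed in ≥ 0.1% of all DRG cells in some condition.

Genes absent from a DE table are treated as not differentially expressed
(p_adj = 1) and flagged. The rank score is a reconstruction — the exact
formula behind "derived from the log2 fold-changes, adj. p-values, and
percent expression values" is unprinted — implemented as the product
`s(g) = |log2FC| · (−log10 max(p_adj, 1e-300)) · pct` summed over ligand and
receptor, which uses precisely the three named ingredients and is strictly
monotone in each; it lives in one pluggable function so alternatives can be
swapped. A pair's score is the max over its records; ranking is descending
with lexicographic (ligand, receptor) tie-break, and the top-k export is
unique per pair. The ligand's "source cell type" is the non-neuronal major
type with the highest mean log-normalized ligand expression — a documented
choice, as no formal rule exists.

## Synthetic cohort generator

The generator emulates the *statistical* structure of a three-condition
human-DRG single-nucleus cohort: 14/10/6 donors (Control/Diabetic/DPN),
1,000 nuclei per donor, 2,000 genes; 8 major classes with neurons a small
minority (8%), 22 neuronal subtypes with atlas-style names; gene-wise
negative-binomial counts (gamma–Poisson, common dispersion 0.5 — one knob,
adequate for the rank-based downstream tests) with log-normal relative
abundances (σ = 1) and log-normal per-cell depths (μ = ln 8000, σ = 0.3).
Depth was set so a healthy nucleus detects roughly 1,200–1,700 of the 2,000
genes and passes the >1,000-gene filter, while low-quality nuclei (2% of
cells, depth ×0.1, mitochondrial share inflated from the baseline 5% to 15%)
fail both filters. The 13 human mitochondrial symbols and the 11 survival-
template symbols are real gene names; all else is synthetic (G0001, …).

Five disjoint 20-gene modules (survival = template + padding; apoptosis,
p53, dna_repair, upr) are laid out deterministically. Module genes sit on a
fixed log-spaced abundance ladder (0.7–5.0 relative units, interleaved so
every module spans the same range): signature genes are then well-detected,
planted fold changes act on representative expression levels, and the module
genes spread across several expression-matching bins instead of stacking
into one bin where they would contaminate each other's control pools — a
distortion a 20k-gene transcriptome does not have but a 2,000-gene synthetic
universe otherwise would.

Planted effects are the ground truth for recovery tests: `expression_shift`
multiplies target-gene NB means by `2^log2FC` in selected cells;
`proportion_shift` multiplies a class probability within a condition
(renormalizing the rest, and failing before sampling if the shift leaves
(0,1)). The realized scope of every effect (cells affected, realized
proportions) is recorded in a truth table with no silent clipping. All
sampling flows from one seeded generator in a fixed order — gene abundances,
labels donor by donor, low-quality flags, depths, count blocks — so a cohort
is byte-reproducible from its config and partial regeneration is impossible.

**What the generator does not emulate:** gene–gene correlation, donor batch
effects, condition-dependent depth, spatial structure, and realistic marker
architecture. Passing recovery tests therefore demonstrates that the
*pipeline machinery* detects effects of the planted kind and size under the
stated noise model — not that it would have the same power on real tissue.

## Pipeline, Nageotte strata, determinism

`run_all` executes simulate → QC → normalize → score → proportions → DE →
interactome, writing per-stage TSVs, a manifest (config SHA-256, seed,
package and library versions, cell counts) and a config echo; tables are
written with a fixed float format so reruns with identical config and seed
are byte-identical. No stage mutates its inputs on disk.

Nageotte nodule burden strata follow the 0–5 histological scale: ≤ 2 → Low,
2–4 → Moderate-High, ≥ 4 → High, missing → Unscored. The source bins
(1–2 / 3–4 / 4–5) overlap at 4; the overlap resolves High-wins because
score-4 ganglia are grouped with the severely degenerated samples when they
are excluded from contrasts, and the boundaries are configurable.

## Problem sizes used in the shipped checks

The acceptance tests run 10 default-scale cohorts (30,000 nuclei each) for
the apoptosis-recovery check, 500 null and 100 power simulations (1,000
cells per condition) for the proportion test, 10 seeds × 400 cells for the
rank-sum DE check, 200 Poisson simulations for the NB engine, 10 reduced
cohorts (2,400 nuclei) for interactome recovery, and one default-scale
pipeline run plus two reduced deterministic reruns; these sizes were chosen
as the smallest at which the targeted rates are stable. `scripts/
acceptance.py` reports each quantity with the problem size it used.

## Known limitations

* The proportion permutation test is cell-level (see above); use the
  donor-level tests for population-level claims.
* The NB Wald engine has no outlier handling or fold-change shrinkage;
  with very few replicates its dispersion estimate leans on the across-gene
  mean.
* The interactome score is a documented reconstruction, not a published
  formula; ranks are comparable within a run, not across variants.
* Gene sets are matched by exact symbol; no alias resolution is attempted.
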