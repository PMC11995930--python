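# Methods

## Overview

`atlaswalk` annotates single-cell RNA-seq cells by correlating them against a
reference atlas of cell-type expression profiles and then refining the
per-cell assignments with the cells' own neighbourhood structure, via an
iterative walk over the cuts of a dendrogram. Downstream, it compares two
conditions within a cell type through Wilcoxon differential expression,
preranked gene-set enrichment, a per-cell signature score built from the
enrichment's core genes, and a two-sample Kolmogorov–Smirnov (KS) test on
the score distributions. A ground-truth simulator generates the data the
whole chain is validated on.

## Quality control

Cells are retained when their UMI total is **strictly greater** than
`min_umis` (default 1,000) and their mitochondrial UMI fraction — computed
over genes named with the `mt-` prefix, on the raw, unfiltered gene set —
is **strictly below** `max_mito_frac`. The mitochondrial threshold default
is 0.01, i.e. a 1% fraction; because thresholds of this kind are sometimes
quoted as "0.01%" (the literal fraction 0.0001, which would discard almost
every real cell), the value is configurable and never hard-coded. Genes
detected in fewer than `min_cells_per_gene` cells (default 2, i.e. genes
quantified in only one cell are dropped) are removed after cell filtering.
Detected-genes bounds for putative doublets/dead cells are an open
interval `(low, high)`; because such bounds are inherently a manual
judgement on the detected-genes distribution, the package only *proposes*
quantile candidates (`propose_gene_count_bounds`) and applies bounds solely
when they are set explicitly in the configuration.

Computing the mitochondrial fraction on the raw gene set makes cell and
gene filtering commute whenever the removed genes carry negligible mass.

## Atlas correlation typing

A reference atlas is a list of `(type_name, source, profile)` entries; the
same type may appear under several sources. Before correlating:

- **Homolog translation** re-indexes the atlas into the sample's gene
  space. Several source genes mapping to one target are collapsed by their
  mean; a source gene with several targets contributes its value to each
  (one-to-many duplication); target genes with no homolog are dropped from
  the correlation support.
- **Expression transform.** Cells are library-size normalized to a fixed
  total (default 10,000) and log1p-transformed; `raw` and `rank`
  (Spearman) modes are available. The same transform is applied to the
  atlas profiles (`normalize_atlas`): Pearson correlation between a
  log-scale cell and a linear-scale profile is dominated by the profile's
  few largest values, so both sides are put on the same measurement scale.
  This is a design choice of the package; the transform is configurable.

Per-cell typing computes the Pearson correlation between each (sketched)
cell and each atlas entry over the intersection of the gene spaces
(at least 3 shared genes required), keeps the best correlation per type
name across duplicate entries, and assigns each cell its argmax type (ties
broken by lexicographic type name; zero-variance vectors give undefined
correlations treated as −∞). Types claiming **strictly less** than
`min_type_frac` (default 0.05%) of the sketch cells are pruned and their
cells labelled `ambiguous`; shares are computed over all sketch cells
including the prospective ambiguous ones.

Expensive steps run on a *sketch*: a uniform random subsample of
`sketch_n` cells (default 5,000) drawn per condition with a seed derived
from the root seed.

## Consensus annotation (dendrogram walk)

1. **Marker panel.** For every unordered pair of retained types, a Wilcoxon
   rank-sum test per gene (ambiguous cells excluded; pairs with a type
   under 3 cells skipped); the top 30 genes per pair by ascending p-value
   (ties: larger |log2FC|, then name) are pooled and deduplicated.
2. **Tree.** Cells are embedded in a PCA (default 20 components) of the
   panel genes; each cell's 20 nearest neighbours (self included) define a
   shared-nearest-neighbour similarity — the Jaccard overlap of neighbour
   sets — converted to distance `1 − J` and agglomerated with average
   linkage. `cut(k)` yields nested partitions; parameters are clamped with
   a warning when they exceed the data size.
3. **Walk.** For k = 1, 2, 3, … the tree is cut into k clusters; each
   cluster is assigned the retained type maximizing the 25%-trimmed mean of
   its member cells' correlations (trim removes ⌊trim·n⌋ values from
   *each* tail, the convention of standard trimmed-mean routines; argmax
   ties go to the lexicographically first name; NaN correlations are
   ignored, a type with no finite value scores −∞). A consensus score
   counts consecutive iterations with an unchanged full label vector and
   resets to 0 on any change; the walk stops when the score reaches the
   patience (default 10). Cuts beyond the singleton partition reuse it, so
   the walk terminates within `n_cells + patience` iterations; exceeding an
   explicit `max_iterations` raises with the walk state.
4. **Projection.** A PCA of the panel genes is fitted on the sketch; every
   other cell is projected and takes the majority label among its 5 nearest
   sketch cells, ties resolved by the closest tied neighbour. Provenance
   (`sketch`/`projected`) is recorded per cell.

If pruning retains a single type, the panel/tree/walk are skipped and all
cells receive that type — the walk would be a no-op.

## Condition comparison

To prevent a condition from dominating a within-type comparison, each
target type is *balanced*: the minimum per-condition count is sampled
without replacement from every condition (seeded).

- **Differential expression.** Two-sided Wilcoxon rank-sum per gene between
  the two conditions' cells, reported only for genes expressed in at least
  `min_frac` (default 0.05) of either group. P-values use the tie-corrected
  normal approximation, switching to the exact distribution when the
  combined group size is ≤ 25 and the gene is tie-free. log2FC is
  `log2(mean₁+1) − log2(mean₂+1)` on normalized means (pseudocount 1,
  configurable).
- **Ranking.** Genes sorted by log2FC descending (ties: p ascending, then
  name) — most up- to most down-regulated.
- **Preranked GSEA.** Weighted KS running statistic: hits increment by
  |score|^weight normalized over in-set genes (weight 1 by default; if all
  in-set scores are zero, equal increments), misses decrement by
  1/(N − N_hit). ES is the running-sum value of maximal absolute
  deviation; the *leading edge* (core-enrichment genes) are the in-set
  genes at or before the peak for positive ES, at or after it for negative
  ES. The p-value permutes gene labels (the preranked convention; default
  1,000 permutations, seeded), counting same-sign equal-or-more-extreme
  scores with an add-one correction. The score requires a nonempty, proper
  intersection with the ranked list.
- **Per-cell signature score** over the leading-edge genes: (1) each gene
  divided by its maximum over the scored population (pooled across
  conditions; genes never detected are dropped with a warning), (2) the
  per-cell mean over core genes, (3) rescaled to [0, 1] by
  (x − min)/(max − min). If all per-cell means coincide the rescale is
  undefined and all scores are set to 0 with a warning.
- **KS comparison.** Two-sample KS statistic D = sup |ECDF_A − ECDF_B|
  with the asymptotic two-sided p-value (an exact small-sample mode is
  available). At n = 200 cells/condition the asymptotic p is slightly
  conservative: the measured type-I error at α = 0.05 is ≈ 0.02–0.03.

## Synthetic data generator

The generator emulates a small droplet scRNA-seq experiment with known
truth. Type profiles share a log-normal baseline (σ = 1) with a disjoint
block of marker genes per type (default 10) multiplied by
`2^type_separation`; separation 0 makes all profiles identical, so typing
accuracy at separation 0 measures chance. Defaults describe the validation
conditions used throughout: 4 types × 500 cells, 300 genes, separation 4,
library sizes log-normal with median 5,000 UMIs (σ = 0.35), 5% dropout,
2% doublets, 10 `mt-` genes with a Beta(2, 398) mitochondrial fraction
(mean 0.5%).

Each cell draws its library size, its mitochondrial mass fraction, and then
its counts from a single multinomial whose probability vector allocates the
mitochondrial fraction to `mt-` genes and the rest proportionally to the
(possibly doublet-averaged) type profile — so with zero dropout every
column total equals the drawn library size exactly. Doublets average the
cell's profile with one other type's and keep the first type as the
recorded label, flagged in the truth table (matching removal-by-threshold
rather than labelling). Dropout zeroes each (cell, gene) entry
independently. Two-condition datasets multiply the signature-gene profile
means by `2^shift_log2fc` in condition B before sampling; at shift 0 the
conditions are exchangeable.

All randomness derives from one integer seed through fixed sub-stream
tags, so identical configurations give bit-identical data. What the
generator deliberately does *not* emulate: batch effects, ambient RNA,
cell-cycle structure, gene–gene correlation beyond the type profiles, or
the empirical depth distribution of any particular experiment — passing
tests demonstrate the correctness and calibration of the algorithms under
the stated generative model, not performance on any real dataset.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` use: end-to-end annotation on
2,000 cells (4 types, separation 4, ≤ 2% doublets, sketch of 1,000) with
the accuracy target ≥ 95% on non-doublets and a chance-level check at
separation 0; brute-force equivalence of the walk on datasets of ≤ 12
cells; KS calibration over 500 repetitions at 200 cells/condition (type-I
error in [0.02, 0.08] at α = 0.05; power ≥ 0.9 at a 2-log2FC shift); and a
file-based pipeline determinism check at ~500 cells/condition. These sizes
were chosen as the smallest at which the measured properties are stable.

## Known limitations

- The SNN-dendrogram construction materializes a dense pairwise Jaccard
  matrix; fine for sketches up to ~10⁴ cells, not beyond.
- The GSEA p-value is a gene-permutation p per set; no normalized
  enrichment score or cross-set FDR machinery is provided.
- The per-gene max-normalization in the signature score is computed over
  the pooled population, an interpretation choice; per-condition
  normalization would change the score's meaning.
- The exact Wilcoxon mode requires tie-free values; tied small samples fall
  back to the tie-corrected normal approximation.
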