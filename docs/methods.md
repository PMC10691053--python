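# Methods

This note records the statistical procedures implemented in `cladespace`,
the defaults and why they were chosen, the conventions adopted where a
definition was genuinely open, and what the synthetic-data tests do and do
not demonstrate.

## Feature-space construction

**Counting.** Fragments are counted into features by ≥ 1 bp overlap of the
whole fragment interval, multiplied by the fragment record's count field.
A fragment spanning a feature boundary therefore contributes to both
features. An insertion-site variant (counting only the two Tn5 cut
positions) would be a straightforward extension; whole-fragment overlap
was chosen as the simplest well-defined contract.

**QC.** Cells are filtered first (fraction of features accessible within
[2.5 %, 97.5 %], inclusive bounds), then features (fraction of *remaining*
cells within [1 %, 97.5 %]). The order matters and is part of the
contract: a ubiquitously open cell can push a feature below the feature
threshold once removed. Removing every cell is a hard error, not a
warning, since every downstream stage would be undefined.

**TF-IDF / LSA.** The weighting is
`ln(1 + TF·IDF·1e4)` with `TF_ij = x_ij / Σ_j x_ij` on the binary matrix
and `IDF_j = ln(1 + N_cells / df_j)`. Published workflows differ in
log-placement and scaling constants; this variant (log-scaled, ×10⁴) is
the convention common in chromatin LSI implementations and is fixed here
as a design choice. The truncated SVD returns cell coordinates `U·S`;
signs are fixed so each component's largest-magnitude entry is positive,
making the embedding deterministic. For `k ≥ min(dims)` a dense SVD is
used (only relevant to tiny matrices in tests).

**Depth component.** Every component's Pearson correlation with
ln(total pre-QC fragments) is evaluated; components with |r| ≥ 0.7 are
*flagged* (1-based indices) and excluded from distances rather than
deleted, keeping component numbering stable. On binarized single-cell
chromatin data the leading component almost always tracks depth, which is
why the check always runs. Constant depth leaves r undefined; nothing is
dropped and a warning is logged.

**Clade tree.** Agglomeration uses cosine distances and the ward.D2 rule:
dissimilarities are squared inside the Lance–Williams update and the
square root of the merge cost is the reported height. scipy's
`linkage(method="ward")` applied to a precomputed condensed distance
matrix is algebraically exactly this recurrence; the test suite verifies
it against a naive Lance–Williams implementation to 1e-9. Ward on
non-Euclidean (cosine) dissimilarities is not a variance decomposition —
it is used as a linkage heuristic, which is the established practice this
package follows.

**Cut statistics.** Candidate heights are midpoints between successive
merge heights, one per achievable clade count (capped at 20 by default so
peak calling cannot be driven by pathological over-cutting). At each
height the mean silhouette and Dunn2 are computed **on the same cosine
distances as the tree** (whether to reuse the tree's metric was open; this
choice keeps the statistics and the tree consistent). Conventions:
silhouette of a singleton, or when `a = b = 0`, is 0; Dunn2 with all
singleton clades (zero denominator) is +∞; a height yielding one clade is
recorded with missing statistics. The selected cut maximizes mean
silhouette, with ties broken by higher Dunn2, then fewer clades. A data-
specific "best" height is never hard-coded.

Note one genuine inconsistency in the classical definitions: silhouette
and Dunn2 with the usual leave-self-out within-cluster means are *not*
invariant to duplicating every observation (duplicates add zero
distances). The package keeps the classical definitions, which are the
ones the brute-force oracles in the test suite pin down.

**Peak calling.** The per-clade caller is a self-contained Poisson-fold
pileup caller, not a reimplementation of any external tool: base-level
coverage from the clade's pooled fragments; candidate bases need coverage
≥ `min_fold` (default 4) × the genome-wide mean λ *and* a one-sided
Poisson tail `P(X ≥ cov) < α` (default 0.05) at rate λ; candidate runs
within `merge_gap` (100 bp) merge; runs shorter than `min_width` (50 bp)
are dropped. λ is computed over all chromosome bases including zeros.
The clade-level contract (call per clade, then merge) is the point;
the caller internals are deliberately simple and replaceable.

**Merging.** Peak sets are unioned; overlapping *or book-ended* intervals
merge, and each merged feature records the set of contributing clades.
Merging is idempotent and order-independent (tested by permutation).

## Feature annotation

Categories are assigned by feature **midpoint** with fixed precedence:
promoter ≤ 1 kb upstream of a TSS > promoter 1–10 kb > 5′ UTR > exon >
intron > 3′ UTR > downstream ≤ 3 kb of a TTS > distal intergenic.
Promoter and downstream windows are strand-aware. "Exon" means the coding
part of an exon when a CDS is annotated (UTR categories take the rest);
gene models without a CDS contribute whole exons and no UTR categories.
TSS distances are signed (positive downstream in the gene's direction;
a midpoint exactly on a TSS is downstream at distance 0).

The shuffle baseline repositions every feature uniformly on its own
chromosome, preserving length, overlaps allowed — the simplest null
consistent with random repositioning; per-chromosome feature counts and
lengths are preserved exactly. Enrichment per category uses a 2×2 Fisher
exact test (observed in/out vs pooled shuffles in/out), two-sided by the
standard "sum of table probabilities ≤ observed" rule (relative tie
tolerance 1e-12), BH-adjusted across categories. The Fisher p-value is
computed by direct hypergeometric enumeration and tested against both an
independent `math.comb` enumeration and `scipy.stats.fisher_exact`.

Set overlaps use a minimum single-partner overlap (default 100 bp): an
element is "in both" only if one partner interval alone shares at least
that many bases. Reported percents (genome coverage, reference recovery,
label fractions) are rounded to one decimal, round-half-even.

## Cell typing

Genes are z-scored across cells. Gene `g` has specificity weight
`w_g = 1 / (#types listing g as positive)` (1 if none does); the score of
cell `c` for type `t` is
`(Σ_{g∈pos(t)} w_g z_cg − Σ_{g∈neg(t)} w_g z_cg) / sqrt(|pos|+|neg|)`.
This is a deliberately simplified, fully specified scoring rule in the
spirit of marker-based annotation tools; the exact published formulas of
those tools are not reproduced.

The unknown rule is per cell: label = argmax type only if the max score
strictly exceeds `mean + k·sd` over that cell's type scores, sample sd
(ddof = 1), default `k = 1.3`. Two consequences worth knowing:

* with fewer than 4 types the rule can never label anything, since the
  max of n values is at most `(n−1)/√n` sample standard deviations above
  their mean, and `(n−1)/√n < 1.3` for n ≤ 3;
* cells with two genuinely high scores (dual identities) are pushed to
  `unknown` — a documented limitation, not a bug.

Whether the threshold should pool scores across cells was open; the
per-cell reading was chosen because it is scale-free per cell and matches
the "cell not having score for any defined cell type higher than…"
phrasing of the rule. Argmax ties go to the lexicographically first type
(logged). Composite genes (`g2m`, `s`) are per-cell means of their
members' z-scores, appended as pseudo-genes so a progenitor type defined
by them competes in the same argmax; missing members are skipped with a
warning, a fully absent composite is an error.

Purity is the dataset-wide fraction of cells matching their cluster's
majority label. The Gini index of a gene is the normalized mean absolute
difference of its per-cluster mean expression,
`Σ_ij |x_i−x_j| / (2 n² μ)`; an all-zero vector is undefined (NaN, not 0).

## Cluster analytics

**Communities.** A shared-nearest-neighbor graph (k = 20 cosine
neighbors including self, Jaccard edge weights, pruned below 1/15) is
partitioned by Leiden with the RB-configuration resolution parameter,
seeded. Note the resolution→0 limit collapses to one community only per
connected component; disconnected data stays apart at any resolution.

**Resolution sweep.** For each candidate resolution (default 1–20), 20
subsampled clusterings (80 % of cells) are scored by per-cluster mean
silhouette on cosine distances; a resolution's score is the median of the
pooled per-cluster values, and the *highest* resolution scoring within
0.05 of the best is chosen — favouring the finest statistically supported
partition. The full-data clustering at that resolution provides the
per-cluster mean silhouette used as the cluster "reliability" score
(the alternative reading — label-transfer prediction score — is also
computed by `transfer_labels`, but silhouette is the default gate).

**Label transfer.** Anchor-based modality integration is out of scope; a
simplified stand-in is provided and clearly flagged: ATAC cells are
summarized as gene activities (summed counts over gene body + 2 kb
upstream), both modalities are z-scored per gene, and each ATAC cell takes
the majority label of its k = 25 nearest RNA cells (transfer score =
majority fraction ∈ [1/k, 1]). Downstream contracts depend only on labels
and scores, so a stronger integration can be swapped in.

**Branch enrichment.** For each of the first ≤ 10 branching points from
the root of the cluster tree, and each child branch,
`R = (category share within branch) / (global category share)`; the root
has R = 1 by construction and the identity Σ_cat (global share)·R = 1
holds within every branch (tested by enumeration). R is missing when the
category is globally absent.

**Differential accessibility.** Features accessible in ≥ 5 % of either
group are tested by logistic regression of binary accessibility on group
with ln(total fragments) as covariate; the p-value is a likelihood-ratio
chi-square (df = 1); BH across tested features. Effect size is
`log2((p_A+ε)/(p_B+ε))`, ε = 0.01, on accessible fractions — a centralized
definition chosen because the corresponding external tool's exact formula
is not published; thresholds are |log2FC| > 0.75 and adjusted p < 0.05.
Perfect separation or non-convergence falls back to an L2-penalized fit
whose penalized log-likelihoods feed the same LRT (logged, never a crash);
a constant column short-circuits to p = 1. Swapping the groups negates the
effect size and leaves p-values unchanged to 1e-9 (tested).

**Locus heatmaps.** Features overlapping TSS ± 50 kb are summarized as
cluster-mean accessibility, columns z-scaled (zero-variance columns become
zeros), rows ordered by Euclidean/ward hierarchical clustering and
partitioned by k-means (k ∈ 2..min(10, n−1), 10 restarts, seeded) at the
silhouette-optimal k.

## Synthetic data: what it emulates, and what it does not

The generator plants: several samples of barcoded fragments; cell types
sharing a common open backbone (200 shared sites by default) plus 50
type-private sites each, 500 bp wide, pairwise disjoint by construction;
negative-binomial per-cell depth (mean 500, dispersion 2 — overdispersion
typical of single-cell depth); uniform off-site noise at rate 0.1; and a
matched expression matrix with 5 positive / 2 negative markers per type at
fold 8, housekeeping genes, and cell-cycle genes up-shifted only in
progenitor-flagged cells. Defaults describe a 10 Mb two-chromosome
autosomal genome with 4 types × 100 cells across 3 samples — a desk-scale
analogue of a multi-region embryonic experiment. Sex chromosomes are not
generated.

Not modeled: PCR duplicates (the count field is always 1), doublets,
fragment-length nucleosome structure, batch effects, read-level sequence,
correlated site usage within a cell beyond type membership. Passing the
planted-structure tests therefore shows the pipeline's logic is correct
and recovers clean planted signal at realistic depth and noise; it does
not certify performance on real data with batch structure, doublets or
ambient contamination.

Problem sizes in the test and acceptance runs (4 × 100 cells, 10 Mb
genome, 2 000 features / 200 + 200 cells for DA calibration) were chosen
as the smallest sizes at which the planted effects are comfortably
identifiable; all are parameters of `SyntheticSpec` and scale up directly.

## Known limitations

* The per-clade peak caller is intentionally minimal (no local background
  λ, no fragment-model smoothing); on real data a dedicated caller can be
  substituted per clade without touching the merge contract.
* Gene activity for label transfer ignores distal regulation entirely.
* The annotation precedence resolves multi-gene conflicts by category
  rank, not by distance; a midpoint in one gene's intron that is also
  within 10 kb of another's TSS is "promoter", matching the stated
  precedence but debatable at boundaries.
* Dunn2 is reported as +∞ when all clades are singletons; callers binning
  statistics should handle the infinity.
* The intergenic/genic split can be reported under either convention
  (promoters counted genic or not) via the annotation categories; both
  are derivable from the returned per-feature categories.
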