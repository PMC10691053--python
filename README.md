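# cladespace

Clade-aware open-chromatin feature spaces, marker-based neurotransmitter
typing, and cluster-tree analytics for single-cell ATAC/RNA data.

## The problem

In scRNA-seq the feature set is fixed (the genes); in scATAC-seq it is not —
reads can fall anywhere in the genome, and peaks called on a pooled sample
wash out the open-chromatin sites private to rare cell populations.
`cladespace` implements a pipeline for building a **common feature space
across samples** that preserves population-private signal, and the
downstream statistics used to characterize and validate it. It is aimed at
computational biologists analyzing multi-sample single-cell chromatin
experiments (e.g. several brain regions of a developing embryo) who need
comparable features across all samples plus defensible per-cell typing.

The stages:

1. **Binning and embedding.** Fragments are counted per cell into 5 kb
   genome bins, QC-filtered by fraction of accessible features (cells kept
   with 2.5–97.5 % of features accessible, then features kept if accessible
   in 1–97.5 % of cells), binarized and weighted by TF-IDF:
   `x_ij -> ln(1 + TF_ij * IDF_j * 1e4)` with `TF_ij = x_ij / Σ_j x_ij`,
   `IDF_j = ln(1 + N / df_j)`, followed by truncated SVD (latent semantic
   analysis). Components correlated with log sequencing depth (|r| ≥ 0.7,
   typically the first) are flagged and excluded from all distances.
2. **Cellular clades.** Cells are agglomerated on cosine distances with the
   ward.D2 rule; candidate cut heights are scored by mean silhouette
   `s(i) = (b-a)/max(a,b)` and Dunn2 (min mean between-clade dissimilarity /
   max mean within-clade dissimilarity), and the cut maximizing silhouette
   (ties: higher Dunn2, then fewer clades) defines the clades.
3. **Per-clade peaks, merged.** Peaks are called separately from each
   clade's pooled fragments — so small clades contribute their private
   peaks on equal footing — with a Poisson-fold pileup caller (coverage ≥
   4× the genome-wide mean and one-sided Poisson tail p < 0.05, merged
   within 100 bp, minimum width 50 bp), then merged across clades into the
   common feature set used to re-score every cell.
4. **Clusters and validity.** Communities are found on a shared-nearest-
   neighbor graph (Leiden), with the resolution chosen by a bootstrapped
   per-cluster-silhouette sweep; cluster trees (ward.D2/cosine on mean
   accessibility profiles) are decorated with branch enrichment
   `R = (category share in branch) / (global category share)`.
5. **Per-cell typing.** Cells are scored against positive/negative marker
   genes on z-scored expression (shared markers down-weighted by how many
   types claim them); a cell is labeled with its argmax type only if that
   score exceeds `mean(scores) + 1.3·sd(scores)` across its type scores,
   otherwise `unknown`. Cell-cycle signatures enter as composite genes
   (`g2m`, `s`) so a progenitor type competes in the same argmax. Cluster
   validity is quantified by purity and by the Gini index of per-cluster
   mean expression.
6. **Differential accessibility.** Logistic regression of binary
   accessibility on group membership with ln(total fragments) as covariate
   (likelihood-ratio test, BH correction); features are reported at
   |avg_log2FC| > 0.75 and adjusted p < 0.05, with
   `avg_log2FC = log2((p_A + 0.01)/(p_B + 0.01))` on accessible fractions.

A first-class synthetic-data module generates multi-sample fragment files
and expression matrices with planted cell types (shared + type-private
accessible sites, negative-binomial depth, marker structure), so every
stage can be tested against known ground truth.

## Worked example

```python
from cladespace import (SyntheticSpec, make_genome, simulate_fragments,
                        simulate_expression, run_feature_pipeline,
                        composite_genes, score_types, assign_labels)

spec = SyntheticSpec(seed=1)           # 4 planted types x 100 cells, 10% noise
genome = make_genome(spec)
fragments, truth = simulate_fragments(genome, spec)

res = run_feature_pipeline(fragments, genome, seed=1)
print(f"cut height {res.cut_height:.2f} -> {res.clades.nunique()} clades")
print(f"{len(res.features)} merged features ({len(truth.sites)} sites planted)")

expr = simulate_expression(truth, spec)
markers = truth.marker_table()
labels = assign_labels(score_types(composite_genes(expr, markers), markers), k=1.3)
acc = (labels.to_numpy() == truth.cells["cell_type"].to_numpy()).mean()
print(f"typing accuracy {100*acc:.1f}%")
```

prints

```
cut height 5.87 -> 4 clades
401 merged features (400 sites planted)
typing accuracy 97.5%
```

The clade tree cut recovers exactly the four planted cell types; the merged
feature space reconstructs the 400 planted accessible sites (one pair of
nearby sites merges into a single feature, hence 401); and the marker-based
per-cell typing recovers 97.5 % of true labels, the remainder falling into
`unknown` by the score-threshold rule.

The same stages are available from a shell:

```bash
cladespace synth --config spec.yaml --seed 1 --out fixtures/
cladespace features --fragments sample0=fixtures/fragments_sample0.tsv.gz \
    --chrom-sizes fixtures/chrom_sizes.tsv --genes fixtures/genes.tsv --out fs/
cladespace annotate --features fs/features.bed --chrom-sizes fixtures/chrom_sizes.tsv \
    --genes fixtures/genes.tsv --shuffles 1000 --seed 7 --out enrichment.tsv
cladespace nttype --mtx fixtures/matrix.mtx --barcodes fixtures/barcodes.tsv \
    --genes fixtures/features.tsv --markers markers.yaml --out labels.tsv
```

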