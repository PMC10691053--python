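"""End-to-end driver: fragments -> common feature space -> clusters.

Chains the canonical stages: 5 kb genome binning, fragment counting, QC,
binarization, TF-IDF/LSA, depth-component removal, clade tree with
statistic-guided cut, per-clade peak calling, cross-clade merging,
re-scoring on the merged features, and community detection with a
bootstrapped resolution sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clusters import SweepResult, resolution_sweep
from .embedding import Embedding, drop_depth_component, tfidf_lsa
from .fragments import FragmentSet
from .genome import FeatureSet, GenomeModel, bin_genome
from .matrix import CellFeatureMatrix, binarize, count_matrix, qc_filter, rescore
from .peaks import call_clade_peaks, merge_peaks
from .tree import CladeTree, build_clade_tree, cosine_distances, cut_statistics, select_cut


@dataclass
class FeatureSpaceResult:
    bin_matrix: CellFeatureMatrix
    embedding: Embedding
    tree: CladeTree
    cut_height: float
    clades: pd.Series               # barcode -> clade id
    clade_peaks: list[FeatureSet]
    features: FeatureSet            # merged common feature space
    rescored: CellFeatureMatrix     # QC'd binary matrix on merged features
    rescored_embedding: Embedding
    sweep: SweepResult | None


def embed_binary_matrix(matrix: CellFeatureMatrix, n_components: int = 50,
                        seed: int = 0) -> Embedding:
    """QC'd binary matrix -> depth-corrected LSA embedding."""
    k = min(n_components, min(matrix.X.shape) - 1)
    emb = tfidf_lsa(matrix, n_components=k, random_state=seed)
    return drop_depth_component(emb, matrix)


def run_feature_pipeline(fragments: list[FragmentSet], genome: GenomeModel,
                         bin_width: int = 5000, n_components: int = 50,
                         max_clades: int | None = 20, seed: int = 0,
                         cluster: bool = True,
                         sweep_resolutions=None) -> FeatureSpaceResult:
    """Run the full clade-aware feature-space construction.

    ``max_clades`` caps the clade counts scored during cut selection
    (peaks are called per clade, so pathological over-cutting is avoided);
    set ``cluster=False`` to skip the final community-detection sweep.
    """
    bins = bin_genome(genome, bin_width)
    counts = count_matrix(fragments, bins)
    qcd = qc_filter(counts)
    binary = binarize(qcd)
    emb = embed_binary_matrix(binary, n_components, seed)
    tree = build_clade_tree(emb)
    D = cosine_distances(emb.retained())
    stats = cut_statistics(tree, D, tree.candidate_heights(max_clades=max_clades))
    height, clade_labels = select_cut(stats, tree)
    clades = pd.Series(clade_labels, index=binary.obs.index, name="clade")
    peaksets = []
    for clade_id in np.unique(clade_labels):
        cells = clades.index[clades == clade_id]
        peaksets.append(call_clade_peaks(fragments, cells, genome, clade_id=clade_id))
    merged = merge_peaks(peaksets, genome)
    scored = rescore(fragments, merged)
    scored = qc_filter(scored)
    scored_binary = binarize(scored)
    emb2 = embed_binary_matrix(scored_binary, n_components, seed)
    sweep = None
    if cluster:
        sweep = resolution_sweep(emb2, resolutions=sweep_resolutions, seed=seed,
                                 k_neighbors=min(20, scored_binary.n_cells - 1),
                                 index=scored_binary.obs.index)
    return FeatureSpaceResult(
        bin_matrix=binary, embedding=emb, tree=tree, cut_height=height,
        clades=clades, clade_peaks=peaksets, features=merged,
        rescored=scored_binary, rescored_embedding=emb2, sweep=sweep)
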