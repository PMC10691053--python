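"""Hierarchical clade trees and statistic-guided cut selection.

Cells (or cluster profiles) are agglomerated on cosine distances with the
ward.D2 rule: squared dissimilarities inside the Lance-Williams update and
the square root of the merge cost reported as height.  Cut heights are
scored with mean silhouette and Dunn2, and the cut is chosen where both
statistics support the partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .embedding import Embedding
from .metrics import dunn2, mean_silhouette


@dataclass
class CladeTree:
    """Agglomeration over cells or cluster profiles.

    ``Z`` is a scipy-format linkage matrix (n_leaves - 1 merges with
    non-decreasing heights).
    """

    Z: np.ndarray
    n_leaves: int
    method: str = "ward.D2"
    metric: str = "cosine"

    def __post_init__(self) -> None:
        if self.Z.shape != (self.n_leaves - 1, 4):
            raise ValueError("linkage matrix must have n_leaves - 1 merges")

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]

    def cut(self, height: float) -> np.ndarray:
        """Clade assignment (dense ids from 0) cutting at the given height."""
        return fcluster(self.Z, t=height, criterion="distance") - 1

    def cut_k(self, k: int) -> np.ndarray:
        return fcluster(self.Z, t=k, criterion="maxclust") - 1

    def candidate_heights(self, max_clades: int | None = None) -> list[float]:
        """Midpoints between successive merge heights, one per clade count.

        Yields one representative height for each achievable number of
        clades from 2 up to ``max_clades`` (default: all).
        """
        h = np.sort(self.heights)
        tops = np.concatenate([h, [h[-1] * 1.05 + 1e-12]])
        out = []
        for i in range(len(h)):
            n_clades = self.n_leaves - 1 - i  # cutting just above merge i
            if n_clades < 2:
                continue
            if max_clades is not None and n_clades > max_clades:
                continue
            lo, hi = tops[i], tops[i + 1]
            if hi > lo:
                out.append(float((lo + hi) / 2))
        return sorted(set(out))


def cosine_distances(points: np.ndarray) -> np.ndarray:
    """Square matrix of pairwise cosine distances."""
    return squareform(pdist(points, metric="cosine"), checks=False)


def build_clade_tree(embedding: Embedding | np.ndarray) -> CladeTree:
    """Agglomerate on cosine distances with the ward.D2 rule.

    scipy's ward update applied to a condensed distance matrix is exactly
    the ward.D2 recurrence (squares inside the Lance-Williams update,
    square-rooted merge heights).
    """
    points = embedding.retained() if isinstance(embedding, Embedding) else np.asarray(embedding)
    if points.shape[0] < 2:
        raise ValueError("need >= 2 observations to build a tree")
    condensed = pdist(points, metric="cosine")
    condensed = np.maximum(condensed, 0.0)  # numerical guard
    Z = linkage(condensed, method="ward")
    return CladeTree(Z, points.shape[0])


@dataclass
class CutStatistics:
    """Per-height clade counts with Dunn2 and mean silhouette."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["height", "n_clades", "dunn2", "silhouette"]))

    def valid(self) -> pd.DataFrame:
        return self.table.dropna(subset=["silhouette"])


def cut_statistics(tree: CladeTree, distances: np.ndarray,
                   heights: list[float] | None = None) -> CutStatistics:
    """Score candidate cut heights of a clade tree.

    ``distances`` is the square dissimilarity matrix over the same
    observations the tree was built from (the same cosine distances by
    default).  Heights yielding a single clade are recorded with missing
    statistics.
    """
    if heights is None:
        heights = tree.candidate_heights()
    rows = []
    for h in heights:
        labels = tree.cut(h)
        n_clades = len(np.unique(labels))
        if n_clades < 2:
            rows.append({"height": h, "n_clades": n_clades,
                         "dunn2": np.nan, "silhouette": np.nan})
            continue
        rows.append({
            "height": h,
            "n_clades": n_clades,
            "dunn2": dunn2(distances, labels),
            "silhouette": mean_silhouette(distances, labels),
        })
    return CutStatistics(pd.DataFrame(rows))


def select_cut(stats: CutStatistics, tree: CladeTree) -> tuple[float, np.ndarray]:
    """Pick the cut height maximizing mean silhouette.

    Ties are broken by higher Dunn2, then by fewer clades.  Returns the
    height and the clade assignment at that height.
    """
    valid = stats.valid()
    if valid.empty:
        raise ValueError("no valid cut height (every candidate yields one clade)")
    ranked = valid.sort_values(
        ["silhouette", "dunn2", "n_clades"],
        ascending=[False, False, True], kind="mergesort")
    best = ranked.iloc[0]
    labels = tree.cut(float(best["height"]))
    return float(best["height"]), labels
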