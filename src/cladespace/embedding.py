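"""TF-IDF weighting and latent semantic analysis of binary accessibility.

The embedding treats cells as documents and accessible features as terms:
term frequency is the per-cell fraction of signal in a feature, inverse
document frequency down-weights ubiquitously open features, and a
truncated SVD yields the low-dimensional representation.  Components that
track sequencing depth (typically the first) are flagged and excluded
from downstream distance computations rather than deleted, keeping
component numbering stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .matrix import CellFeatureMatrix

log = logging.getLogger(__name__)


@dataclass
class Embedding:
    """Cells x k real embedding with singular values.

    ``dropped_components`` uses 1-based component numbers (component 1 is
    the leading singular component).
    """

    components: np.ndarray
    singular_values: np.ndarray
    dropped_components: list[int] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def retained(self) -> np.ndarray:
        """Component matrix with depth-flagged columns removed."""
        keep = [i for i in range(self.n_components) if (i + 1) not in self.dropped_components]
        return self.components[:, keep]


def tfidf_transform(matrix: CellFeatureMatrix) -> sp.csr_matrix:
    """log(1 + TF * IDF * 1e4) weighting of a binary accessibility matrix.

    TF_ij = x_ij / sum_j x_ij; IDF_j = ln(1 + N_cells / N_cells_open_at_j).
    """
    X = matrix.X.tocsr().astype(np.float64)
    row_sums = np.asarray(X.sum(axis=1)).ravel()
    if np.any(row_sums == 0):
        bad = matrix.obs.index[row_sums == 0][0]
        raise ValueError(f"cell {bad!r} has no accessible features (run QC first)")
    df = np.asarray((X > 0).sum(axis=0)).ravel()
    with np.errstate(divide="ignore"):
        idf = np.log1p(np.where(df > 0, X.shape[0] / np.maximum(df, 1), 0.0))
    idf[df == 0] = 0.0
    tf = sp.diags(1.0 / row_sums) @ X
    out = tf @ sp.diags(idf)
    out.data = np.log1p(out.data * 1e4)
    return out.tocsr()


def tfidf_lsa(matrix: CellFeatureMatrix, n_components: int = 50,
              random_state: int = 0) -> Embedding:
    """TF-IDF weighting followed by truncated SVD (latent semantic analysis).

    Returns cell coordinates ``U * S`` and the singular values.  Signs are
    fixed so each component's largest-magnitude loading is positive, which
    makes the embedding deterministic.
    """
    weighted = tfidf_transform(matrix)
    n, m = weighted.shape
    k = n_components
    if k >= min(n, m):
        U, s, _ = np.linalg.svd(weighted.toarray(), full_matrices=False)
        U, s = U[:, :k], s[:k]
    else:
        rng = np.random.default_rng(random_state)
        v0 = rng.standard_normal(min(n, m))
        U, s, _ = sp.linalg.svds(weighted, k=k, v0=v0)
        order = np.argsort(s)[::-1]
        U, s = U[:, order], s[order]
    comps = U * s
    # deterministic sign convention
    for j in range(comps.shape[1]):
        col = comps[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            comps[:, j] = -col
    return Embedding(comps, s)


def drop_depth_component(embedding: Embedding, matrix: CellFeatureMatrix,
                         threshold_abs_corr: float = 0.7) -> Embedding:
    """Flag components correlated with log sequencing depth.

    Every component's Pearson correlation with ln(total_fragments) is
    evaluated; components with |r| >= threshold are recorded in
    ``dropped_components`` (1-based) and excluded by :meth:`Embedding.retained`.
    """
    depth = matrix.obs["total_fragments"].to_numpy(dtype=float)
    log_depth = np.log(np.maximum(depth, 1.0))
    if np.std(log_depth) == 0:
        log.warning("constant sequencing depth: no component dropped")
        return Embedding(embedding.components, embedding.singular_values, [])
    dropped: list[int] = []
    for j in range(embedding.n_components):
        col = embedding.components[:, j]
        if np.std(col) == 0:
            continue
        r = np.corrcoef(col, log_depth)[0, 1]
        if abs(r) >= threshold_abs_corr:
            dropped.append(j + 1)
            log.info("component %d correlates with depth (r=%.3f); dropped", j + 1, r)
    return Embedding(embedding.components, embedding.singular_values, dropped)
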