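"""Cell x feature count matrices: counting, QC filtering, binarization.

The matrix rows are barcodes (cells, possibly pooled across samples) and
the columns a :class:`~cladespace.genome.FeatureSet` (genome bins or merged
peaks).  ``obs`` carries per-cell metadata; ``total_fragments`` is fixed at
counting time (row sums of the pre-QC count matrix) and preserved through
QC and binarization so it can later serve as the depth covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .fragments import FragmentSet
from .genome import FeatureSet, overlap_matrix_indices

log = logging.getLogger(__name__)


@dataclass
class CellFeatureMatrix:
    """Sparse cells x features matrix with per-cell metadata."""

    X: sp.csr_matrix
    obs: pd.DataFrame  # indexed by barcode; columns include sample, total_fragments
    features: FeatureSet

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        if self.X.shape[0] != len(self.obs):
            raise ValueError("X rows must match obs")
        if self.X.shape[1] != len(self.features):
            raise ValueError("X columns must match features")

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def copy(self) -> "CellFeatureMatrix":
        return CellFeatureMatrix(self.X.copy(), self.obs.copy(), self.features)


def count_matrix(fragments: list[FragmentSet], features: FeatureSet) -> CellFeatureMatrix:
    """Count fragments per cell per feature (>= 1 bp overlap).

    A fragment spanning several features contributes its ``count`` to each.
    Cells from all samples are concatenated; a barcode seen in more than
    one sample is disambiguated by suffixing the sample id (logged).
    """
    if not features.is_sorted() or not features.is_disjoint():
        raise ValueError("features must be sorted and non-overlapping")
    seen: dict[str, str] = {}
    collide: set[str] = set()
    for fs in fragments:
        for bc in fs.barcodes:
            if bc in seen and seen[bc] != fs.sample:
                collide.add(bc)
            else:
                seen.setdefault(bc, fs.sample)
    if collide:
        log.warning("%d barcodes collide across samples; suffixing sample id", len(collide))

    all_barcodes: list[str] = []
    all_samples: list[str] = []
    bc_index: dict[str, int] = {}
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    totals: dict[int, float] = {}
    for fs in fragments:
        r = fs.records
        bcs = r["barcode"].astype(str)
        if collide:
            bcs = bcs.where(~bcs.isin(collide), bcs + ":" + fs.sample)
        for bc in pd.unique(bcs):
            if bc not in bc_index:
                bc_index[bc] = len(all_barcodes)
                all_barcodes.append(bc)
                all_samples.append(fs.sample)
        cell_idx = bcs.map(bc_index).to_numpy()
        qidx, fidx = overlap_matrix_indices(
            features, r["chrom"].to_numpy(dtype=object),
            r["start"].to_numpy(), r["end"].to_numpy())
        cnt = r["count"].to_numpy()
        rows.append(cell_idx[qidx])
        cols.append(fidx)
        vals.append(cnt[qidx].astype(np.float64))
    n_cells = len(all_barcodes)
    if rows:
        X = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_cells, len(features))).tocsr()
    else:
        X = sp.csr_matrix((n_cells, len(features)))
    obs = pd.DataFrame({"sample": all_samples}, index=pd.Index(all_barcodes, name="barcode"))
    obs["total_fragments"] = np.asarray(X.sum(axis=1)).ravel()
    return CellFeatureMatrix(X, obs, features)


def qc_filter(matrix: CellFeatureMatrix, cell_min_frac: float = 0.025,
              cell_max_frac: float = 0.975, feat_min_frac: float = 0.01,
              feat_max_frac: float = 0.975) -> CellFeatureMatrix:
    """Fraction-based QC: filter cells first, then features (inclusive bounds).

    Cells are kept when the fraction of features they access lies in
    ``[cell_min_frac, cell_max_frac]``; features are then kept when the
    fraction of *remaining* cells accessing them lies in
    ``[feat_min_frac, feat_max_frac]``.
    """
    if matrix.n_cells == 0 or matrix.n_features == 0:
        raise ValueError("qc_filter requires a nonempty matrix")
    B = matrix.X.sign()
    cell_frac = np.asarray(B.sum(axis=1)).ravel() / matrix.n_features
    keep_cells = (cell_frac >= cell_min_frac) & (cell_frac <= cell_max_frac)
    if not keep_cells.any():
        raise ValueError(
            f"QC removed all {matrix.n_cells} cells "
            f"(accessible-fraction range {cell_frac.min():.4f}-{cell_frac.max():.4f})")
    X = matrix.X[keep_cells]
    n_kept = int(keep_cells.sum())
    feat_frac = np.asarray(X.sign().sum(axis=0)).ravel() / n_kept
    keep_feats = (feat_frac >= feat_min_frac) & (feat_frac <= feat_max_frac)
    log.info("qc_filter: kept %d/%d cells, %d/%d features",
             n_kept, matrix.n_cells, int(keep_feats.sum()), matrix.n_features)
    feats = matrix.features
    src = [feats.source[i] for i in np.flatnonzero(keep_feats)] if feats.source else None
    sub = FeatureSet(feats.chrom[keep_feats], feats.start[keep_feats],
                     feats.end[keep_feats], src)
    return CellFeatureMatrix(X[:, keep_feats].tocsr(), matrix.obs.loc[keep_cells].copy(), sub)


def binarize(matrix: CellFeatureMatrix) -> CellFeatureMatrix:
    """0/1 accessibility matrix; per-cell total_fragments metadata kept."""
    return CellFeatureMatrix(matrix.X.sign().tocsr(), matrix.obs.copy(), matrix.features)


def rescore(fragments: list[FragmentSet], common_features: FeatureSet) -> CellFeatureMatrix:
    """Re-count fragments over a merged common feature set.

    Same contract as :func:`count_matrix`; provided as the explicit
    second-pass scoring step once clade peaks have been merged.
    """
    return count_matrix(fragments, common_features)
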