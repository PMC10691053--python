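"""Clustering of cells on the accessibility embedding and downstream
cluster analytics: bootstrapped resolution selection, cross-modality label
transfer, cluster trees with branch enrichment, differential accessibility
with a depth covariate, closest genes and locus heatmaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import leidenalg as la
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import chi2
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

from .embedding import Embedding
from .genome import FeatureSet, GenomeModel
from .matrix import CellFeatureMatrix
from .metrics import benjamini_hochberg, silhouette_samples
from .tree import CladeTree, build_clade_tree, cosine_distances

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# community detection

@dataclass
class ClusterAssignment:
    labels: pd.Series          # cell -> dense cluster id from 0
    resolution: float
    reliability: pd.Series | None = None   # per-cluster mean silhouette

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())


def _points(embedding) -> np.ndarray:
    return embedding.retained() if isinstance(embedding, Embedding) else np.asarray(embedding)


def snn_graph(points: np.ndarray, k_neighbors: int = 20,
              prune: float = 1 / 15) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph with Jaccard weights, pruned."""
    n = points.shape[0]
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be < number of cells")
    nn = NearestNeighbors(n_neighbors=k_neighbors, metric="cosine").fit(points)
    ind = nn.kneighbors(return_distance=False)
    rows = np.repeat(np.arange(n), k_neighbors)
    A = sp.csr_matrix((np.ones(n * k_neighbors), (rows, ind.ravel())), shape=(n, n))
    A = A + sp.eye(n, format="csr")  # each cell neighbors itself
    shared = (A @ A.T).tocoo()
    ksize = k_neighbors + 1
    jac = shared.data / (2 * ksize - shared.data)
    keep = (jac >= prune) & (shared.row != shared.col)
    return sp.csr_matrix((jac[keep], (shared.row[keep], shared.col[keep])), shape=(n, n))


def snn_cluster(embedding, resolution: float, k_neighbors: int = 20,
                seed: int = 0, index=None) -> ClusterAssignment:
    """SNN graph + Leiden modularity community detection.

    ``resolution`` scales the modularity null model (higher -> more,
    smaller communities); the partition is deterministic under ``seed``.
    """
    points = _points(embedding)
    W = sp.triu(snn_graph(points, k_neighbors), k=1).tocoo()
    g = ig.Graph(n=points.shape[0],
                 edges=list(zip(W.row.tolist(), W.col.tolist())),
                 edge_attrs={"weight": W.data.tolist()})
    part = la.find_partition(g, la.RBConfigurationVertexPartition,
                             weights="weight", resolution_parameter=resolution,
                             seed=seed)
    labels = np.asarray(part.membership)
    # dense ids ordered by first occurrence
    _, labels = np.unique(labels, return_inverse=True)
    idx = index if index is not None else pd.RangeIndex(points.shape[0])
    return ClusterAssignment(pd.Series(labels, index=idx, name="cluster"), resolution)


# ---------------------------------------------------------------------------
# resolution sweep

@dataclass
class SweepResult:
    resolution: float
    table: pd.DataFrame
    assignment: ClusterAssignment


def resolution_sweep(embedding, resolutions=None, n_boot: int = 20,
                     subsample: float = 0.8, seed: int = 0,
                     k_neighbors: int = 20, tolerance: float = 0.05,
                     index=None) -> SweepResult:
    """Pick a clustering resolution by a bootstrapped silhouette sweep.

    For each resolution, ``n_boot`` random subsamples are clustered and
    per-cluster mean silhouettes (cosine distances) pooled; a resolution's
    score is the median of that pool.  The chosen resolution is the
    highest one whose score is within ``tolerance`` of the best score —
    favouring finer partitions that remain statistically supported.  The
    full-data clustering at the chosen resolution is returned with
    per-cluster mean silhouette as the reliability score.
    """
    if resolutions is None:
        resolutions = list(range(1, 21))
    resolutions = sorted(resolutions)
    if len(resolutions) < 2:
        raise ValueError("need >= 2 candidate resolutions")
    points = _points(embedding)
    n = points.shape[0]
    rng = np.random.default_rng(seed)
    D_full = cosine_distances(points)
    rows = []
    for res in resolutions:
        pooled: list[float] = []
        n_clusters = []
        for b in range(n_boot):
            sub = rng.choice(n, size=max(int(round(subsample * n)), k_neighbors + 2),
                             replace=False)
            assign = snn_cluster(points[sub], resolution=res,
                                 k_neighbors=min(k_neighbors, len(sub) - 1),
                                 seed=seed + b)
            lab = assign.labels.to_numpy()
            n_clusters.append(assign.n_clusters)
            if assign.n_clusters < 2:
                pooled.append(0.0)
                continue
            sil = silhouette_samples(D_full[np.ix_(sub, sub)], lab)
            for c in np.unique(lab):
                pooled.append(float(sil[lab == c].mean()))
        rows.append({"resolution": res,
                     "median_cluster_silhouette": float(np.median(pooled)),
                     "mean_n_clusters": float(np.mean(n_clusters))})
    table = pd.DataFrame(rows)
    best = table["median_cluster_silhouette"].max()
    ok = table[table["median_cluster_silhouette"] >= best - tolerance]
    chosen = float(ok["resolution"].max())
    assignment = snn_cluster(points, resolution=chosen, k_neighbors=k_neighbors,
                             seed=seed, index=index)
    lab = assignment.labels.to_numpy()
    if assignment.n_clusters >= 2:
        sil = silhouette_samples(D_full, lab)
        rel = {c: float(sil[lab == c].mean()) for c in np.unique(lab)}
    else:
        rel = {c: np.nan for c in np.unique(lab)}
    assignment.reliability = pd.Series(rel, name="reliability")
    return SweepResult(chosen, table, assignment)


# ---------------------------------------------------------------------------
# cross-modality label transfer

def gene_activity(matrix: CellFeatureMatrix, genome: GenomeModel,
                  upstream: int = 2000) -> pd.DataFrame:
    """Per-cell gene activity: summed feature counts over gene body plus
    ``upstream`` bp before the TSS (strand-aware)."""
    spans = genome.gene_spans()
    feats = matrix.features
    cols = {}
    X = matrix.X.tocsc()
    for g in spans.itertuples(index=False):
        s, e = g.start, g.end
        if g.strand == "+":
            s = max(s - upstream, 0)
        else:
            e = e + upstream
        m = (feats.chrom == g.chrom) & (feats.start < e) & (feats.end > s)
        if m.any():
            cols[g.gene_id] = np.asarray(X[:, np.flatnonzero(m)].sum(axis=1)).ravel()
        else:
            cols[g.gene_id] = np.zeros(matrix.n_cells)
    return pd.DataFrame(cols, index=matrix.obs.index)


def transfer_labels(atac_matrix: CellFeatureMatrix, rna_expr, rna_labels,
                    genome: GenomeModel, k: int = 25,
                    ) -> tuple[pd.Series, pd.Series]:
    """Nearest-neighbor label transfer from RNA cells to ATAC cells.

    ATAC cells are summarized as gene activities, both modalities are
    z-scored per gene, and each ATAC cell takes the majority label of its
    ``k`` nearest RNA cells in the shared gene space; the transfer score
    is the majority fraction (in [1/k, 1]).
    """
    activity = gene_activity(atac_matrix, genome)
    rna_genes = list(rna_expr.var_names)
    shared = [g for g in activity.columns if g in set(rna_genes)]
    if not shared:
        raise ValueError("no shared genes between modalities")
    A = activity[shared].to_numpy(dtype=float)
    Xr = rna_expr[:, shared].X
    R = np.asarray(Xr.todense()) if hasattr(Xr, "todense") else np.asarray(Xr, dtype=float)

    def z(M):
        sd = M.std(axis=0)
        sd[sd == 0] = 1.0
        return (M - M.mean(axis=0)) / sd

    A, R = z(A), z(R)
    labels = np.asarray(rna_labels)
    nn = NearestNeighbors(n_neighbors=min(k, R.shape[0])).fit(R)
    ind = nn.kneighbors(A, return_distance=False)
    out_labels = []
    out_scores = []
    for row in ind:
        vals, counts = np.unique(labels[row], return_counts=True)
        j = np.argmax(counts)
        out_labels.append(vals[j])
        out_scores.append(counts[j] / len(row))
    idx = atac_matrix.obs.index
    return (pd.Series(out_labels, index=idx, name="transferred_label"),
            pd.Series(out_scores, index=idx, name="transfer_score"))


# ---------------------------------------------------------------------------
# cluster profiles, trees, branch enrichment

def cluster_profiles(matrix: CellFeatureMatrix, clusters) -> pd.DataFrame:
    """Mean binary accessibility per cluster (clusters x features)."""
    clusters = np.asarray(clusters)
    if len(clusters) != matrix.n_cells:
        raise ValueError("cluster vector must align with cells")
    B = matrix.X.sign()
    uniq = np.unique(clusters)
    profs = np.zeros((len(uniq), matrix.n_features))
    for i, c in enumerate(uniq):
        m = clusters == c
        if not m.any():
            raise ValueError(f"cluster {c} is empty")
        profs[i] = np.asarray(B[m].mean(axis=0)).ravel()
    return pd.DataFrame(profs, index=pd.Index(uniq, name="cluster"),
                        columns=matrix.features.names())


def cluster_tree(profiles: pd.DataFrame) -> CladeTree:
    """ward.D2 / cosine tree over cluster mean-accessibility profiles."""
    if len(profiles) < 2:
        raise ValueError("need >= 2 clusters")
    return build_clade_tree(profiles.to_numpy())


def _leaf_sets(Z: np.ndarray, n: int) -> dict[int, list[int]]:
    sets: dict[int, list[int]] = {i: [i] for i in range(n)}
    for m, (a, b, _, _) in enumerate(Z):
        sets[n + m] = sets[int(a)] + sets[int(b)]
    return sets


def branch_enrichment(tree: CladeTree, clusters, categories,
                      max_splits: int = 10) -> pd.DataFrame:
    """Relative enrichment R of cell categories in the top tree branches.

    ``R = (category share within branch) / (global category share)``; the
    root (all cells) therefore has R = 1 for every category.  The first
    ``max_splits`` branching points from the top of the tree are
    traversed; leaves of the tree are cluster ids in sorted order and
    cells enter branches through their cluster.  R is missing when the
    category is globally absent.
    """
    clusters = np.asarray(clusters)
    categories = np.asarray(categories)
    if len(clusters) != len(categories):
        raise ValueError("clusters and categories must align")
    leaf_ids = np.unique(clusters)
    n_leaves = tree.n_leaves
    if len(leaf_ids) != n_leaves:
        raise ValueError("tree leaves must match cluster ids")
    sets = _leaf_sets(tree.Z, n_leaves)
    cats = np.unique(categories)
    n_total = len(clusters)
    global_counts = {c: int((categories == c).sum()) for c in cats}
    rows = []

    def emit(split_idx, branch_name, leaf_idx_list):
        members = np.isin(clusters, leaf_ids[leaf_idx_list])
        n_branch = int(members.sum())
        for c in cats:
            n_cat = int((categories[members] == c).sum())
            if global_counts[c] == 0 or n_branch == 0:
                R = np.nan
            else:
                R = (n_cat / n_branch) / (global_counts[c] / n_total)
            rows.append({"split": split_idx, "branch": branch_name, "category": c,
                         "R": R, "n_branch": n_branch, "n_category_branch": n_cat})

    emit(0, "root", list(range(n_leaves)))
    n_merges = n_leaves - 1
    for s in range(1, min(max_splits, n_merges) + 1):
        merge = n_merges - s  # splits from the top, root first
        a, b = int(tree.Z[merge, 0]), int(tree.Z[merge, 1])
        emit(s, f"split{s}_left", sets[a])
        emit(s, f"split{s}_right", sets[b])
    return pd.DataFrame(rows)


def select_dominant_clusters(clusters, labels, reliability, target_label,
                             frac: float = 0.75,
                             min_reliability: float = 0.5) -> list:
    """Clusters dominated by a label: strictly > ``frac`` of cells carry
    ``target_label`` and cluster reliability strictly > ``min_reliability``."""
    clusters = np.asarray(clusters)
    labels = np.asarray(labels)
    rel = pd.Series(reliability)
    out = []
    for c in np.unique(clusters):
        m = clusters == c
        share = (labels[m] == target_label).mean()
        if share > frac and float(rel.get(c, np.nan)) > min_reliability:
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# differential accessibility

def _logit_lrt(y: np.ndarray, group: np.ndarray, covar: np.ndarray) -> float:
    """Likelihood-ratio p-value for the group term in
    accessibility ~ group + covariate, with a penalized fallback under
    separation."""
    import statsmodels.api as sm

    if y.min() == y.max():
        return 1.0  # constant accessibility carries no group information
    X_full = np.column_stack([np.ones_like(covar), group, covar])
    X_red = np.column_stack([np.ones_like(covar), covar])
    try:
        with np.errstate(all="ignore"):
            full = sm.Logit(y, X_full).fit(disp=0, maxiter=100)
            red = sm.Logit(y, X_red).fit(disp=0, maxiter=100)
        if not (np.isfinite(full.llf) and np.isfinite(red.llf)):
            raise ValueError("non-finite likelihood")
        stat = 2 * (full.llf - red.llf)
    except Exception:
        # separation or failed convergence: small-ridge penalized fit
        log.debug("penalized fallback for a separated feature")
        from sklearn.linear_model import LogisticRegression

        def pen_ll(X):
            clf = LogisticRegression(C=10.0, max_iter=1000).fit(X, y)
            p = np.clip(clf.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
            return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))

        stat = 2 * (pen_ll(X_full[:, 1:]) - pen_ll(X_full[:, 2:]))
    stat = max(stat, 0.0)
    return float(chi2.sf(stat, df=1))


def da_features(matrix: CellFeatureMatrix, group_a, group_b,
                min_pct: float = 0.05, fc_cut: float = 0.75,
                alpha: float = 0.05, epsilon: float = 0.01) -> pd.DataFrame:
    """Differential accessibility between two cell groups.

    Features accessible in at least ``min_pct`` of either group are tested
    with a logistic regression of binary accessibility on group membership
    with ln(total fragments) as covariate (likelihood-ratio test), BH
    adjusted.  ``avg_log2FC = log2((pA + eps) / (pB + eps))`` on the
    per-group accessible fractions.  The returned table covers all tested
    features; rows passing ``|avg_log2FC| > fc_cut`` and ``p_adj < alpha``
    are flagged ``significant``.
    """
    obs_index = matrix.obs.index
    a_mask = obs_index.isin(group_a)
    b_mask = obs_index.isin(group_b)
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise ValueError("both groups need >= 2 cells")
    sel = a_mask | b_mask
    B = matrix.X.sign().tocsc()[np.flatnonzero(sel)]
    grp = a_mask[sel].astype(float)
    covar = np.log(np.maximum(
        matrix.obs.loc[sel, "total_fragments"].to_numpy(dtype=float), 1.0))
    pA = np.asarray(B[grp == 1].mean(axis=0)).ravel()
    pB = np.asarray(B[grp == 0].mean(axis=0)).ravel()
    tested = np.flatnonzero((pA >= min_pct) | (pB >= min_pct))
    if len(tested) == 0:
        return pd.DataFrame(columns=["feature", "feature_idx", "avg_log2FC",
                                     "pct_a", "pct_b", "p_value", "p_adj",
                                     "significant"])
    log2fc = np.log2((pA[tested] + epsilon) / (pB[tested] + epsilon))
    Bd = B.toarray()
    pvals = np.array([_logit_lrt(Bd[:, j], grp, covar) for j in tested])
    padj = benjamini_hochberg(pvals)
    names = matrix.features.names()
    out = pd.DataFrame({
        "feature": [names[j] for j in tested],
        "feature_idx": tested,
        "avg_log2FC": log2fc,
        "pct_a": pA[tested],
        "pct_b": pB[tested],
        "p_value": pvals,
        "p_adj": padj,
    })
    out["significant"] = (np.abs(out["avg_log2FC"]) > fc_cut) & (out["p_adj"] < alpha)
    return out


def closest_gene(features: FeatureSet, genome: GenomeModel, da: pd.DataFrame,
                 fc_gate: float = 0.7) -> pd.DataFrame:
    """Closest gene for each upregulated DA feature (avg_log2FC > gate).

    Distance is the minimal bp gap between the feature interval and the
    gene span (0 when overlapping); ties go to the gene with the smaller
    span start (logged).
    """
    if not len(genome.genes):
        raise ValueError("genome has no genes")
    spans = genome.gene_spans()
    rows = []
    gated = da[da["avg_log2FC"] > fc_gate]
    for r in gated.itertuples(index=False):
        i = int(r.feature_idx)
        c, s, e = features.chrom[i], int(features.start[i]), int(features.end[i])
        g = spans[spans["chrom"] == c]
        if g.empty:
            rows.append({"feature": r.feature, "gene_id": None, "distance": np.nan})
            continue
        gs = g["start"].to_numpy()
        ge = g["end"].to_numpy()
        # gap between [s,e) and [gs,ge): 0 when overlapping
        d = np.maximum(np.maximum(gs - e, s - ge), 0)
        dmin = d.min()
        cand = np.flatnonzero(d == dmin)
        if len(cand) > 1:
            log.info("feature %s equidistant to %d genes; smallest-start tie-break",
                     r.feature, len(cand))
            cand = cand[np.argsort(gs[cand], kind="mergesort")]
        j = cand[0]
        rows.append({"feature": r.feature, "gene_id": g["gene_id"].iloc[j],
                     "distance": int(dmin)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# locus heatmap

@dataclass
class LocusHeatmap:
    matrix: pd.DataFrame            # clusters x features, column z-scaled
    row_order: list
    row_partition: pd.Series
    k: int


def locus_heatmap(matrix: CellFeatureMatrix, clusters, gene_id: str,
                  genome: GenomeModel, window: int = 50000,
                  seed: int = 0) -> LocusHeatmap | None:
    """Cluster-mean accessibility of features within +-window of a gene TSS.

    Columns are z-scaled (zero-variance columns become zeros), rows are
    ordered by Euclidean/ward.D2 hierarchical clustering and partitioned
    by k-means with k chosen in 2..min(10, n_rows - 1) to maximize the
    mean silhouette (10 restarts per k, seeded).
    """
    g = genome.genes[genome.genes["gene_id"] == gene_id]
    if g.empty:
        raise ValueError(f"gene {gene_id!r} not in genome")
    tss = int(g["tss"].iloc[0])
    chrom = g["chrom"].iloc[0]
    feats = matrix.features
    m = (feats.chrom == chrom) & (feats.start < tss + window + 1) & (feats.end > tss - window)
    if not m.any():
        log.warning("no features within %d bp of %s TSS", window, gene_id)
        return None
    cols = np.flatnonzero(m)
    profiles = cluster_profiles(
        CellFeatureMatrix(matrix.X[:, cols].tocsr(), matrix.obs,
                          FeatureSet(feats.chrom[m], feats.start[m], feats.end[m])),
        clusters)
    Z = profiles.to_numpy()
    sd = Z.std(axis=0)
    mu = Z.mean(axis=0)
    Zs = np.where(sd > 0, (Z - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    scaled = pd.DataFrame(Zs, index=profiles.index, columns=profiles.columns)
    if len(scaled) > 1:
        link = linkage(Zs, method="ward", metric="euclidean")
        order = [scaled.index[i] for i in leaves_list(link)]
    else:
        order = list(scaled.index)
    n_rows = len(scaled)
    best_k, best_score, best_labels = 1, -np.inf, np.zeros(n_rows, dtype=int)
    for k in range(2, min(10, n_rows - 1) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Zs)
        if len(np.unique(km.labels_)) < 2:
            continue
        score = silhouette_score(Zs, km.labels_)
        if score > best_score:
            best_k, best_score, best_labels = k, score, km.labels_
    return LocusHeatmap(scaled, order,
                        pd.Series(best_labels, index=scaled.index, name="partition"),
                        best_k)


def cluster_contingency(assign_a, assign_b) -> pd.DataFrame:
    """Contingency table of two cluster assignments over the same cells."""
    a = pd.Series(assign_a)
    b = pd.Series(assign_b)
    if len(a) != len(b) or not a.index.equals(b.index):
        raise ValueError("assignments must cover the same cells")
    return pd.crosstab(a, b, margins=True)
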