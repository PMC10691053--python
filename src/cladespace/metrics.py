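"""Cluster-validity and inequality statistics.

Conventions used throughout:

* silhouette ``s(i) = (b - a) / max(a, b)``; a cell in a singleton cluster
  gets 0, and ``a = b = 0`` (all points identical) also gives 0;
* Dunn2 = (minimum over cluster pairs of the mean between-cluster
  dissimilarity) / (maximum over clusters of the mean within-cluster
  dissimilarity), singleton clusters contributing within-dissimilarity 0;
* purity = dataset-wide fraction of points matching their cluster's
  majority label;
* Gini = normalized mean absolute difference of a nonnegative vector.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom


def _check_square(D: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if len(labels) != D.shape[0]:
        raise ValueError("labels length must match distance matrix")
    return D, labels


def silhouette_samples(D: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-point silhouette widths from a precomputed distance matrix."""
    D, labels = _check_square(D, labels)
    uniq, inv = np.unique(labels, return_inverse=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("silhouette requires >= 2 clusters")
    n = len(labels)
    sizes = np.bincount(inv, minlength=k)
    # sums of distances from each point to each cluster
    sums = np.zeros((n, k))
    for ci in range(k):
        sums[:, ci] = D[:, inv == ci].sum(axis=1)
    own = sizes[inv]
    s = np.zeros(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(own > 1, sums[np.arange(n), inv] / np.maximum(own - 1, 1), 0.0)
        other = sums / sizes[None, :]
        other[np.arange(n), inv] = np.inf
        b = other.min(axis=1)
        denom = np.maximum(a, b)
        s = np.where((own > 1) & (denom > 0), (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
    return s


def mean_silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    return float(silhouette_samples(D, labels).mean())


def dunn2(D: np.ndarray, labels: np.ndarray) -> float:
    """Minimum mean between-cluster over maximum mean within-cluster dissimilarity."""
    D, labels = _check_square(D, labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Dunn2 requires >= 2 clusters")
    members = [np.flatnonzero(labels == u) for u in uniq]
    max_within = 0.0
    for idx in members:
        if len(idx) > 1:
            sub = D[np.ix_(idx, idx)]
            mean_within = sub.sum() / (len(idx) * (len(idx) - 1))
            max_within = max(max_within, mean_within)
    min_between = np.inf
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            min_between = min(min_between, D[np.ix_(members[i], members[j])].mean())
    if max_within == 0.0:
        return np.inf
    return float(min_between / max_within)


def purity(clusters, labels) -> float:
    """Fraction of points matching the majority label of their cluster."""
    clusters = np.asarray(clusters)
    labels = np.asarray(labels)
    if len(clusters) != len(labels):
        raise ValueError("clusters and labels must align")
    if len(clusters) == 0:
        raise ValueError("empty clustering")
    total = 0
    for c in np.unique(clusters):
        sub = labels[clusters == c]
        _, counts = np.unique(sub, return_counts=True)
        total += counts.max()
    return float(total / len(clusters))


def gini(values) -> float:
    """Gini index of a nonnegative vector: sum |x_i - x_j| / (2 n^2 mu).

    Returns NaN for an all-zero vector (undefined inequality).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("gini expects a 1-D vector")
    if np.any(x < 0):
        raise ValueError("gini requires nonnegative values")
    mu = x.mean()
    if mu == 0:
        return float("nan")
    n = len(x)
    xs = np.sort(x)
    # sum_{i<j} (x_j - x_i) via the sorted prefix identity
    diffsum = 2.0 * float(np.sum((2 * np.arange(1, n + 1) - n - 1) * xs))
    return float(diffsum / (2 * n * n * mu))


def fisher_exact_2x2(table, tie_rel_tol: float = 1e-12) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 contingency table.

    Computed by direct hypergeometric enumeration: the p-value is the sum
    of probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (up to a relative tie
    tolerance).  Returns ``(odds_ratio, p_value)`` with the conditional
    sample odds ratio (inf/nan conventions as in the common implementations).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 nonnegative")
    a, b = t[0]
    c, d = t[1]
    n = a + b + c + d
    if n == 0:
        return float("nan"), 1.0
    row1 = a + b
    col1 = a + c
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    probs = hypergeom.pmf(support, n, row1, col1)
    p_obs = hypergeom.pmf(a, n, row1, col1)
    p = float(probs[probs <= p_obs * (1 + tie_rel_tol)].sum())
    p = min(p, 1.0)
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return float(odds), p


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
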