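"""Marker-based per-cell neurotransmitter typing and validity metrics.

Each cell is scored against every neurotransmitter type from positive and
negative marker genes on z-scored expression, with marker specificity
weights (a gene claimed as positive by several types counts less).  A
cell whose best score does not exceed the per-cell threshold
``mean(scores) + k * sd(scores)`` (sample sd, default k = 1.3) is labeled
``unknown`` — which is where e.g. glial cells land when no glial markers
are curated.  Cell-cycle phase signatures (g2m, s) enter as composite
pseudo-genes so a progenitor type can compete in the same argmax.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from anndata import AnnData

from .metrics import gini, purity  # noqa: F401  (re-exported validity metrics)

log = logging.getLogger(__name__)

UNKNOWN = "unknown"


@dataclass
class MarkerTable:
    """Cell type -> positive/negative marker genes, plus composite genes."""

    positive: dict[str, list[str]]
    negative: dict[str, list[str]] = field(default_factory=dict)
    composites: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, pos in self.positive.items():
            neg = set(self.negative.get(t, []))
            both = neg & set(pos)
            if both:
                raise ValueError(f"genes {sorted(both)} both positive and negative for {t!r}")

    @property
    def types(self) -> list[str]:
        return list(self.positive)

    @classmethod
    def from_yaml(cls, path) -> "MarkerTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(positive={t: list(v.get("positive", [])) for t, v in raw["types"].items()},
                   negative={t: list(v.get("negative", [])) for t, v in raw["types"].items()},
                   composites={k: list(v) for k, v in raw.get("composites", {}).items()})

    def to_yaml(self, path) -> None:
        raw = {"types": {t: {"positive": self.positive[t],
                             "negative": self.negative.get(t, [])}
                         for t in self.positive},
               "composites": dict(self.composites)}
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh)


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _dense(expr: AnnData) -> np.ndarray:
    X = expr.X
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X, dtype=float)


def composite_genes(expr: AnnData, markers: MarkerTable) -> AnnData:
    """Append one pseudo-gene per composite: the per-cell mean of its
    members' z-scored expression.  Members missing from the matrix are
    logged and skipped; a composite with no present member is an error.
    """
    if not markers.composites:
        return expr
    X = _dense(expr)
    Z = _zscore(X)
    var_index = {g: i for i, g in enumerate(expr.var_names)}
    new_cols = []
    new_names = []
    for name, members in markers.composites.items():
        present = [var_index[g] for g in members if g in var_index]
        missing = [g for g in members if g not in var_index]
        if missing:
            log.warning("composite %s: members %s missing, skipped", name, missing)
        if not present:
            raise ValueError(f"composite {name!r} has no member present in the matrix")
        new_cols.append(Z[:, present].mean(axis=1))
        new_names.append(name)
    Xout = np.column_stack([X] + new_cols)
    var = pd.DataFrame(index=list(expr.var_names) + new_names)
    out = AnnData(X=Xout, obs=expr.obs.copy(), var=var)
    return out


@dataclass
class TypeScoreMatrix:
    """Cells x types scores plus per-cell assigned labels."""

    scores: pd.DataFrame  # index = cells, columns = types
    labels: pd.Series | None = None


def score_types(expr: AnnData, markers: MarkerTable) -> TypeScoreMatrix:
    """Score every cell against every marker-defined type.

    Genes are z-scored across cells; gene g gets specificity weight
    ``1 / (number of types listing g as positive)`` (1 when none does);
    the type score is the weighted sum of positive-marker z-values minus
    negative-marker z-values, divided by sqrt(number of contributing
    markers).  Composite pseudo-genes must already be appended.
    """
    X = _dense(expr)
    Z = _zscore(X)
    var_index = {g: i for i, g in enumerate(expr.var_names)}
    pos_claims: dict[str, int] = {}
    for t in markers.types:
        for g in markers.positive[t]:
            pos_claims[g] = pos_claims.get(g, 0) + 1
    cols = {}
    for t in markers.types:
        pos = [g for g in markers.positive[t] if g in var_index]
        neg = [g for g in markers.negative.get(t, []) if g in var_index]
        n_contrib = len(pos) + len(neg)
        if n_contrib == 0:
            log.warning("type %s has no marker present in the matrix; dropped", t)
            continue
        score = np.zeros(X.shape[0])
        for g in pos:
            score += Z[:, var_index[g]] / pos_claims.get(g, 1)
        for g in neg:
            score -= Z[:, var_index[g]] / max(pos_claims.get(g, 0), 1)
        cols[t] = score / np.sqrt(n_contrib)
    if not cols:
        raise ValueError("no type has any marker present")
    return TypeScoreMatrix(pd.DataFrame(cols, index=expr.obs_names))


def assign_labels(scores: TypeScoreMatrix, k: float = 1.3) -> pd.Series:
    """Per-cell label: argmax type, or ``unknown`` below the score threshold.

    The threshold is per cell: mean over that cell's type scores plus
    ``k`` sample standard deviations (ddof=1).  Argmax ties go to the
    lexicographically first type (logged).
    """
    S = scores.scores
    if S.shape[1] < 2:
        raise ValueError("assign_labels requires >= 2 types (sd undefined otherwise)")
    vals = S.to_numpy()
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    threshold = mean + k * sd
    # lexicographic tie-break: scan columns in sorted name order
    order = np.argsort(S.columns.to_numpy())
    sorted_names = S.columns.to_numpy()[order]
    sorted_vals = vals[:, order]
    best = np.argmax(sorted_vals, axis=1)
    ties = (sorted_vals == sorted_vals.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        log.info("%d cells with tied top scores; lexicographic tie-break", int(ties.sum()))
    labels = np.where(sorted_vals[np.arange(len(best)), best] > threshold,
                      sorted_names[best], UNKNOWN)
    out = pd.Series(labels, index=S.index, name="label")
    scores.labels = out
    return out


def label_fraction(labels, target: str) -> tuple[int, int, float]:
    """Count and percent (one decimal) of cells carrying a given label."""
    arr = np.asarray(labels)
    n = len(arr)
    count = int((arr == target).sum())
    pct = round(100.0 * count / n, 1) if n else 0.0
    return count, n, pct


def gene_set_gini(expr: AnnData, clusters, genes: list[str]) -> pd.Series:
    """Per-gene Gini index over cluster-mean expression; mean via ``.mean()``.

    Genes absent from the matrix are skipped; an all-zero gene yields NaN.
    """
    X = _dense(expr)
    var_index = {g: i for i, g in enumerate(expr.var_names)}
    clusters = np.asarray(clusters)
    uniq = np.unique(clusters)
    out = {}
    for g in genes:
        if g not in var_index:
            log.warning("gene %s not in matrix; skipped in Gini", g)
            continue
        col = X[:, var_index[g]]
        cluster_means = np.array([col[clusters == c].mean() for c in uniq])
        out[g] = gini(np.maximum(cluster_means, 0.0))
    return pd.Series(out, name="gini")
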