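"""Correlation-based feature clustering and per-gene representative selection.

Correlated radiomics features are grouped by complete-linkage agglomerative
clustering of the distance ``d(i, j) = 1 - rho_s(i, j)**2`` (squared Spearman
correlation), so monotone transforms and sign flips of a feature do not move
it between clusters.  The dendrogram is cut to ``k`` clusters (default 7) once
per feature table; the cut is independent of mutation status.  For each gene,
one representative per cluster is then chosen: the member with the largest
squared Spearman correlation with that gene's mutation labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FeaturePartition",
    "ReducedFeatureSet",
    "spearman_rho",
    "correlation_distance_matrix",
    "complete_linkage_clusters",
    "select_cluster_representatives",
    "ClusterRepresentativeSelector",
]


@dataclass
class FeaturePartition:
    """A cut dendrogram: feature -> cluster index (1..k) plus merge heights."""

    k: int
    assignment: dict[str, int]
    linkage_heights: np.ndarray

    def members(self, cluster: int) -> list[str]:
        return [f for f, c in self.assignment.items() if c == cluster]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "assignment": dict(self.assignment),
            "linkage_heights": [float(h) for h in self.linkage_heights],
        }


@dataclass
class ReducedFeatureSet:
    """Per-gene representatives: one feature per cluster, ordered by cluster."""

    gene: str
    features: list[str]
    scores: list[float]

    def to_dict(self) -> dict:
        return {"gene": self.gene, "features": list(self.features), "scores": list(self.scores)}


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Binary vectors are handled by the same mid-rank formula.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("degenerate input: constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def correlation_distance_matrix(table: pd.DataFrame) -> np.ndarray:
    """Pairwise distance ``1 - rho_s**2`` between feature columns."""
    X = table.to_numpy(float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    for col in table.columns:
        v = table[col].to_numpy(float)
        if np.all(v == v[0]):
            raise ValueError(f"degenerate feature column {col!r}: zero variance")
    rho = stats.spearmanr(X).statistic
    if np.isscalar(rho):  # spearmanr returns a scalar for 2 columns
        rho = np.array([[1.0, rho], [rho, 1.0]])
    dist = 1.0 - np.asarray(rho) ** 2
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 1.0)
    return dist


def complete_linkage_clusters(
    dist: np.ndarray, k: int, feature_names: list[str] | None = None
) -> FeaturePartition:
    """Cut a complete-linkage dendrogram of ``dist`` to exactly ``k`` clusters.

    Cluster indices are relabelled 1..k by first occurrence in feature order
    so the labelling is stable across runs.
    """
    dist = np.asarray(dist, dtype=float)
    p = dist.shape[0]
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(p)]
    if not 1 <= k <= p:
        raise ValueError(f"k must lie in [1, {p}], got {k}")
    if p == 1:
        return FeaturePartition(1, {feature_names[0]: 1}, np.empty(0))
    Z = linkage(squareform(dist, checks=False), method="complete")
    raw = fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(raw)) != k:
        # maxclust can return fewer clusters only under exact height ties
        raise ValueError(f"could not cut dendrogram into exactly {k} clusters")
    relabel: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for name, c in zip(feature_names, raw):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        assignment[name] = relabel[c]
    return FeaturePartition(k=k, assignment=assignment, linkage_heights=Z[:, 2].copy())


def select_cluster_representatives(
    table: pd.DataFrame, labels: np.ndarray, partition: FeaturePartition
) -> ReducedFeatureSet:
    """Per cluster, the member with the largest squared Spearman correlation
    with the labels; ties go to the lexicographically smallest feature name.
    """
    gene = getattr(labels, "name", "") or ""
    y = np.asarray(labels, dtype=float).ravel()
    if np.all(y == y[0]):
        raise ValueError("degenerate labels: single class")
    missing = [f for f in partition.assignment if f not in table.columns]
    if missing:
        raise ValueError(f"partition features missing from table: {missing}")
    features: list[str] = []
    scores: list[float] = []
    for cluster in range(1, partition.k + 1):
        members = sorted(partition.members(cluster))
        best_name, best_score = None, -1.0
        for name in members:
            score = spearman_rho(table[name].to_numpy(float), y) ** 2
            if score > best_score:
                best_name, best_score = name, score
        features.append(best_name)
        scores.append(best_score)
    return ReducedFeatureSet(gene=str(gene), features=features, scores=scores)


class ClusterRepresentativeSelector(TransformerMixin, BaseEstimator):
    """Reduce a feature table to ``k`` per-gene representative columns.

    ``fit(X, y)`` clusters the columns of ``X`` (complete linkage on
    ``1 - rho_s**2``) — or reuses a precomputed ``partition`` so that every
    gene shares one cut — and picks the member of each cluster with the
    largest squared Spearman correlation with ``y``.  ``transform`` returns
    the representative columns.

    Parameters
    ----------
    k : int, default 7
        Number of clusters, hence of selected features.
    partition : FeaturePartition, optional
        Precomputed cut to reuse; clustering is skipped when given.

    Attributes
    ----------
    partition_ : FeaturePartition
    reduced_ : ReducedFeatureSet
    selected_features_ : list of str
    """

    def __init__(self, k: int = 7, partition: FeaturePartition | None = None):
        self.k = k
        self.partition = partition

    def fit(self, X: pd.DataFrame, y=None) -> "ClusterRepresentativeSelector":
        if y is None:
            raise ValueError("y (binary mutation labels) is required")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, float), columns=[f"x{i}" for i in range(np.asarray(X).shape[1])])
        if self.partition is not None:
            partition = self.partition
        else:
            dist = correlation_distance_matrix(X)
            partition = complete_linkage_clusters(dist, self.k, list(map(str, X.columns)))
        self.partition_ = partition
        self.reduced_ = select_cluster_representatives(X, y, partition)
        self.selected_features_ = list(self.reduced_.features)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "selected_features_")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, float), columns=list(self.feature_names_in_))
        return X[self.selected_features_]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "selected_features_")
        return np.asarray(self.selected_features_, dtype=object)
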