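"""Independent reference implementations used only to cross-check the package.

These deliberately avoid the package's own code paths: logistic fits go
through statsmodels, rank correlations through an explicit mid-rank Pearson
formula, and the subset search through plain enumeration.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import statsmodels.api as sm


def midrank_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation as the Pearson correlation of mid-ranks."""

    def midranks(v: np.ndarray) -> np.ndarray:
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(np.asarray(x, float)), midranks(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def statsmodels_logit(X: np.ndarray, y: np.ndarray):
    """Unpenalized ML logistic fit via statsmodels Newton iterations."""
    design = sm.add_constant(np.asarray(X, float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(np.asarray(y, float), design).fit(disp=0, maxiter=200)
    return float(fit.params[0]), np.asarray(fit.params[1:], float)


def youden_at_threshold(y: np.ndarray, probs: np.ndarray, threshold: float = 0.5) -> float:
    pred = probs >= threshold
    pos = np.asarray(y) == 1
    tp = int(np.sum(pred & pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    fp = int(np.sum(pred & ~pos))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return sens + spec - 1.0


def brute_force_aps(
    X: np.ndarray, y: np.ndarray, names: list[str], threshold: float = 0.5
) -> tuple[tuple[str, ...], float]:
    """Enumerate every non-empty subset, fit with statsmodels, and keep the
    first (fewest features, then lexicographic names) training-Youden argmax."""
    name_col = {n: i for i, n in enumerate(names)}
    best_subset, best_j = None, -np.inf
    ordered = sorted(names)
    for size in range(1, len(ordered) + 1):
        for combo in itertools.combinations(ordered, size):
            cols = [name_col[f] for f in combo]
            intercept, coef = statsmodels_logit(X[:, cols], y)
            probs = 1.0 / (1.0 + np.exp(-(intercept + X[:, cols] @ coef)))
            j = youden_at_threshold(y, probs, threshold)
            if j > best_j:
                best_subset, best_j = combo, j
    return best_subset, best_j


def brute_force_complete_linkage_partitions(dist: np.ndarray, k: int) -> list[set]:
    """All k-partitions reachable by complete-linkage merges, exploring every
    optimal merge choice at every step (handles ties exhaustively)."""
    n = dist.shape[0]

    def cluster_dist(a: frozenset, b: frozenset) -> float:
        return max(dist[i, j] for i in a for j in b)

    results: list[set] = []

    def recurse(clusters: frozenset):
        if len(clusters) == k:
            partition = {fs for fs in clusters}
            if partition not in results:
                results.append(partition)
            return
        pairs = list(itertools.combinations(clusters, 2))
        dists = [cluster_dist(a, b) for a, b in pairs]
        dmin = min(dists)
        for (a, b), d in zip(pairs, dists):
            if d == dmin:
                merged = (clusters - {a, b}) | {a | b}
                recurse(merged)

    recurse(frozenset(frozenset([i]) for i in range(n)))
    return results
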