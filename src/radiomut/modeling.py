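"""Cross-validation resampling, logistic fitting and all-subset search.

The model-building stage mirrors a small-cohort radiogenomics design: the
cohort is split into many random train/test partitions (default 1000 sets of
37 training and 10 testing patients), and for each gene an exhaustive
all-possible-subset logistic regression (APS-LR) over the reduced candidate
features picks the subset maximizing the training-set Youden index
(sensitivity + specificity - 1) at the classification threshold.

Two model-building methods are provided:

* Method 1 repeats the full APS-LR search on every training set and evaluates
  the per-split winner on the matching test set; how often a feature appears
  among the per-split winners is its importance count.
* Method 2 runs APS-LR once on the complete cohort to fix the subset per
  gene, then only re-estimates that model's coefficients on each training set.

Logistic fits use Newton/IRLS vectorized across all splits at once, with a
small ridge fallback (lambda = 1e-4 on standardized slopes) on separation or
non-convergence so every subset yields a comparable finite model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .evaluation import PerformanceRecord, confusion_counts, performance_metrics
from .preprocessing import LogSkewTransformer, ModelingTransformDecision
from .reduction import ReducedFeatureSet

__all__ = [
    "CVSplit",
    "LogisticModel",
    "SubsetSearchResult",
    "Method1Result",
    "Method2Result",
    "make_cv_splits",
    "fit_logistic",
    "evaluate_on_split",
    "aps_lr",
    "run_method1",
    "run_method2",
    "SubsetLogisticRegression",
]

SEPARATION_COEF_BOUND = 15.0  # on standardized predictors
RIDGE_LAMBDA = 1e-4


@dataclass
class CVSplit:
    """One disjoint train/test partition of the cohort indices."""

    train_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class LogisticModel:
    """A fitted logistic regression on raw (untransformed-scale) predictors."""

    features: list[str]
    intercept: float
    coefficients: np.ndarray
    threshold: float = 0.5
    converged: bool = True
    penalized: bool = False

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, len(self.features))
        return expit(self.intercept + X @ self.coefficients)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(int)


@dataclass
class SubsetSearchResult:
    """Winner of one exhaustive subset search."""

    gene: str
    best_subset: tuple[str, ...]
    model: LogisticModel
    train_youden: float
    n_subsets_evaluated: int


@dataclass
class Method1Result:
    """Per-split APS-LR: one search result and one test record per usable split."""

    gene: str
    search_results: list[SubsetSearchResult]
    records: list[PerformanceRecord]
    n_splits_skipped: int
    n_penalized_fits: int
    transform_decisions: list[ModelingTransformDecision] = field(default_factory=list)


@dataclass
class Method2Result:
    """One full-data APS-LR fixing the subset, re-estimated on every split."""

    gene: str
    search: SubsetSearchResult
    split_models: list[LogisticModel]
    records: list[PerformanceRecord]
    n_splits_skipped: int
    n_penalized_fits: int
    transform_decisions: list[ModelingTransformDecision] = field(default_factory=list)


def make_cv_splits(
    n: int,
    n_test: int,
    n_sets: int,
    seed: int,
    labels: np.ndarray | None = None,
    stratify: bool = False,
) -> list[CVSplit]:
    """``n_sets`` independent simple-random train/test partitions.

    Splits are unstratified by default (patients "randomly allocated"); with
    ``stratify=True`` and labels given, the test set keeps the class mix as
    closely as integer counts allow.
    """
    if not 0 < n_test < n:
        raise ValueError(f"n_test must lie in (0, {n}), got {n_test}")
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    splits: list[CVSplit] = []
    if stratify:
        if labels is None:
            raise ValueError("stratify=True requires labels")
        labels = np.asarray(labels).ravel()
        pos = np.flatnonzero(labels == 1)
        neg = np.flatnonzero(labels != 1)
        n_test_pos = int(round(n_test * len(pos) / n))
        n_test_pos = min(max(n_test_pos, 0), min(n_test, len(pos)))
        n_test_neg = n_test - n_test_pos
        for _ in range(n_sets):
            tpos = rng.choice(pos, size=n_test_pos, replace=False)
            tneg = rng.choice(neg, size=n_test_neg, replace=False)
            test = np.sort(np.concatenate([tpos, tneg]))
            train = np.setdiff1d(np.arange(n), test)
            splits.append(CVSplit(train_idx=train, test_idx=test))
        return splits
    for _ in range(n_sets):
        perm = rng.permutation(n)
        splits.append(
            CVSplit(train_idx=np.sort(perm[n_test:]), test_idx=np.sort(perm[:n_test]))
        )
    return splits


# ---------------------------------------------------------------------------
# batched Newton/IRLS


def _irls_batch(
    D: np.ndarray, y: np.ndarray, ridge: float, max_iter: int, tol: float = 1e-9
) -> tuple[np.ndarray, np.ndarray]:
    """Newton iterations on a (B, n, q) design stack; column 0 is intercept.

    The ridge penalty applies to slopes only.  Returns (beta (B, q),
    converged (B,)).
    """
    B, n, q = D.shape
    beta = np.zeros((B, q))
    penalty = np.zeros(q)
    penalty[1:] = ridge
    jitter = np.full(q, 1e-10)
    converged = np.zeros(B, dtype=bool)
    for _ in range(max_iter):
        eta = np.einsum("bnq,bq->bn", D, beta)
        mu = expit(eta)
        w = mu * (1.0 - mu) + 1e-12
        grad = np.einsum("bnq,bn->bq", D, y - mu) - penalty * beta
        H = np.einsum("bnq,bn,bnr->bqr", D, w, D)
        H[:, np.arange(q), np.arange(q)] += penalty + jitter
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        np.clip(step, -10.0, 10.0, out=step)
        beta += step
        converged = np.max(np.abs(step), axis=1) < tol
        if converged.all():
            break
    return beta, converged


def _fit_logistic_batch(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """ML logistic fits across a (B, n, p) stack with ridge fallback.

    Predictors are standardized per batch item internally; the returned
    intercepts (B,) and coefficients (B, p) are on the raw predictor scale.
    """
    B, n, p = X.shape
    if p == 0:
        ybar = y.mean(axis=1)
        return logit(ybar), np.zeros((B, 0)), np.ones(B, bool), np.zeros(B, bool)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True, ddof=1)
    sd[sd == 0] = 1.0
    Xs = (X - mean) / sd
    D = np.concatenate([np.ones((B, n, 1)), Xs], axis=2)
    beta, conv = _irls_batch(D, y, ridge=0.0, max_iter=35)
    separated = np.max(np.abs(beta[:, 1:]), axis=1) > SEPARATION_COEF_BOUND
    bad = ~conv | separated
    penalized = np.zeros(B, dtype=bool)
    if bad.any():
        beta_r, conv_r = _irls_batch(D[bad], y[bad], ridge=RIDGE_LAMBDA, max_iter=150)
        beta[bad] = beta_r
        conv = conv.copy()
        conv[bad] = conv_r
        penalized[bad] = True
    slopes = beta[:, 1:] / sd[:, 0, :]
    intercept = beta[:, 0] - np.sum(beta[:, 1:] * mean[:, 0, :] / sd[:, 0, :], axis=1)
    return intercept, slopes, conv, penalized


def fit_logistic(
    X: np.ndarray, y: np.ndarray, feature_names: list[str] | None = None
) -> LogisticModel:
    """Maximum-likelihood logistic fit with the ridge fallback contract.

    On non-convergence or separation (any standardized slope beyond 15 in
    absolute value) the fit is repeated with a small ridge penalty
    (lambda = 1e-4 on slopes) and flagged ``penalized``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if X.size == 0:
        X = X.reshape(len(y), 0)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate labels: y must contain both classes")
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X.shape[1])]
    inter, coef, conv, pen = _fit_logistic_batch(X[None, :, :], y[None, :])
    return LogisticModel(
        features=list(feature_names),
        intercept=float(inter[0]),
        coefficients=coef[0],
        converged=bool(conv[0]),
        penalized=bool(pen[0]),
    )


def evaluate_on_split(
    model: LogisticModel, X_test: np.ndarray, y_test: np.ndarray
) -> PerformanceRecord:
    """Threshold the predicted probabilities and score the confusion counts."""
    pred = model.predict(X_test)
    return performance_metrics(confusion_counts(np.asarray(y_test).ravel(), pred))


# ---------------------------------------------------------------------------
# exhaustive subset search


def _enumerate_subsets(names: list[str]) -> list[tuple[str, ...]]:
    """Non-empty subsets ordered by (size, lexicographic name tuple) — the
    tie-break order of the search."""
    ordered = sorted(names)
    out: list[tuple[str, ...]] = []
    for size in range(1, len(ordered) + 1):
        out.extend(itertools.combinations(ordered, size))
    return out


def _batch_youden(y: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Youden index per batch item with the 0/0 -> 0 convention."""
    pos = y == 1
    tp = np.sum(pred & pos, axis=1)
    fn = np.sum(~pred & pos, axis=1)
    tn = np.sum(~pred & ~pos, axis=1)
    fp = np.sum(pred & ~pos, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        spec = np.where(tn + fp > 0, tn / np.maximum(tn + fp, 1), 0.0)
    return sens + spec - 1.0


def _youden_threshold_batch(probs: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Training-ROC-optimal cutpoint per batch item (ties -> larger threshold)."""
    B, n = probs.shape
    order = np.argsort(probs, axis=1)
    ps = np.take_along_axis(probs, order, axis=1)
    ys = np.take_along_axis(y, order, axis=1)
    npos = ys.sum(axis=1, keepdims=True)
    nneg = n - npos
    # tp[:, i] = positives with prob >= ps[:, i] (valid at first index of a tie run)
    tp = np.cumsum(ys[:, ::-1], axis=1)[:, ::-1]
    pred_pos = n - np.arange(n)[None, :]
    fp = pred_pos - tp
    tn = nneg - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        j = np.where(npos > 0, tp / np.maximum(npos, 1), 0.0) + np.where(
            nneg > 0, tn / np.maximum(nneg, 1), 0.0
        ) - 1.0
    valid = np.ones((B, n), dtype=bool)
    valid[:, 1:] = ps[:, 1:] > ps[:, :-1]
    j = np.where(valid, j, -np.inf)
    # sentinel: predict none (threshold above every probability), J = 0
    j_full = np.concatenate([j, np.zeros((B, 1))], axis=1)
    idx = n - np.argmax(j_full[:, ::-1], axis=1)  # largest argmax index
    thresholds = np.empty(B)
    take = idx < n
    thresholds[take] = ps[np.arange(B)[take], idx[take]]
    top = np.minimum((ps[:, -1] + 1.0) / 2.0, 1.0)
    thresholds[~take] = top[~take]
    return thresholds


class _SearchOutput:
    """Per-split winners of one exhaustive search over candidate subsets."""

    def __init__(self, subsets, best_idx, intercepts, coefs, thresholds, youdens,
                 converged, penalized, n_penalized_total):
        self.subsets = subsets
        self.best_idx = best_idx
        self.intercepts = intercepts
        self.coefs = coefs
        self.thresholds = thresholds
        self.youdens = youdens
        self.converged = converged
        self.penalized = penalized
        self.n_penalized_total = n_penalized_total


def _search_across_splits(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str],
    train_sets: np.ndarray,
    threshold_rule: str = "fixed",
    threshold: float = 0.5,
) -> _SearchOutput:
    """Run the exhaustive subset search on every training set at once.

    ``train_sets`` is a (B, n_train) index array whose rows all contain both
    classes.  For each subset, models are fitted across all B training sets in
    one batched IRLS; the per-split winner is the first subset (in tie-break
    order: fewer features, then lexicographically smaller name tuple)
    attaining the maximal training Youden index.
    """
    subsets = _enumerate_subsets(names)
    col_of = {name: i for i, name in enumerate(names)}
    B = train_sets.shape[0]
    y_tr = y[train_sets]
    X_tr = X[train_sets]

    best_j = np.full(B, -np.inf)
    best_idx = np.zeros(B, dtype=int)
    all_inter, all_coef, all_thr = [], [], []
    all_conv, all_pen = [], []
    n_pen_total = 0
    for subset in subsets:
        cols = [col_of[f] for f in subset]
        Xs = X_tr[:, :, cols]
        inter, coef, conv, pen = _fit_logistic_batch(Xs, y_tr)
        probs = expit(inter[:, None] + np.einsum("bnk,bk->bn", Xs, coef))
        if threshold_rule == "youden":
            thr = _youden_threshold_batch(probs, y_tr)
        else:
            thr = np.full(B, threshold)
        pred = probs >= thr[:, None]
        j = _batch_youden(y_tr, pred)
        improved = j > best_j
        best_j[improved] = j[improved]
        best_idx[improved] = len(all_inter)
        all_inter.append(inter)
        all_coef.append(coef)
        all_thr.append(thr)
        all_conv.append(conv)
        all_pen.append(pen)
        n_pen_total += int(pen.sum())

    rows = np.arange(B)
    intercepts = np.stack(all_inter, axis=0)[best_idx, rows]
    thresholds = np.stack(all_thr, axis=0)[best_idx, rows]
    converged = np.stack(all_conv, axis=0)[best_idx, rows]
    penalized = np.stack(all_pen, axis=0)[best_idx, rows]
    coefs = [all_coef[best_idx[b]][b] for b in range(B)]
    return _SearchOutput(
        subsets=subsets,
        best_idx=best_idx,
        intercepts=intercepts,
        coefs=coefs,
        thresholds=thresholds,
        youdens=best_j,
        converged=converged,
        penalized=penalized,
        n_penalized_total=n_pen_total,
    )


def aps_lr(
    X: np.ndarray,
    y: np.ndarray,
    candidates: list[str],
    threshold_rule: str = "fixed",
    threshold: float = 0.5,
    gene: str = "",
    max_candidates: int = 20,
) -> SubsetSearchResult:
    """All-possible-subset logistic regression maximizing the training Youden
    index; evaluates every one of the ``2**p - 1`` non-empty subsets.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if len(candidates) != X.shape[1]:
        raise ValueError("candidates must name every column of X")
    if len(candidates) > max_candidates:
        raise ValueError(
            f"{len(candidates)} candidates exceed the exhaustive-search guard "
            f"({max_candidates}); reduce the feature set first"
        )
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate labels: y must contain both classes")
    out = _search_across_splits(
        X, y, list(candidates), np.arange(len(y))[None, :], threshold_rule, threshold
    )
    subset = out.subsets[out.best_idx[0]]
    model = LogisticModel(
        features=list(subset),
        intercept=float(out.intercepts[0]),
        coefficients=out.coefs[0],
        threshold=float(out.thresholds[0]),
        converged=bool(out.converged[0]),
        penalized=bool(out.penalized[0]),
    )
    return SubsetSearchResult(
        gene=gene,
        best_subset=subset,
        model=model,
        train_youden=float(out.youdens[0]),
        n_subsets_evaluated=len(out.subsets),
    )


# ---------------------------------------------------------------------------
# the two model-building methods


def _prepare_gene_design(
    table: pd.DataFrame, reduced: ReducedFeatureSet
) -> tuple[np.ndarray, list[str], list[ModelingTransformDecision]]:
    """Modeling-transformed design matrix for one gene's reduced features.

    The raw-vs-log decision is made once on the full cohort, before any
    cross-validation, so every split sees the same fixed per-feature map.
    """
    missing = [f for f in reduced.features if f not in table.columns]
    if missing:
        raise ValueError(f"reduced features missing from table: {missing}")
    sub = table[list(reduced.features)]
    transformer = LogSkewTransformer().fit(sub)
    return (
        transformer.transform(sub).to_numpy(float),
        list(reduced.features),
        transformer.decisions_,
    )


def _usable_split_mask(y: np.ndarray, splits: list[CVSplit]) -> np.ndarray:
    train = np.stack([s.train_idx for s in splits])
    y_tr = y[train]
    return (y_tr.min(axis=1) == 0) & (y_tr.max(axis=1) == 1)


def run_method1(
    table: pd.DataFrame,
    labels: np.ndarray,
    reduced: ReducedFeatureSet,
    splits: list[CVSplit],
    threshold_rule: str = "fixed",
    threshold: float = 0.5,
) -> Method1Result:
    """APS-LR on every training set, each winner scored on its own test set.

    Splits whose training labels contain a single class admit no logistic fit
    and are skipped; the count is reported.
    """
    y = np.asarray(labels, dtype=float).ravel()
    X, names, decisions = _prepare_gene_design(table, reduced)
    usable = _usable_split_mask(y, splits)
    used = [s for s, ok in zip(splits, usable) if ok]
    n_skipped = int((~usable).sum())
    if not used:
        return Method1Result(reduced.gene, [], [], n_skipped, 0, decisions)
    train_sets = np.stack([s.train_idx for s in used])
    out = _search_across_splits(X, y, names, train_sets, threshold_rule, threshold)

    search_results: list[SubsetSearchResult] = []
    records: list[PerformanceRecord] = []
    col_of = {name: i for i, name in enumerate(names)}
    for b, split in enumerate(used):
        subset = out.subsets[out.best_idx[b]]
        model = LogisticModel(
            features=list(subset),
            intercept=float(out.intercepts[b]),
            coefficients=out.coefs[b],
            threshold=float(out.thresholds[b]),
            converged=bool(out.converged[b]),
            penalized=bool(out.penalized[b]),
        )
        search_results.append(
            SubsetSearchResult(
                gene=reduced.gene,
                best_subset=subset,
                model=model,
                train_youden=float(out.youdens[b]),
                n_subsets_evaluated=len(out.subsets),
            )
        )
        cols = [col_of[f] for f in subset]
        records.append(
            evaluate_on_split(model, X[split.test_idx][:, cols], y[split.test_idx])
        )
    return Method1Result(
        gene=reduced.gene,
        search_results=search_results,
        records=records,
        n_splits_skipped=n_skipped,
        n_penalized_fits=out.n_penalized_total,
        transform_decisions=decisions,
    )


def run_method2(
    table: pd.DataFrame,
    labels: np.ndarray,
    reduced: ReducedFeatureSet,
    splits: list[CVSplit],
    threshold_rule: str = "fixed",
    threshold: float = 0.5,
) -> Method2Result:
    """One full-cohort APS-LR fixes the subset; coefficients are re-estimated
    on every training set and evaluated on the matching test set."""
    y = np.asarray(labels, dtype=float).ravel()
    X, names, decisions = _prepare_gene_design(table, reduced)
    col_of = {name: i for i, name in enumerate(names)}
    search = aps_lr(
        X, y, names, threshold_rule=threshold_rule, threshold=threshold, gene=reduced.gene
    )
    cols = [col_of[f] for f in search.best_subset]

    usable = _usable_split_mask(y, splits)
    used = [s for s, ok in zip(splits, usable) if ok]
    n_skipped = int((~usable).sum())
    if not used:
        return Method2Result(reduced.gene, search, [], [], n_skipped, 0, decisions)
    train_sets = np.stack([s.train_idx for s in used])
    y_tr = y[train_sets]
    X_tr = X[train_sets][:, :, cols]
    inter, coef, conv, pen = _fit_logistic_batch(X_tr, y_tr)
    if threshold_rule == "youden":
        probs = expit(inter[:, None] + np.einsum("bnk,bk->bn", X_tr, coef))
        thr = _youden_threshold_batch(probs, y_tr)
    else:
        thr = np.full(len(used), threshold)

    split_models: list[LogisticModel] = []
    records: list[PerformanceRecord] = []
    for b, split in enumerate(used):
        model = LogisticModel(
            features=list(search.best_subset),
            intercept=float(inter[b]),
            coefficients=coef[b],
            threshold=float(thr[b]),
            converged=bool(conv[b]),
            penalized=bool(pen[b]),
        )
        split_models.append(model)
        records.append(
            evaluate_on_split(model, X[split.test_idx][:, cols], y[split.test_idx])
        )
    return Method2Result(
        gene=reduced.gene,
        search=search,
        split_models=split_models,
        records=records,
        n_splits_skipped=n_skipped,
        n_penalized_fits=int(pen.sum()),
        transform_decisions=decisions,
    )


# ---------------------------------------------------------------------------
# scikit-learn estimator facade


class SubsetLogisticRegression(ClassifierMixin, BaseEstimator):
    """Exhaustive all-subset logistic classifier maximizing the Youden index.

    ``fit`` evaluates every non-empty subset of the input features (the guard
    ``max_candidates`` bounds the 2**p blow-up), keeping the subset whose
    fitted model attains the largest training-set Youden index at the
    classification threshold.  Ties prefer fewer features, then
    lexicographically smaller feature-name tuples.

    Parameters
    ----------
    threshold_rule : {"fixed", "youden"}, default "fixed"
        "fixed" classifies positive at ``threshold``; "youden" uses the
        training-ROC-optimal cutpoint per fitted model.
    threshold : float, default 0.5
    max_candidates : int, default 20

    Attributes
    ----------
    best_subset_ : tuple of str
    model_ : LogisticModel
    train_youden_ : float
    n_subsets_evaluated_ : int
    classes_ : ndarray
    """

    def __init__(
        self,
        threshold_rule: str = "fixed",
        threshold: float = 0.5,
        max_candidates: int = 20,
    ):
        self.threshold_rule = threshold_rule
        self.threshold = threshold
        self.max_candidates = max_candidates

    def fit(self, X, y) -> "SubsetLogisticRegression":
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            X_arr = X.to_numpy(float)
        else:
            X_arr = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(X_arr.shape[1])]
        y_arr = np.asarray(y, dtype=float).ravel()
        if set(np.unique(y_arr)) - {0.0, 1.0}:
            raise ValueError("y must be binary 0/1")
        result = aps_lr(
            X_arr,
            y_arr,
            names,
            threshold_rule=self.threshold_rule,
            threshold=self.threshold,
            max_candidates=self.max_candidates,
        )
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = X_arr.shape[1]
        self.classes_ = np.array([0, 1])
        self.best_subset_ = result.best_subset
        self.model_ = result.model
        self.train_youden_ = result.train_youden
        self.n_subsets_evaluated_ = result.n_subsets_evaluated
        self._cols = [names.index(f) for f in result.best_subset]
        return self

    def _subset_matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X[list(self.best_subset_)].to_numpy(float)
        return np.asarray(X, dtype=float)[:, self._cols]

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        p1 = self.model_.predict_proba(self._subset_matrix(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict(self._subset_matrix(X))
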