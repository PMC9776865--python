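"""Data-dependent normalization for clustering and the modeling log-rule.

Two distinct transforms appear in the pipeline:

* Before the features are clustered, every column is normalized by the
  best-of-family rule: each candidate monotone family is fitted, the
  transformed vector is scored by a Pearson chi-squared goodness-of-normality
  statistic, and the family with the lowest score wins.  Every candidate is
  strictly increasing, so rank statistics (and hence the Spearman-based
  clustering and selection downstream) are unchanged.
* For modeling, a feature enters the logistic regressions either raw or
  log-transformed: the log is used exactly when the sample mean/median ratio
  exceeds 1.5 (a simple right-skew screen), with an additive shift when
  non-positive values are present.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "TransformRecord",
    "ModelingTransformDecision",
    "normality_score",
    "select_normalizing_transform",
    "normalize_for_clustering",
    "modeling_transform",
    "NormalizingTransformer",
    "LogSkewTransformer",
]

FAMILY_ORDER = (
    "identity",
    "shifted-log",
    "square-root",
    "inverse-hyperbolic-sine",
    "power-family",
    "rank-inverse-normal",
)


@dataclass
class TransformRecord:
    """Audit record of the normalizing transform chosen for one feature."""

    feature: str
    family: str
    parameters: dict[str, float] = field(default_factory=dict)
    normality_score: float = math.nan
    # standardization applied after the family transform
    mean: float = 0.0
    sd: float = 1.0
    # training values/quantiles, needed by the rank family to map new data
    train_sorted: np.ndarray | None = None
    train_normal_scores: np.ndarray | None = None

    def apply(self, values: np.ndarray) -> np.ndarray:
        transformed = _apply_family(
            np.asarray(values, dtype=float),
            self.family,
            self.parameters,
            self.train_sorted,
            self.train_normal_scores,
        )
        return (transformed - self.mean) / self.sd

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "family": self.family,
            "parameters": self.parameters,
            "normality_score": self.normality_score,
            "mean": self.mean,
            "sd": self.sd,
        }


@dataclass
class ModelingTransformDecision:
    """Outcome of the mean/median > 1.5 raw-vs-log rule for one feature."""

    feature: str
    ratio: float
    use_log: bool
    shift: float = 0.0
    undefined_ratio: bool = False

    def apply(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.use_log:
            return np.log(values + self.shift)
        return values

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "ratio": self.ratio,
            "use_log": self.use_log,
            "shift": self.shift,
            "undefined_ratio": self.undefined_ratio,
        }


def _check_vector(values: np.ndarray, min_n: int = 8) -> np.ndarray:
    values = np.asarray(values, dtype=float).ravel()
    if values.size < min_n:
        raise ValueError(f"need at least {min_n} values, got {values.size}")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if np.all(values == values[0]):
        raise ValueError("degenerate input: all values equal")
    return values


def normality_score(values: np.ndarray) -> float:
    """Pearson chi-squared goodness-of-normality statistic per degree of freedom.

    The vector is standardized, binned into ``ceil(n**0.4)`` bins equiprobable
    under the standard normal, and ``sum((obs - exp)^2 / exp)`` is divided by
    ``bins - 3`` degrees of freedom.  Lower is more normal; the score is
    location- and scale-free.  Scores near 1 are typical of normal samples.
    """
    values = _check_vector(values)
    n = values.size
    z = (values - values.mean()) / values.std(ddof=1)
    n_bins = max(int(math.ceil(n**0.4)), 4)
    edges = stats.norm.ppf(np.arange(1, n_bins) / n_bins)
    observed = np.bincount(np.searchsorted(edges, z), minlength=n_bins)
    expected = n / n_bins
    chi2 = float(np.sum((observed - expected) ** 2) / expected)
    return chi2 / (n_bins - 3)


def _rank_normal_scores(n: int) -> np.ndarray:
    # Blom offset, the standard rank-based inverse-normal convention
    return stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))


def _apply_family(
    values: np.ndarray,
    family: str,
    params: dict[str, float],
    train_sorted: np.ndarray | None = None,
    train_normal_scores: np.ndarray | None = None,
) -> np.ndarray:
    if family == "identity":
        return values
    if family == "shifted-log":
        return np.log(values + params["shift"])
    if family == "square-root":
        return np.sqrt(values + params["shift"])
    if family == "inverse-hyperbolic-sine":
        return np.arcsinh(values)
    if family == "power-family":
        return stats.yeojohnson(values, lmbda=params["lmbda"])
    if family == "rank-inverse-normal":
        # interpolate new values through the training quantile map
        if train_sorted is None or train_normal_scores is None:
            raise ValueError("rank-inverse-normal record is missing training quantiles")
        return np.interp(values, train_sorted, train_normal_scores)
    raise ValueError(f"unknown transform family {family!r}")


def _fit_family(values: np.ndarray, family: str) -> tuple[np.ndarray, dict[str, float]]:
    if family == "identity":
        return values, {}
    if family == "shifted-log":
        shift = 1.0 - values.min() if values.min() <= 0 else 0.0
        return np.log(values + shift), {"shift": shift}
    if family == "square-root":
        shift = max(0.0, -values.min())
        return np.sqrt(values + shift), {"shift": shift}
    if family == "inverse-hyperbolic-sine":
        return np.arcsinh(values), {}
    if family == "power-family":
        transformed, lmbda = stats.yeojohnson(values)
        return transformed, {"lmbda": float(lmbda)}
    if family == "rank-inverse-normal":
        ranks = stats.rankdata(values)  # mid-ranks for ties
        n = values.size
        transformed = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
        return transformed, {}
    raise ValueError(f"unknown transform family {family!r}")


def select_normalizing_transform(values: np.ndarray, feature: str = "") -> TransformRecord:
    """Fit every candidate family and keep the one with the lowest normality
    score; ties break in ``FAMILY_ORDER``.  A family that fails numerically
    (overflow in the power-family likelihood on extreme inputs) scores +inf.
    """
    values = _check_vector(values)
    best: TransformRecord | None = None
    for family in FAMILY_ORDER:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                with np.errstate(all="ignore"):
                    transformed, params = _fit_family(values, family)
            if not np.all(np.isfinite(transformed)):
                continue
            score = normality_score(transformed)
        except (ValueError, FloatingPointError):
            continue
        if best is None or score < best.normality_score:
            mean = float(transformed.mean())
            sd = float(transformed.std(ddof=1))
            record = TransformRecord(
                feature=feature,
                family=family,
                parameters=params,
                normality_score=score,
                mean=mean,
                sd=sd,
            )
            if family == "rank-inverse-normal":
                order = np.argsort(values, kind="stable")
                record.train_sorted = values[order]
                record.train_normal_scores = transformed[order]
            best = record
    if best is None:  # all families failed — cannot happen for finite non-constant input
        raise ValueError(f"no normalizing transform could be fitted for {feature!r}")
    return best


class NormalizingTransformer(TransformerMixin, BaseEstimator):
    """Per-column best-of-family normalization followed by standardization.

    Each column is independently transformed by the family minimizing the
    Pearson chi-squared normality score, then centered and scaled to unit
    sample variance.  All families are strictly increasing, so the Spearman
    correlation matrix of the output equals that of the input.

    Attributes
    ----------
    records_ : list of TransformRecord
        One audit record per column, in column order.
    feature_names_in_ : ndarray of str
    """

    def fit(self, X: pd.DataFrame, y=None) -> "NormalizingTransformer":
        X = _as_frame(X)
        records = []
        for col in X.columns:
            try:
                records.append(select_normalizing_transform(X[col].to_numpy(float), str(col)))
            except ValueError as err:
                raise ValueError(f"column {col!r}: {err}") from err
        self.records_ = records
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = len(records)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "records_")
        X = _as_frame(X)
        out = {}
        for record in self.records_:
            with np.errstate(all="ignore"):
                out[record.feature] = record.apply(X[record.feature].to_numpy(float))
        return pd.DataFrame(out, index=X.index)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "records_")
        return np.asarray([r.feature for r in self.records_], dtype=object)


def normalize_for_clustering(table: pd.DataFrame) -> tuple[pd.DataFrame, list[TransformRecord]]:
    """Normalize every column for clustering; returns the table and audit records."""
    transformer = NormalizingTransformer().fit(table)
    return transformer.transform(table), transformer.records_


def modeling_transform(
    values: np.ndarray, feature: str = ""
) -> tuple[np.ndarray, ModelingTransformDecision]:
    """Raw-vs-log rule for modeling: log when mean/median > 1.5.

    The shift is ``1 - min(values)`` when non-positive values are present so
    the log is defined everywhere.  A zero median makes the ratio undefined;
    the value is kept raw and the decision flagged.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0 or not np.all(np.isfinite(values)):
        raise ValueError("values must be a nonempty finite vector")
    median = float(np.median(values))
    mean = float(values.mean())
    if median == 0.0:
        decision = ModelingTransformDecision(
            feature=feature, ratio=math.nan, use_log=False, undefined_ratio=True
        )
        return values, decision
    ratio = mean / median
    if ratio > 1.5:
        shift = 1.0 - values.min() if values.min() <= 0 else 0.0
        decision = ModelingTransformDecision(
            feature=feature, ratio=ratio, use_log=True, shift=shift
        )
        return np.log(values + shift), decision
    return values, ModelingTransformDecision(feature=feature, ratio=ratio, use_log=False)


class LogSkewTransformer(TransformerMixin, BaseEstimator):
    """Column-wise mean/median > 1.5 log rule as a transformer.

    The decision (and shift) is fixed at fit time and re-applied verbatim to
    new data, so cross-validation folds see a single, data-independent map.

    Attributes
    ----------
    decisions_ : list of ModelingTransformDecision
    """

    def fit(self, X: pd.DataFrame, y=None) -> "LogSkewTransformer":
        X = _as_frame(X)
        self.decisions_ = [
            modeling_transform(X[col].to_numpy(float), str(col))[1] for col in X.columns
        ]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = len(self.decisions_)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "decisions_")
        X = _as_frame(X)
        return pd.DataFrame(
            {d.feature: d.apply(X[d.feature].to_numpy(float)) for d in self.decisions_},
            index=X.index,
        )

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "decisions_")
        return np.asarray([d.feature for d in self.decisions_], dtype=object)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
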