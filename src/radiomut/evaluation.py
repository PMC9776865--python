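"""Confusion-matrix metrics, distributional summaries and importance tables.

Test sets of ten patients routinely produce degenerate confusion tables (no
predicted positives, no true negatives, ...).  Every 0/0 ratio is defined as
0 and flagged, so all cross-validation splits contribute to the summaries
— a zero-fill that matches reporting medians of 0.00 for PPV/sensitivity of
low-prevalence genes — and the Youden identity (J = sensitivity +
specificity - 1) holds exactly on every record.  Distributions over the
resamples are summarized by the median with an empirical 95% interval
(2.5th/97.5th percentiles, linear-interpolation quantiles).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "PerformanceRecord",
    "PerformanceSummary",
    "METRICS",
    "confusion_counts",
    "performance_metrics",
    "summarize_distribution",
    "feature_importance",
    "render_report",
]

METRICS = ("npv", "ppv", "sensitivity", "specificity", "youden")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class PerformanceRecord:
    npv: float
    ppv: float
    sensitivity: float
    specificity: float
    youden: float
    degenerate_flags: frozenset[str] = frozenset()

    def metric(self, name: str) -> float:
        return getattr(self, name)


@dataclass
class PerformanceSummary:
    """Median and empirical 95% interval per metric over CV resamples."""

    median: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    n_splits_used: int


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).ravel().astype(int)
    y_pred = np.asarray(y_pred).ravel().astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValueError("empty test set")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _safe_ratio(num: int, den: int, flag: str, flags: set[str]) -> float:
    if den == 0:
        flags.add(flag)
        return 0.0
    return num / den


def performance_metrics(counts: ConfusionCounts) -> PerformanceRecord:
    """NPV/PPV/sensitivity/specificity with the 0/0 -> 0 convention, flagged."""
    if counts.total == 0:
        raise ValueError("empty confusion table")
    flags: set[str] = set()
    sensitivity = _safe_ratio(counts.tp, counts.tp + counts.fn, "no_true_pos", flags)
    specificity = _safe_ratio(counts.tn, counts.tn + counts.fp, "no_true_neg", flags)
    ppv = _safe_ratio(counts.tp, counts.tp + counts.fp, "no_pred_pos", flags)
    npv = _safe_ratio(counts.tn, counts.tn + counts.fn, "no_pred_neg", flags)
    return PerformanceRecord(
        npv=npv,
        ppv=ppv,
        sensitivity=sensitivity,
        specificity=specificity,
        youden=sensitivity + specificity - 1.0,
        degenerate_flags=frozenset(flags),
    )


def summarize_distribution(records: list[PerformanceRecord]) -> PerformanceSummary:
    """Per-metric median and 2.5/97.5 percentiles (linear interpolation)."""
    if not records:
        raise ValueError("no performance records to summarize")
    median, lo, hi = {}, {}, {}
    for m in METRICS:
        values = np.array([r.metric(m) for r in records], dtype=float)
        median[m] = float(np.percentile(values, 50))
        lo[m] = float(np.percentile(values, 2.5))
        hi[m] = float(np.percentile(values, 97.5))
    return PerformanceSummary(
        median=median, ci_low=lo, ci_high=hi, n_splits_used=len(records)
    )


def feature_importance(search_results: list) -> dict[str, int]:
    """Number of per-split winning subsets each feature appears in; features
    never selected are omitted.  Sorted by descending count, then name."""
    if not search_results:
        raise ValueError("no search results")
    counts: dict[str, int] = {}
    for result in search_results:
        for feature in result.best_subset:
            counts[feature] = counts.get(feature, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


def summary_frame(summaries: dict[str, PerformanceSummary]) -> pd.DataFrame:
    """Long-form gene x metric table of median / ci_low / ci_high."""
    rows = []
    for gene, s in summaries.items():
        for m in METRICS:
            rows.append(
                {
                    "gene": gene,
                    "metric": m,
                    "median": s.median[m],
                    "ci_low": s.ci_low[m],
                    "ci_high": s.ci_high[m],
                    "n_splits_used": s.n_splits_used,
                }
            )
    return pd.DataFrame(rows)


def render_report(
    method1_results: dict,
    method2_results: dict,
    out_dir: str | Path,
) -> list[Path]:
    """Write importance CSVs, per-method summary CSVs, the Method-2 fixed
    subsets and per-gene Youden boxplots comparing the two methods."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for gene, res in method1_results.items():
        imp = feature_importance(res.search_results)
        path = out_dir / f"importance_{gene}_method1.csv"
        pd.DataFrame(
            {"feature": list(imp), "count": list(imp.values())}
        ).to_csv(path, index=False)
        written.append(path)

    fixed = {
        gene: list(res.search.best_subset) for gene, res in method2_results.items()
    }
    path = out_dir / "fixed_subset_method2.json"
    path.write_text(json.dumps(fixed, indent=2) + "\n")
    written.append(path)

    for label, results in (("method1", method1_results), ("method2", method2_results)):
        summaries = {g: summarize_distribution(r.records) for g, r in results.items()}
        path = out_dir / f"summary_{label}.csv"
        summary_frame(summaries).to_csv(path, index=False, float_format="%.6g")
        written.append(path)

    written.extend(_youden_boxplots(method1_results, method2_results, out_dir))
    return written


def _youden_boxplots(method1_results, method2_results, out_dir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genes = list(method1_results)
    fig, axes = plt.subplots(1, max(len(genes), 1), figsize=(3 * max(len(genes), 1), 4))
    if len(genes) == 1:
        axes = [axes]
    for ax, gene in zip(np.atleast_1d(axes).ravel(), genes):
        data = [
            [r.youden for r in method1_results[gene].records],
            [r.youden for r in method2_results[gene].records],
        ]
        ax.boxplot(data, tick_labels=["method 1", "method 2"])
        ax.set_title(gene)
        ax.set_ylabel("Youden index")
        ax.set_ylim(-1.05, 1.05)
    fig.tight_layout()
    paths = [out_dir / "youden_boxplots.png", out_dir / "youden_boxplots.svg"]
    for p in paths:
        fig.savefig(p)
    plt.close(fig)
    return paths
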