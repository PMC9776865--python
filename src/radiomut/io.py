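"""File I/O, configuration and end-to-end pipeline orchestration.

Feature tables and mutation labels travel as CSV with the patient ID in the
first column; patients are aligned by ID join, never by row order.  A run is
a pure function of (inputs, config, seed): the manifest written next to the
reports suffices to re-execute an identical run.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import render_report
from .modeling import Method1Result, Method2Result, make_cv_splits, run_method1, run_method2
from .preprocessing import normalize_for_clustering
from .reduction import (
    FeaturePartition,
    ReducedFeatureSet,
    complete_linkage_clusters,
    correlation_distance_matrix,
    select_cluster_representatives,
)

__all__ = [
    "CohortManifest",
    "RunConfig",
    "PipelineResult",
    "read_feature_table",
    "read_mutation_labels",
    "write_table",
    "mutation_prevalence",
    "run_pipeline",
]


@dataclass
class CohortManifest:
    """Cohort bookkeeping: identified minus the (disjoint) exclusions."""

    n_identified: int
    n_excluded_no_imaging: int
    n_excluded_no_wgs: int

    @property
    def n_included(self) -> int:
        return self.n_identified - self.n_excluded_no_imaging - self.n_excluded_no_wgs


@dataclass
class RunConfig:
    """Design parameters of one pipeline run.

    The defaults reproduce the reference study design: features cut into 7
    clusters, 1000 cross-validation sets of 10 test patients (leaving 37 of a
    47-patient cohort for training), classification at probability 0.5.
    """

    k_clusters: int = 7
    n_sets: int = 1000
    test_size: int = 10
    threshold_rule: str = "fixed"
    threshold: float = 0.5
    seed: int = 0
    genes: list[str] | None = None
    method: str = "both"  # "1", "2" or "both"
    stratify: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    config: RunConfig
    partition: FeaturePartition
    reduced: dict[str, ReducedFeatureSet]
    method1: dict[str, Method1Result] = field(default_factory=dict)
    method2: dict[str, Method2Result] = field(default_factory=dict)
    written: list[Path] = field(default_factory=list)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a patient x feature CSV (patient ID first column)."""
    table = pd.read_csv(path, index_col=0)
    table.index = table.index.astype(str)
    table.index.name = "patient_id"
    dup = table.index[table.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate patient IDs: {dup}")
    for col in table.columns:
        if not np.issubdtype(table[col].dtype, np.number):
            bad = table.index[pd.to_numeric(table[col], errors="coerce").isna()].tolist()
            raise ValueError(f"non-numeric values in column {col!r} at rows {bad}")
    if table.isna().any().any():
        cells = [
            (str(i), str(c))
            for i, c in zip(*np.where(table.isna().to_numpy()))
        ]
        locs = [(table.index[int(i)], table.columns[int(c)]) for i, c in cells[:5]]
        raise ValueError(f"missing values at {locs}")
    return table.astype(float)


def read_mutation_labels(
    path: str | Path, genes: list[str] | None = None, patients: pd.Index | None = None
) -> pd.DataFrame:
    """Read and validate a patient x gene 0/1 CSV, aligned to ``patients``."""
    labels = pd.read_csv(path, index_col=0)
    labels.index = labels.index.astype(str)
    labels.index.name = "patient_id"
    dup = labels.index[labels.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate patient IDs: {dup}")
    if genes is not None:
        missing = [g for g in genes if g not in labels.columns]
        if missing:
            raise ValueError(f"genes not present in label table: {missing}")
        labels = labels[list(genes)]
    for col in labels.columns:
        values = pd.to_numeric(labels[col], errors="coerce")
        if values.isna().any() or not values.isin([0, 1]).all():
            bad = labels.index[~values.isin([0, 1])].tolist()
            raise ValueError(f"labels for {col!r} must be 0/1; bad rows: {bad}")
    labels = labels.astype(int)
    if patients is not None:
        only_features = sorted(set(patients) - set(labels.index))
        only_labels = sorted(set(labels.index) - set(patients))
        if only_features or only_labels:
            raise ValueError(
                "patient mismatch between feature and label tables: "
                f"features-only={only_features}, labels-only={only_labels}"
            )
        labels = labels.loc[patients]
    return labels


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index_label="patient_id")
    return path


def mutation_prevalence(labels: pd.DataFrame) -> dict[str, tuple[int, int]]:
    """Per gene, the positive count and the percent rounded to nearest integer."""
    if len(labels) == 0:
        raise ValueError("empty label table")
    out = {}
    for gene in labels.columns:
        count = int(labels[gene].sum())
        out[gene] = (count, int(np.floor(100.0 * count / len(labels) + 0.5)))
    return out


def reduce_features(
    features: pd.DataFrame, labels: pd.DataFrame, k: int
) -> tuple[FeaturePartition, dict[str, ReducedFeatureSet]]:
    """Normalize, cluster once, then pick per-gene cluster representatives.

    The cut is shared by every gene; only the representative choice depends
    on mutation status.
    """
    normalized, _records = normalize_for_clustering(features)
    dist = correlation_distance_matrix(normalized)
    partition = complete_linkage_clusters(dist, k, [str(c) for c in features.columns])
    reduced = {
        gene: select_cluster_representatives(features, labels[gene], partition)
        for gene in labels.columns
    }
    return partition, reduced


def run_pipeline(
    config: RunConfig,
    features: pd.DataFrame,
    labels: pd.DataFrame,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full pipeline: normalize -> cluster once -> per-gene
    representatives -> modeling transforms -> CV splits -> methods 1/2 ->
    reports, writing report files and a machine-readable run manifest."""
    genes = config.genes or list(labels.columns)
    labels = labels[genes]
    partition, reduced = reduce_features(features, labels, config.k_clusters)
    splits = make_cv_splits(
        n=len(features),
        n_test=config.test_size,
        n_sets=config.n_sets,
        seed=config.seed,
    )
    result = PipelineResult(config=config, partition=partition, reduced=reduced)
    for gene in genes:
        y = labels[gene].to_numpy()
        if config.method in ("1", "both"):
            result.method1[gene] = run_method1(
                features, y, reduced[gene], splits,
                config.threshold_rule, config.threshold,
            )
        if config.method in ("2", "both"):
            result.method2[gene] = run_method2(
                features, y, reduced[gene], splits,
                config.threshold_rule, config.threshold,
            )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if result.method1 and result.method2:
            result.written = render_report(result.method1, result.method2, out_dir)
        _write_partition(result, out_dir)
        _write_manifest(result, out_dir)
    return result


def _write_partition(result: PipelineResult, out_dir: Path) -> None:
    payload = {
        "partition": result.partition.to_dict(),
        "reduced": {g: r.to_dict() for g, r in result.reduced.items()},
    }
    path = out_dir / "feature_reduction.json"
    path.write_text(json.dumps(payload, indent=2) + "\n")
    result.written.append(path)


def _write_manifest(result: PipelineResult, out_dir: Path) -> None:
    manifest = {
        "config": result.config.to_dict(),
        "package_version": __version__,
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
        "skipped_splits": {
            "method1": {g: r.n_splits_skipped for g, r in result.method1.items()},
            "method2": {g: r.n_splits_skipped for g, r in result.method2.items()},
        },
        "penalized_fits": {
            "method1": {g: r.n_penalized_fits for g, r in result.method1.items()},
            "method2": {g: r.n_penalized_fits for g, r in result.method2.items()},
        },
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    result.written.append(path)
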