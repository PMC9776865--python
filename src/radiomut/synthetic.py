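"""Synthetic radiomics cohorts with planted correlation and label structure.

The generator emulates the statistical shape of a CT-radiomics table paired
with binary driver-gene mutation calls: features fall into blocks of mutually
correlated columns (the dendrogram structure the reduction stage cuts), a
subset of columns is right-skewed (so the mean/median log-rule fires), and
mutation labels follow a logistic model on a few planted informative features
with the marginal prevalence calibrated to a target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "SyntheticConfig",
    "generate_feature_table",
    "generate_mutation_labels",
    "make_fixture_cohort",
    "FIXTURE_GENES",
    "FIXTURE_PREVALENCES",
]

# texture-family prefixes, cycled over cluster blocks for radiomics flavour
_FAMILIES = ("HU", "GLCM", "GLRLM", "GLZLM", "NGLDM", "SHAPE", "PARAMS")

FIXTURE_GENES = ("KRAS", "TP53", "SMAD4", "CDKN2A")
FIXTURE_PREVALENCES = {"KRAS": 0.81, "TP53": 0.68, "SMAD4": 0.26, "CDKN2A": 0.19}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    ``within_corr``/``between_corr`` are latent Gaussian correlations inside
    and across feature blocks; ``skew_fraction`` of the columns is passed
    through ``exp(skew_scale * z)``, a strictly increasing convex map, so
    their sample mean/median ratio exceeds 1.5 with high probability while
    every rank statistic is unchanged.  ``effects`` gives, per gene, a list of
    ``(feature_name, coefficient)`` pairs on the standardized feature scale.
    """

    n_patients: int = 47
    n_features: int = 49
    n_clusters: int = 7
    within_corr: float = 0.8
    between_corr: float = 0.2
    skew_fraction: float = 0.3
    skew_scale: float = 1.5
    effects: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    target_prevalence: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_features < 1 or self.n_clusters < 1:
            raise ValueError("n_patients, n_features and n_clusters must be positive")
        if self.n_clusters > self.n_features:
            raise ValueError("n_clusters must not exceed n_features")
        if not 0.0 <= self.within_corr < 1.0:
            raise ValueError("within_corr must lie in [0, 1)")
        if not 0.0 <= self.between_corr < self.within_corr:
            raise ValueError("between_corr must lie in [0, within_corr)")
        if not 0.0 <= self.skew_fraction <= 1.0:
            raise ValueError("skew_fraction must lie in [0, 1]")
        names = set(feature_names(self.n_features, self.n_clusters))
        for gene, pairs in self.effects.items():
            for name, _ in pairs:
                if name not in names:
                    raise ValueError(f"effect feature {name!r} for gene {gene!r} is not generated")
        for gene, p in self.target_prevalence.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"target_prevalence for {gene!r} must lie in (0, 1)")


def block_assignment(n_features: int, n_clusters: int) -> np.ndarray:
    """Planted block index (0-based) of each feature, blocks as equal as possible."""
    return np.sort(np.arange(n_features) % n_clusters)


def feature_names(n_features: int, n_clusters: int) -> list[str]:
    blocks = block_assignment(n_features, n_clusters)
    return [
        f"{_FAMILIES[b % len(_FAMILIES)]}_f{i:02d}" for i, b in enumerate(blocks)
    ]


def generate_feature_table(config: SyntheticConfig) -> pd.DataFrame:
    """Draw an ``n_patients x n_features`` table with planted block correlation.

    The latent draw is an exchangeable-within-block Gaussian factor model:
    ``x = sqrt(b)*g + sqrt(w-b)*u_block + sqrt(1-w)*e`` which has correlation
    ``w`` within a block and ``b`` across blocks.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p, k = config.n_patients, config.n_features, config.n_clusters
    blocks = block_assignment(p, k)

    g = rng.standard_normal((n, 1))
    u = rng.standard_normal((n, k))
    e = rng.standard_normal((n, p))
    w, b = config.within_corr, config.between_corr
    latent = np.sqrt(b) * g + np.sqrt(w - b) * u[:, blocks] + np.sqrt(1.0 - w) * e

    values = latent.copy()
    n_skew = int(round(config.skew_fraction * p))
    if n_skew > 0:
        skew_cols = rng.choice(p, size=n_skew, replace=False)
        values[:, skew_cols] = np.exp(config.skew_scale * latent[:, skew_cols])

    index = pd.Index([f"P{i + 1:03d}" for i in range(n)], name="patient_id")
    return pd.DataFrame(values, index=index, columns=feature_names(p, k))


def _calibrate_intercept(linpred: np.ndarray, target: float) -> float:
    """Solve mean(expit(a + linpred)) = target for the intercept a."""

    def gap(a: float) -> float:
        return float(np.mean(expit(a + linpred))) - target

    return float(brentq(gap, -60.0, 60.0, xtol=1e-6))


def generate_mutation_labels(
    features: pd.DataFrame,
    effects: dict[str, list[tuple[str, float]]],
    target_prevalence: dict[str, float],
    seed: int,
) -> pd.DataFrame:
    """Bernoulli mutation labels from a logistic model on standardized features.

    The per-gene intercept is found by 1-D root finding so that the expected
    prevalence over the realized cohort equals ``target_prevalence`` (within
    the root-finder tolerance, 1e-6 on the prevalence scale).
    """
    rng = np.random.default_rng(seed)
    labels: dict[str, np.ndarray] = {}
    for gene in effects:
        if gene not in target_prevalence:
            raise ValueError(f"no target prevalence for gene {gene!r}")
        if not 0.0 < target_prevalence[gene] < 1.0:
            raise ValueError(f"target_prevalence for {gene!r} must lie in (0, 1)")
        linpred = np.zeros(len(features))
        for name, coef in effects[gene]:
            if name not in features.columns:
                raise ValueError(f"unknown effect feature {name!r} for gene {gene!r}")
            col = features[name].to_numpy(float)
            sd = col.std(ddof=1)
            if sd == 0:
                raise ValueError(f"effect feature {name!r} is constant")
            linpred = linpred + coef * (col - col.mean()) / sd
        alpha = _calibrate_intercept(linpred, target_prevalence[gene])
        probs = expit(alpha + linpred)
        labels[gene] = (rng.random(len(features)) < probs).astype(int)
    return pd.DataFrame(labels, index=features.index.copy())


# one planted informative feature per gene, each in a different block
_FIXTURE_EFFECTS = {
    "KRAS": [("HU_f00", 2.0)],
    "TP53": [("GLCM_f07", 2.0)],
    "SMAD4": [("GLRLM_f14", 2.0)],
    "CDKN2A": [("GLZLM_f21", 2.0)],
}

FIXTURE_SEED = 20221214


def make_fixture_cohort(
    n_patients: int = 47, seed: int = FIXTURE_SEED
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fixed-seed study-scale cohort: 47 patients, 49 features in 7 blocks,
    4 genes at prevalences 0.81/0.68/0.26/0.19 with one planted feature each.

    The returned values are frozen artifacts of this generator, not data from
    any patient cohort.
    """
    config = SyntheticConfig(
        n_patients=n_patients,
        effects=_FIXTURE_EFFECTS,
        target_prevalence=dict(FIXTURE_PREVALENCES),
        seed=seed,
    )
    features = generate_feature_table(config)
    labels = generate_mutation_labels(
        features, config.effects, config.target_prevalence, seed=seed + 1
    )
    return features, labels
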