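"""CV resampling, logistic fitting and the exhaustive subset search."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from radiomut.modeling import (
    SubsetLogisticRegression,
    aps_lr,
    evaluate_on_split,
    fit_logistic,
    make_cv_splits,
    run_method1,
    run_method2,
)
from radiomut.reduction import ReducedFeatureSet

from .oracles import brute_force_aps, statsmodels_logit, youden_at_threshold


class TestMakeCvSplits:
    def test_study_design_sizes(self):
        splits = make_cv_splits(47, 10, 1000, seed=0)
        assert len(splits) == 1000
        assert all(len(s.train_idx) == 37 and len(s.test_idx) == 10 for s in splits)

    def test_partition_contract(self):
        for split in make_cv_splits(20, 6, 50, seed=1):
            assert len(np.intersect1d(split.train_idx, split.test_idx)) == 0
            assert sorted(np.concatenate([split.train_idx, split.test_idx])) == list(range(20))

    def test_seeded_determinism(self):
        a = make_cv_splits(47, 10, 20, seed=5)
        b = make_cv_splits(47, 10, 20, seed=5)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.train_idx, sb.train_idx)
            np.testing.assert_array_equal(sa.test_idx, sb.test_idx)

    def test_stratified_keeps_class_mix(self):
        y = np.r_[np.ones(33), np.zeros(14)]
        for split in make_cv_splits(47, 10, 30, seed=2, labels=y, stratify=True):
            assert y[split.test_idx].sum() == 7  # round(10 * 33/47)

    @pytest.mark.parametrize("n,n_test,n_sets", [(10, 0, 5), (10, 10, 5), (10, 3, 0)])
    def test_invalid_sizes_rejected(self, n, n_test, n_sets):
        with pytest.raises(ValueError):
            make_cv_splits(n, n_test, n_sets, seed=0)


class TestFitLogistic:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_newton_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((60, 3))
        y = (rng.random(60) < expit(X @ np.array([0.8, -0.5, 0.2]))).astype(float)
        model = fit_logistic(X, y)
        assert model.converged and not model.penalized
        intercept, coef = statsmodels_logit(X, y)
        assert model.intercept == pytest.approx(intercept, abs=1e-6)
        np.testing.assert_allclose(model.coefficients, coef, atol=1e-6)

    def test_empty_feature_set_gives_closed_form_intercept(self):
        y = np.r_[np.ones(7), np.zeros(3)]
        model = fit_logistic(np.empty((10, 0)), y)
        assert model.intercept == pytest.approx(float(logit(0.7)))
        assert model.coefficients.size == 0

    def test_perfect_separation_falls_back_to_ridge(self):
        x = np.r_[np.linspace(-2, -1, 20), np.linspace(1, 2, 20)].reshape(-1, 1)
        y = np.r_[np.zeros(20), np.ones(20)]
        model = fit_logistic(x, y)
        assert model.penalized
        assert np.all(np.isfinite(model.coefficients))

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.random.default_rng(0).standard_normal((10, 1)), np.ones(10))


class TestEvaluateOnSplit:
    def test_all_positive_truth_with_all_positive_predictions(self):
        model = fit_logistic(
            np.r_[np.zeros(5), np.ones(5)].reshape(-1, 1),
            np.r_[np.zeros(5), np.ones(5)],
        )
        model.intercept, model.coefficients = 10.0, np.array([0.0])
        record = evaluate_on_split(model, np.ones((4, 1)), np.ones(4))
        assert record.sensitivity == 1.0
        assert record.specificity == 0.0  # no true negatives -> zero convention
        assert record.youden == 0.0
        assert "no_true_neg" in record.degenerate_flags


class TestApsLr:
    def test_evaluates_every_nonempty_subset(self, rng):
        X = rng.standard_normal((47, 7))
        y = (rng.random(47) < 0.5).astype(float)
        result = aps_lr(X, y, [f"f{i}" for i in range(7)])
        assert result.n_subsets_evaluated == 127

    def test_two_candidates_equal_manual_enumeration(self, rng):
        X = rng.standard_normal((40, 2))
        y = (rng.random(40) < expit(1.2 * X[:, 0])).astype(float)
        result = aps_lr(X, y, ["a", "b"])
        subset, j = brute_force_aps(X, y, ["a", "b"])
        assert result.best_subset == subset
        assert result.train_youden == pytest.approx(j, abs=1e-9)

    def test_separating_candidate_dominates(self, rng):
        noise = rng.standard_normal((40, 2))
        sep = np.r_[-1 - rng.random(20), 1 + rng.random(20)].reshape(-1, 1)
        y = np.r_[np.zeros(20), np.ones(20)]
        X = np.hstack([noise, sep])
        result = aps_lr(X, y, ["n0", "n1", "sep"])
        assert "sep" in result.best_subset
        assert result.train_youden == pytest.approx(1.0)

    def test_guard_on_candidate_count(self, rng):
        X = rng.standard_normal((30, 21))
        y = (rng.random(30) < 0.5).astype(float)
        with pytest.raises(ValueError, match="reduce the feature set"):
            aps_lr(X, y, [f"f{i}" for i in range(21)])

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_enumeration_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        p = 4
        X = rng.standard_normal((40, p))
        beta = rng.uniform(-1, 1, p)
        y = (rng.random(40) < expit(X @ beta)).astype(float)
        names = [f"f{i}" for i in range(p)]
        result = aps_lr(X, y, names)
        subset, j = brute_force_aps(X, y, names)
        assert result.best_subset == subset
        assert result.train_youden == pytest.approx(j, abs=1e-9)


def _toy_gene(rng, n=200, effect=2.0):
    table = pd.DataFrame(
        {
            "signal": rng.standard_normal(n),
            "noise1": rng.standard_normal(n),
            "noise2": rng.standard_normal(n),
        }
    )
    y = (rng.random(n) < expit(effect * table["signal"].to_numpy())).astype(int)
    reduced = ReducedFeatureSet(gene="G", features=["signal", "noise1", "noise2"],
                                scores=[0.0, 0.0, 0.0])
    return table, y, reduced


class TestMethods:
    def test_method1_record_cardinality_and_importance(self, rng):
        table, y, reduced = _toy_gene(rng)
        splits = make_cv_splits(len(table), 10, 30, seed=0)
        res = run_method1(table, y, reduced, splits)
        assert len(res.records) + res.n_splits_skipped == 30
        assert len(res.search_results) == len(res.records)
        from radiomut.evaluation import feature_importance

        imp = feature_importance(res.search_results)
        assert max(imp.values()) <= len(res.records)
        assert imp.get("signal", 0) == max(imp.values())

    def test_method2_fixes_subset_but_not_coefficients(self, rng):
        table, y, reduced = _toy_gene(rng)
        splits = make_cv_splits(len(table), 10, 25, seed=1)
        res = run_method2(table, y, reduced, splits)
        assert "signal" in res.search.best_subset
        subsets = {tuple(m.features) for m in res.split_models}
        assert subsets == {tuple(res.search.best_subset)}
        coefs = np.array([m.coefficients for m in res.split_models])
        assert np.ptp(coefs, axis=0).max() > 0.0

    def test_single_class_training_splits_are_skipped(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"x": rng.standard_normal(12)})
        y = np.r_[np.ones(11), 0.0].astype(int)  # one negative patient
        reduced = ReducedFeatureSet(gene="G", features=["x"], scores=[0.0])
        splits = make_cv_splits(12, 4, 50, seed=3)
        res = run_method1(table, y, reduced, splits)
        expected_skips = sum(1 for s in splits if y[s.train_idx].min() == 1)
        assert res.n_splits_skipped == expected_skips
        assert len(res.records) == 50 - expected_skips

    def test_null_labels_have_near_zero_youden_and_ci_covering_zero(self, rng):
        from radiomut.evaluation import summarize_distribution

        table = pd.DataFrame(rng.standard_normal((60, 3)), columns=list("abc"))
        y = (rng.random(60) < 0.5).astype(int)
        reduced = ReducedFeatureSet(gene="G", features=list("abc"), scores=[0] * 3)
        splits = make_cv_splits(60, 10, 100, seed=4)
        for res in (run_method1(table, y, reduced, splits),
                    run_method2(table, y, reduced, splits)):
            summary = summarize_distribution(res.records)
            assert summary.ci_low["youden"] <= 0.0 <= summary.ci_high["youden"]


class TestSubsetLogisticRegressionEstimator:
    def test_sklearn_api_roundtrip(self, rng):
        from sklearn.base import clone

        X = pd.DataFrame(rng.standard_normal((80, 3)), columns=list("abc"))
        y = (rng.random(80) < expit(2.0 * X["a"].to_numpy())).astype(int)
        est = SubsetLogisticRegression()
        assert clone(est).get_params() == est.get_params()
        est.fit(X, y)
        assert "a" in est.best_subset_
        assert est.n_subsets_evaluated_ == 7
        proba = est.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert set(est.predict(X)) <= {0, 1}
        acc = (est.predict(X) == y).mean()
        assert acc > 0.7

    def test_youden_threshold_rule_reaches_at_least_fixed_youden_on_train(self, rng):
        X = pd.DataFrame(rng.standard_normal((60, 2)), columns=list("ab"))
        y = (rng.random(60) < expit(1.5 * X["a"].to_numpy() - 1.0)).astype(int)
        fixed = SubsetLogisticRegression(threshold_rule="fixed").fit(X, y)
        tuned = SubsetLogisticRegression(threshold_rule="youden").fit(X, y)
        assert tuned.train_youden_ >= fixed.train_youden_ - 1e-12
        probs = tuned.predict_proba(X)[:, 1]
        assert tuned.train_youden_ == pytest.approx(
            youden_at_threshold(y, probs, tuned.model_.threshold), abs=1e-9
        )
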