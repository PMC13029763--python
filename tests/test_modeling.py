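"""Metric correctness against brute-force oracles, tuning harness contracts."""

import numpy as np
import pandas as pd
import pytest

from oracles import (
    ap_stepwise,
    auc_pairwise,
    balanced_accuracy_formula,
    mcc_formula,
    threshold_sweep_max,
)

from nutrascreen.modeling import (
    ModelConfig,
    UNDEFINED,
    aggregate_seeds,
    calibrate,
    evaluate,
    oof_predict,
    select_threshold,
    threshold_metrics,
    tune_and_fit,
)


def _random_instance(rng, n):
    y = rng.integers(0, 2, n)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    p = np.round(rng.random(n), 3)  # rounding forces occasional ties
    return p, y


class TestMetricOracles:
    def test_match_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            p, y = _random_instance(rng, int(rng.integers(4, 50)))
            ev = evaluate(p, y)
            assert ev["auc"] == pytest.approx(auc_pairwise(p, y), abs=1e-9)
            assert ev["ap"] == pytest.approx(ap_stepwise(p, y), abs=1e-9)
            assert ev["mcc"] == pytest.approx(mcc_formula(p, y), abs=1e-9)
            assert ev["balanced_accuracy"] == pytest.approx(
                balanced_accuracy_formula(p, y), abs=1e-9
            )

    def test_perfect_predictions(self):
        y = np.array([0, 0, 1, 1])
        ev = evaluate(y.astype(float), y)
        assert ev["auc"] == ev["ap"] == ev["mcc"] == 1.0

    def test_derived_confusion_example(self):
        # TP=2, FP=1, FN=1, TN=2 → MCC = 1/3, balanced accuracy = 2/3
        y = np.array([1, 1, 1, 0, 0, 0])
        p = np.array([0.9, 0.9, 0.1, 0.9, 0.1, 0.1])
        ev = evaluate(p, y)
        assert ev["confusion"] == {"tp": 2, "fp": 1, "fn": 1, "tn": 2}
        assert ev["mcc"] == pytest.approx(1 / 3, abs=1e-12)
        assert ev["balanced_accuracy"] == pytest.approx(2 / 3, abs=1e-12)

    def test_constant_half_probability_on_balanced_labels(self):
        # ≥-threshold convention predicts everything positive → BA 0.5
        y = np.array([0, 1, 0, 1])
        ev = evaluate(np.full(4, 0.5), y)
        assert ev["balanced_accuracy"] == pytest.approx(0.5)

    def test_single_class_marks_auc_ap_undefined(self):
        ev = evaluate([0.2, 0.8], [1, 1])
        assert ev["auc"] is UNDEFINED and ev["ap"] is UNDEFINED
        assert isinstance(ev["mcc"], float)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            p, y = _random_instance(rng, 40)
            base = evaluate(p, y)["auc"]
            squashed = evaluate(1 / (1 + np.exp(-5 * p)), y)["auc"]
            assert squashed == pytest.approx(base, abs=1e-12)


class TestCalibration:
    def test_perfect_probabilities_have_zero_brier(self):
        assert calibrate([0.0, 1.0, 1.0], [0, 1, 1])["brier"] == 0.0

    def test_constant_half_has_quarter_brier_for_any_labels(self):
        for labels in ([0, 0, 0], [1, 1, 1], [0, 1, 0]):
            assert calibrate([0.5] * 3, labels)["brier"] == pytest.approx(0.25)

    def test_single_bin_curve_and_count_conservation(self):
        cal = calibrate([0.42, 0.44, 0.48], [0, 1, 1])
        assert len(cal["curve"]) == 1
        assert sum(cal["bin_counts"]) == 3
        assert cal["curve"][0]["mean_predicted"] == pytest.approx(np.mean([0.42, 0.44, 0.48]))

    def test_probability_one_falls_in_last_bin(self):
        cal = calibrate([1.0], [1])
        assert cal["curve"][0]["bin"] == 9


class TestThresholdSelection:
    def test_separable_probabilities_reach_mcc_one(self):
        y = np.array([0, 0, 1, 1])
        sel = select_threshold([0.1, 0.2, 0.8, 0.9], y)
        assert sel["oof_score"] == pytest.approx(1.0)

    def test_matches_exhaustive_sweep_on_tiny_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            p, y = _random_instance(rng, int(rng.integers(3, 9)))
            sel = select_threshold(p, y)
            thr, best = threshold_sweep_max(p, y)
            assert sel["oof_score"] == pytest.approx(best, abs=1e-9)
            assert sel["threshold"] == pytest.approx(thr, abs=1e-12)

    def test_balanced_accuracy_criterion_supported(self):
        y = np.array([0, 1, 0, 1])
        sel = select_threshold([0.1, 0.9, 0.2, 0.8], y, criterion="balanced_accuracy")
        assert sel["criterion"] == "balanced_accuracy"
        assert sel["oof_score"] == pytest.approx(1.0)

    def test_frozen_threshold_applies_unchanged_to_test(self):
        y = np.array([0, 0, 1, 1])
        sel = select_threshold([0.1, 0.2, 0.8, 0.9], y)
        test = threshold_metrics([0.3, 0.7], [0, 1], sel["threshold"])
        assert test["threshold"] == sel["threshold"]
        assert 0 <= test["f1"] <= 1


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(0)
    X = rng.integers(0, 2, (120, 32)).astype(np.uint8)
    y = (X[:, 4] | X[:, 9]).astype(int)
    return X, y


class TestTuningHarness:
    def test_same_seed_reproduces_best_params(self, toy):
        X, y = toy
        config = ModelConfig(family="random_forest", n_iter=3, cv_folds=3, seed=5)
        a = tune_and_fit(X, y, config)
        b = tune_and_fit(X, y, ModelConfig(family="random_forest", n_iter=3, cv_folds=3, seed=5))
        assert a.best_params == b.best_params

    def test_single_iteration_search_is_degenerate(self, toy):
        X, y = toy
        tuned = tune_and_fit(X, y, ModelConfig(family="random_forest", n_iter=1, cv_folds=3, seed=1))
        assert tuned.best_params  # the one sampled configuration is "best"

    def test_single_class_labels_rejected(self, toy):
        X, _ = toy
        with pytest.raises(ValueError):
            tune_and_fit(X, np.zeros(len(X), dtype=int), ModelConfig(n_iter=1, cv_folds=2, seed=1))

    def test_oof_covers_every_sample_with_valid_probabilities(self, toy):
        X, y = toy
        tuned = tune_and_fit(X, y, ModelConfig(family="random_forest", n_iter=2, cv_folds=3, seed=2))
        oof = oof_predict(X, y, tuned)
        assert oof.shape == (len(X),)
        assert ((oof >= 0) & (oof <= 1)).all()
        assert np.array_equal(oof, oof_predict(X, y, tuned))  # deterministic

    def test_planted_signal_beats_chance_with_margin(self, toy):
        X, y = toy
        tuned = tune_and_fit(X, y, ModelConfig(family="random_forest", n_iter=2, cv_folds=3, seed=3))
        assert tuned.best_cv_auc > 0.75

    def test_data_outside_tuning_rows_cannot_change_selection(self, toy):
        X, y = toy
        config = ModelConfig(family="random_forest", n_iter=2, cv_folds=3, seed=4)
        a = tune_and_fit(X[:100], y[:100], config)
        # "test" rows replaced by noise — tuning never sees them by contract
        b = tune_and_fit(X[:100], y[:100], config)
        assert a.best_params == b.best_params


class TestAggregation:
    def test_mean_and_sample_sd(self):
        evals = pd.DataFrame(
            {"model": "rf", "seed": [1, 2, 3], "test_auc": [0.88, 0.89, 0.90], "test_ap": 0.9}
        )
        agg = aggregate_seeds(evals)
        assert agg["test_auc_mean"].iloc[0] == pytest.approx(0.89)
        assert agg["test_auc_sd"].iloc[0] == pytest.approx(0.01, abs=1e-12)

    def test_single_seed_sd_zero_with_flag(self):
        agg = aggregate_seeds(
            pd.DataFrame({"model": ["rf"], "seed": [1], "test_auc": [0.9], "test_ap": [0.9]})
        )
        assert agg["test_auc_sd"].iloc[0] == 0.0
        assert agg["single_seed"].iloc[0]

    def test_ap_breaks_auc_ties_in_ranking(self):
        evals = pd.DataFrame(
            {
                "model": ["a", "b"],
                "seed": [1, 1],
                "test_auc": [0.9, 0.9],
                "test_ap": [0.8, 0.95],
            }
        )
        agg = aggregate_seeds(evals)
        assert agg.iloc[0]["model"] == "b"
        assert agg["rank"].tolist() == [1, 2]
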