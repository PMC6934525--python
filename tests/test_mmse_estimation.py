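"""Regressor families, LOSO cross-validation and screening metrics."""

import numpy as np
import pandas as pd
import pytest

from dualgait.bayes_nn import BayesianRegularizedNN
from dualgait.errors import DegenerateFitError, SchemaError, ValidationError
from dualgait.mmse_estimation import (BAYES_NN, LINEAR_SVR, RANDOM_FOREST,
                                      EstimationResult, RegressorSpec,
                                      _select_n_hidden, evaluate,
                                      fit_regressor, loso_cv, predict_scores)
from dualgait.types import CLASS_HIGH, CLASS_LOW, FEATURE_NAMES


def _toy_table(n_subjects=6, trials=3, seed=0, oracle=False, scores=None):
    """Feature table with mmse spread over both classes; optionally one
    column equal to the true score (the others mild noise)."""
    rng = np.random.default_rng(seed)
    rows = []
    if scores is None:
        scores = np.linspace(15, 30, n_subjects).round()
    for i, mmse in enumerate(scores):
        for k in range(trials):
            scale = 0.1 if oracle else 1.0
            feats = dict(zip(FEATURE_NAMES, rng.normal(scale=scale, size=12)))
            if oracle:
                feats["single_step_interval_mean"] = float(mmse)
            rows.append({"subject_id": f"S{i:02d}", "trial_index": k + 1,
                         **feats, "mmse": int(mmse)})
    return pd.DataFrame(rows)


class TestFitPredict:
    def test_linear_svr_recovers_realizable_linear_target(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 3))
        y = 3.0 * X[:, 0] + 20.0
        model = fit_regressor(RegressorSpec(family=LINEAR_SVR), X[:200],
                              y[:200], np.random.default_rng(2))
        preds = predict_scores(model, X[200:])
        assert np.max(np.abs(preds - np.clip(y[200:], 0, 30))) < 0.5

    def test_random_forest_on_noise_has_no_held_out_skill(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 5))
        y = rng.uniform(10, 30, size=200)
        model = fit_regressor(RegressorSpec(family=RANDOM_FOREST), X[:150],
                              y[:150], np.random.default_rng(4))
        preds = predict_scores(model, X[150:])
        ss_res = np.sum((y[150:] - preds) ** 2)
        ss_tot = np.sum((y[150:] - y[150:].mean()) ** 2)
        assert 1 - ss_res / ss_tot <= 0.1

    def test_random_forest_in_sample_beats_out_of_sample(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(300, 4))
        y = 24 + 2 * X[:, 0] + rng.normal(scale=1.0, size=300)
        model = fit_regressor(RegressorSpec(family=RANDOM_FOREST), X[:200],
                              y[:200], np.random.default_rng(6))
        rmse_in = np.sqrt(np.mean((model.predict(X[:200]) - y[:200]) ** 2))
        rmse_out = np.sqrt(np.mean((model.predict(X[200:]) - y[200:]) ** 2))
        assert rmse_in <= rmse_out

    def test_nn_grid_selects_width_for_nonlinear_target(self):
        """A sine target needs more than one tanh unit; the inner CV should
        notice in most seeded runs."""
        chosen = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.uniform(-3, 3, size=(200, 1))
            y = np.sin(X[:, 0]) * 5 + 24
            h = _select_n_hidden(RegressorSpec(family=BAYES_NN), X, y,
                                 seed=100 + seed)
            chosen.append(h)
        assert sum(h > 1 for h in chosen) >= 8

    def test_constant_targets_rejected(self):
        X = np.random.default_rng(0).normal(size=(30, 2))
        with pytest.raises(DegenerateFitError):
            fit_regressor(RegressorSpec(family=LINEAR_SVR), X,
                          np.full(30, 24.0), np.random.default_rng(0))

    def test_non_finite_features_rejected(self):
        X = np.random.default_rng(0).normal(size=(30, 2))
        X[3, 1] = np.nan
        with pytest.raises(ValidationError):
            fit_regressor(RegressorSpec(family=RANDOM_FOREST), X,
                          np.linspace(10, 30, 30), np.random.default_rng(0))

    def test_predictions_are_clipped_to_mmse_range(self):
        class Stub:
            n_features_in_ = 2

            def predict(self, X):
                return np.array([33.2, -4.0, 21.0])

        preds = predict_scores(Stub(), np.zeros((3, 2)))
        assert preds.tolist() == [30.0, 0.0, 21.0]

    def test_feature_count_mismatch_raises_schema_error(self):
        net = BayesianRegularizedNN(n_hidden=1, random_state=0)
        rng = np.random.default_rng(0)
        net.fit(rng.normal(size=(50, 3)), rng.normal(size=50))
        with pytest.raises(SchemaError):
            predict_scores(net, rng.normal(size=(5, 4)))


class TestLoso:
    def test_folds_partition_all_trials(self):
        table = _toy_table(n_subjects=7)
        result = loso_cv(table, RegressorSpec(family=LINEAR_SVR), seed=0)
        t = result.table
        assert len(t) == len(table)
        key = t[["subject_id", "trial_index"]].apply(tuple, axis=1)
        assert key.is_unique
        assert set(t["subject_id"]) == set(table["subject_id"])
        assert np.isfinite(t["predicted_mmse"]).all()

    @pytest.mark.parametrize("family", [LINEAR_SVR, RANDOM_FOREST, BAYES_NN])
    def test_oracle_feature_gives_perfect_screening(self, family):
        table = _toy_table(n_subjects=8, trials=5, oracle=True,
                           scores=[12, 15, 18, 20, 27, 28, 29, 30])
        result = loso_cv(table, RegressorSpec(family=family), seed=1)
        metrics = evaluate(result)
        assert metrics.recall == 1.0 and metrics.specificity == 1.0

    def test_trial_order_does_not_change_predictions(self):
        table = _toy_table(n_subjects=5, trials=4, seed=2)
        shuffled = table.sample(frac=1.0, random_state=9).reset_index(drop=True)
        spec = RegressorSpec(family=RANDOM_FOREST, n_trees=50)
        a = loso_cv(table, spec, seed=3).table
        b = loso_cv(shuffled, spec, seed=3).table
        pd.testing.assert_frame_equal(a, b)

    def test_single_subject_rejected(self):
        table = _toy_table(n_subjects=6)
        single = table[table["subject_id"] == "S00"]
        with pytest.raises(ValidationError):
            loso_cv(single, RegressorSpec(family=LINEAR_SVR), seed=0)


def test_larger_effect_sizes_improve_screening():
    """Scaling every MMSE link and dual-task cost up should raise the
    median recall + specificity across seeds (parameter recovery)."""
    from dualgait.pipeline import simulate_feature_table
    from dualgait.synthetic_cohort import CohortConfig

    def cohort_sum(scale, seed):
        cfg = CohortConfig(
            n_subjects=14, trials_per_subject=5, frame_rate_hz=15.0,
            amplitude_slope_rad=0.012 * scale, jitter_slope=0.03 * scale,
            accuracy_slope=0.010 * scale, answer_time_slope_s=0.05 * scale,
            dual_cost_jitter=0.10 * scale, dual_cost_amplitude=0.006 * scale)
        _, table = simulate_feature_table(cfg, np.random.default_rng(seed))
        result = loso_cv(table, RegressorSpec(family=LINEAR_SVR), seed=seed)
        return evaluate(result).sum

    medians = []
    for scale in (0.0, 0.5, 1.5):
        medians.append(np.median([cohort_sum(scale, 50 + s) for s in range(3)]))
    assert medians[0] < medians[2]
    assert medians[1] <= medians[2] + 0.05  # monotone up to seed noise


class TestEvaluate:
    @staticmethod
    def _result(truth, pred):
        return EstimationResult(table=pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(len(truth))],
            "trial_index": [1] * len(truth),
            "true_mmse": truth, "predicted_mmse": pred,
            "true_class": [CLASS_LOW if v < 24 else CLASS_HIGH for v in truth],
            "predicted_class": [CLASS_LOW if v < 24 else CLASS_HIGH
                                for v in pred]}))

    def test_perfect_predictions(self):
        m = evaluate(self._result([20, 28, 22, 30], [19, 27, 21, 29]))
        assert (m.recall, m.specificity, m.sum) == (1.0, 1.0, 2.0)

    def test_confusion_counts_arithmetic(self):
        truth = [20] * 4 + [28] * 5           # 4 low, 5 high
        pred = [20, 20, 20, 28, 28, 28, 28, 28, 20]  # TP=3 FN=1 TN=4 FP=1
        m = evaluate(self._result(truth, pred))
        assert m.recall == pytest.approx(0.75)
        assert m.specificity == pytest.approx(0.80)
        assert m.sum == pytest.approx(1.55)

    def test_all_predicted_high_gives_zero_recall(self):
        m = evaluate(self._result([20, 20, 28], [28, 28, 28]))
        assert m.recall == 0.0 and m.specificity == 1.0

    def test_absent_truth_class_is_undefined(self):
        m = evaluate(self._result([28, 29], [28, 20]))
        assert np.isnan(m.recall) and m.specificity == 0.5

    def test_subject_level_majority_vote(self):
        t = pd.DataFrame({
            "subject_id": ["A"] * 3 + ["B"] * 3,
            "trial_index": [1, 2, 3] * 2,
            "true_mmse": [20] * 3 + [28] * 3,
            "predicted_mmse": [20.0, 25.0, 21.0, 27.0, 28.0, 29.0],
            "true_class": [CLASS_LOW] * 3 + [CLASS_HIGH] * 3,
            "predicted_class": [CLASS_LOW, CLASS_HIGH, CLASS_LOW,
                                CLASS_HIGH, CLASS_HIGH, CLASS_HIGH]})
        agg = EstimationResult(table=t).to_subject_level().table
        assert len(agg) == 2
        assert agg.set_index("subject_id").loc["A", "predicted_class"] == CLASS_LOW
        assert agg.set_index("subject_id").loc["B", "predicted_class"] == CLASS_HIGH
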