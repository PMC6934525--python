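"""Importance, ablation, feature-set, trial-group and contrast analyses."""

import numpy as np
import pandas as pd
import pytest

from dualgait.cohort_analysis import (CONTRAST_MEASURES, PHYSICAL_FEATURES,
                                      TRIAL_GROUPS, ablate_feature,
                                      ablation_report, bonferroni,
                                      compare_feature_sets,
                                      experience_contrast, feature_importance,
                                      trial_group_analysis)
from dualgait.errors import ValidationError
from dualgait.mmse_estimation import LINEAR_SVR, RegressorSpec, loso_cv
from dualgait.types import BASE_FEATURE_TYPES, FEATURE_NAMES

SVR = RegressorSpec(family=LINEAR_SVR)


def _linear_table(n_subjects=20, trials=4, seed=0, informative=None,
                  noise=1.0, scores=None):
    """Feature table whose `informative` columns are linear in mmse."""
    rng = np.random.default_rng(seed)
    informative = informative or []
    rows = []
    if scores is None:
        scores = np.round(np.linspace(14, 30, n_subjects))
    for i, mmse in enumerate(scores):
        for k in range(trials):
            feats = {c: float(rng.normal(scale=noise)) for c in FEATURE_NAMES}
            for c in informative:
                feats[c] = 0.1 * float(mmse) + float(rng.normal(scale=0.05))
            rows.append({"subject_id": f"S{i:02d}", "trial_index": k + 1,
                         **feats, "mmse": int(mmse)})
    return pd.DataFrame(rows)


class TestImportance:
    def test_feature_equal_to_predictions_scores_one(self):
        table = _linear_table(informative=["dual_knee_amplitude_mean"])
        result = loso_cv(table, SVR, seed=0)
        augmented = table.sort_values(["subject_id", "trial_index"],
                                      kind="mergesort").reset_index(drop=True)
        augmented["oracle_of_predictions"] = \
            result.table["predicted_mmse"].to_numpy()
        report = feature_importance(augmented, SVR, seed=0, result=result)
        assert report.scores["oracle_of_predictions"] == pytest.approx(1.0)

    def test_pure_noise_feature_scores_near_zero(self):
        table = _linear_table(n_subjects=30, trials=40, seed=1,
                              informative=["dual_step_interval_sd"])
        report = feature_importance(table, SVR, seed=1)
        assert report.scores["single_answer_rate"] < 0.02
        assert report.scores["dual_step_interval_sd"] > 0.5

    def test_duplicated_columns_score_equally(self):
        table = _linear_table(informative=["dual_knee_amplitude_mean"])
        table["dual_knee_amplitude_sd"] = table["dual_knee_amplitude_mean"]
        report = feature_importance(table, SVR, seed=2)
        assert report.scores["dual_knee_amplitude_sd"] == pytest.approx(
            report.scores["dual_knee_amplitude_mean"])

    def test_constant_feature_scores_zero_with_warning(self):
        table = _linear_table(informative=["dual_knee_amplitude_mean"])
        table["single_answer_rate"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            report = feature_importance(table, SVR, seed=3)
        assert report.scores["single_answer_rate"] == 0.0


class TestAblation:
    def test_ten_columns_remain(self):
        table = _linear_table(informative=["dual_knee_amplitude_mean"])
        entry = ablate_feature(table, "knee_amplitude_mean", SVR, seed=0)
        assert entry.n_columns == 10

    def test_unknown_feature_type_rejected(self):
        table = _linear_table()
        with pytest.raises(ValidationError):
            ablate_feature(table, "stride_length", SVR, seed=0)

    def test_ablation_preserves_trial_count_for_all_types(self):
        table = _linear_table(n_subjects=6, trials=2)
        report = ablation_report(table, SVR, seed=0)
        assert [e.feature_type for e in report.entries] == list(BASE_FEATURE_TYPES)
        assert all(e.n_columns == 10 for e in report.entries)


class TestFeatureSets:
    def test_report_structure(self):
        table = _linear_table(n_subjects=8, trials=2)
        report = compare_feature_sets(table, SVR, seed=0)
        assert set(report.dimensions) == {"single_physical", "single_cognitive",
                                          "single_all", "dual", "combined"}
        assert [report.dimensions[k] for k in
                ("single_physical", "single_cognitive", "single_all", "dual",
                 "combined")] == [4, 2, 6, 6, 12]


class TestTrialGroups:
    @staticmethod
    def _practised_table(trial_counts, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        scores = [16, 20, 27, 30] * ((len(trial_counts) + 3) // 4)
        for i, count in enumerate(trial_counts):
            mmse = scores[i]
            for k in range(1, count + 1):
                feats = {c: float(rng.normal()) for c in FEATURE_NAMES}
                feats["dual_knee_amplitude_mean"] = 0.1 * mmse + float(
                    rng.normal(scale=0.1))
                rows.append({"subject_id": f"S{i:02d}", "trial_index": k,
                             **feats, "mmse": mmse})
        return pd.DataFrame(rows)

    def test_hundred_trial_subject_contributes_twenty_per_group(self):
        table = self._practised_table([100, 100, 100, 100])
        report = trial_group_analysis(table, SVR, seed=0)
        assert report.n_subjects == 4
        assert [g.trial_range for g in report.groups] == list(TRIAL_GROUPS)
        assert all(g.n_trials == 80 for g in report.groups)  # 4 x 20

    def test_ninety_nine_trial_subject_is_excluded(self):
        table = self._practised_table([100, 100, 99, 100])
        report = trial_group_analysis(table, SVR, seed=0)
        assert report.n_subjects == 3

    def test_strict_filter_demands_more_than_min(self):
        table = self._practised_table([100, 101, 101, 101])
        report = trial_group_analysis(table, SVR, seed=0, strict=True)
        assert report.n_subjects == 3

    def test_group_reports_cover_physical_means(self):
        table = self._practised_table([100, 100, 100, 100])
        report = trial_group_analysis(table, SVR, seed=0)
        for g in report.groups:
            assert set(g.physical_means) == set(PHYSICAL_FEATURES)

    def test_invariant_to_subject_ordering(self):
        table = self._practised_table([100, 100, 100, 100])
        shuffled = table.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = trial_group_analysis(table, SVR, seed=1)
        b = trial_group_analysis(shuffled, SVR, seed=1)
        for ga, gb in zip(a.groups, b.groups):
            assert ga.metrics == gb.metrics
            assert ga.physical_means == pytest.approx(gb.physical_means)

    def test_learning_raises_knee_importance_until_plateau(self):
        """With the practice gain active, the knee-amplitude importance is
        higher in the post-plateau trial groups than in the first group."""
        from dualgait.pipeline import simulate_feature_table
        from dualgait.synthetic_cohort import CohortConfig
        cfg = CohortConfig(
            n_subjects=10, trials_per_subject=105, frame_rate_hz=15.0,
            mmse_mean=24.0, mmse_sd=5.0, amplitude_slope_rad=0.004,
            learning_gain_rad=0.006, frame_noise_m=0.0)
        _, table = simulate_feature_table(cfg, np.random.default_rng(17))
        report = trial_group_analysis(table, SVR, seed=17)
        imps = [g.importance["single_knee_amplitude_mean"]
                for g in report.groups]
        assert np.mean(imps[2:]) > imps[0]

    def test_no_qualifying_subject_is_an_error(self):
        table = self._practised_table([60, 50, 40, 70])
        with pytest.raises(ValidationError):
            trial_group_analysis(table, SVR, seed=0)


class TestContrast:
    @staticmethod
    def _experience_table(n_per_stratum=8, trials=45, gain=0.0, seed=0):
        """Feature table with an optional knee-amplitude practice gain for
        the high-MMSE stratum only."""
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(2 * n_per_stratum):
            high = i >= n_per_stratum
            mmse = int(rng.integers(25, 31)) if high else int(rng.integers(15, 24))
            base_amp = 0.4 + rng.normal(scale=0.05)
            for k in range(1, trials + 1):
                feats = {c: float(rng.normal(scale=0.02)) for c in FEATURE_NAMES}
                bump = gain * min(k, 40) if high else 0.0
                feats["single_knee_amplitude_mean"] = base_amp + bump + float(
                    rng.normal(scale=0.01))
                feats["dual_knee_amplitude_mean"] = base_amp + bump + float(
                    rng.normal(scale=0.01))
                feats["single_step_interval_mean"] = 0.6 + float(
                    rng.normal(scale=0.01))
                feats["dual_step_interval_mean"] = 0.65 + float(
                    rng.normal(scale=0.01))
                rows.append({"subject_id": f"S{i:02d}", "trial_index": k,
                             **feats, "mmse": mmse})
        return pd.DataFrame(rows)

    def test_bonferroni_arithmetic(self):
        assert bonferroni(0.01, 8) == pytest.approx(0.08)
        assert bonferroni(0.5, 8) == 1.0

    def test_report_covers_all_strata_and_measures(self):
        report = experience_contrast(self._experience_table())
        assert len(report.table) == 2 * len(CONTRAST_MEASURES)
        assert report.n_tests == 8

    def test_gain_detected_only_in_high_stratum(self):
        report = experience_contrast(
            self._experience_table(gain=0.005, seed=3))
        t = report.table.set_index(["stratum", "measure"])
        assert t.loc[("high", "knee_amplitude_single"), "significant_05"]
        assert t.loc[("high", "knee_amplitude_dual"), "significant_05"]
        assert not t.loc[("low", "knee_amplitude_single"), "significant_05"]

    def test_null_type_one_error_is_controlled(self):
        """Under no true effect at most a small fraction of repeated cohorts
        shows any Bonferroni-significant contrast."""
        hits = 0
        for rep in range(100):
            report = experience_contrast(
                self._experience_table(n_per_stratum=5, trials=45, gain=0.0,
                                       seed=1000 + rep))
            hits += bool(report.table["significant_05"].any())
        assert hits <= 10

    def test_small_stratum_flagged_undefined(self):
        table = self._experience_table(n_per_stratum=8)
        table = table[(table["mmse"] >= 24) | (table["subject_id"] == "S00")]
        report = experience_contrast(table)
        low = report.table[report.table["stratum"] == "low"]
        assert low["p_raw"].isna().all()
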