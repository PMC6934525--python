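"""Secondary cohort analyses around the MMSE estimator.

* **Feature importance** — per feature, the coefficient of determination
  (R^2) of a univariate linear fit of the cross-validated predictions on
  that feature.  This asks "how much of what the model predicts does this
  one feature explain?"; a permutation-importance alternative on a
  full-data fit is available behind ``method="permutation"``.
* **Leave-feature-out ablation** — a base feature type is removed from
  *both* task contexts (12 -> 10 columns) and LOSO CV is re-run; the drop in
  recall + specificity measures how much the classifier leaned on it.
* **Feature-set comparison** — LOSO metrics for the five canonical column
  subsets: single-physical (4), single-cognitive (2), single-all (6),
  dual (6) and combined (12).
* **Trial-group transitions** — subjects with at least ``min_trials`` trials
  are split into five 20-trial groups (1-20 ... 81-100); metrics, importance
  and physical-feature means are computed per group to expose learning.
* **Experience contrasts** — per MMSE stratum (<24 / >=24) and measure,
  first-trial values are compared against per-subject means of trials >= 41
  with two-tailed t-tests (Welch by default) under Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .mmse_estimation import (EstimationResult, RegressorSpec, evaluate,
                              feature_columns, fit_regressor, loso_cv,
                              predict_scores)
from .types import (BASE_FEATURE_TYPES, FEATURE_NAMES, FEATURE_SETS,
                    MMSE_THRESHOLD, ClassificationMetrics)

#: The gait (physical) feature columns reported by the trial-group analysis.
PHYSICAL_FEATURES = tuple(c for c in FEATURE_NAMES
                          if "step_interval" in c or "knee_amplitude" in c)

#: Five 20-trial groups partitioning trials 1-100.
TRIAL_GROUPS = ((1, 20), (21, 40), (41, 60), (61, 80), (81, 100))


# ---------------------------------------------------------------------------
# importance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImportanceReport:
    """Per-feature importance scores in [0, 1]."""

    scores: dict[str, float]
    method: str = "r2_prediction"


def _univariate_r2(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def feature_importance(dataset: pd.DataFrame, spec: RegressorSpec,
                       seed: int = 0, method: str = "r2_prediction",
                       result: EstimationResult | None = None
                       ) -> ImportanceReport:
    """Importance of each feature column for the estimator's output.

    The default scores each feature by the R^2 of a univariate linear fit
    of the LOSO-CV predictions on that feature (pass a precomputed
    ``result`` to avoid re-running the CV).  Constant features score 0 with
    a warning.
    """
    cols = feature_columns(dataset)
    if method == "r2_prediction":
        if result is None:
            result = loso_cv(dataset, spec, seed=seed)
        df = dataset.sort_values(
            ["subject_id", "trial_index"] if "trial_index" in dataset.columns
            else ["subject_id"], kind="mergesort").reset_index(drop=True)
        preds = result.table["predicted_mmse"].to_numpy()
        scores = {}
        for c in cols:
            x = df[c].to_numpy(dtype=float)
            if np.std(x) == 0:
                warnings.warn(f"feature {c} is constant; importance set to 0")
                scores[c] = 0.0
            else:
                scores[c] = _univariate_r2(x, preds)
        return ImportanceReport(scores=scores, method=method)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        X = dataset[cols].to_numpy(dtype=float)
        y = dataset["mmse"].to_numpy(dtype=float)
        model = fit_regressor(spec, X, y, rng)
        base = float(np.mean((predict_scores(model, X) - y) ** 2))
        scores = {}
        for j, c in enumerate(cols):
            errs = []
            for _ in range(5):
                Xp = X.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                errs.append(float(np.mean((predict_scores(model, Xp) - y) ** 2)))
            scores[c] = max(float(np.mean(errs)) - base, 0.0)
        total = sum(scores.values())
        if total > 0:
            scores = {c: v / total for c, v in scores.items()}
        return ImportanceReport(scores=scores, method=method)
    raise ConfigurationError(f"unknown importance method {method!r}")


# ---------------------------------------------------------------------------
# ablation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AblationEntry:
    """Metrics after removing one base feature type from both contexts."""

    feature_type: str
    n_columns: int
    metrics: ClassificationMetrics
    delta_sum: float  # metrics.sum - full-model sum


@dataclass(frozen=True)
class AblationReport:
    full_metrics: ClassificationMetrics
    entries: list[AblationEntry]


def ablate_feature(dataset: pd.DataFrame, feature_type: str,
                   spec: RegressorSpec, seed: int = 0,
                   full_metrics: ClassificationMetrics | None = None
                   ) -> AblationEntry:
    """LOSO metrics on the 10 columns remaining after dropping one type."""
    if feature_type not in BASE_FEATURE_TYPES:
        raise ValidationError(f"unknown feature type {feature_type!r}; "
                              f"expected one of {BASE_FEATURE_TYPES}")
    dropped = [f"single_{feature_type}", f"dual_{feature_type}"]
    reduced = dataset.drop(columns=[c for c in dropped if c in dataset.columns])
    n_cols = len(feature_columns(reduced))
    metrics = evaluate(loso_cv(reduced, spec, seed=seed))
    if full_metrics is None:
        full_metrics = evaluate(loso_cv(dataset, spec, seed=seed))
    return AblationEntry(feature_type=feature_type, n_columns=n_cols,
                         metrics=metrics,
                         delta_sum=metrics.sum - full_metrics.sum)


def ablation_report(dataset: pd.DataFrame, spec: RegressorSpec,
                    seed: int = 0,
                    feature_types: tuple[str, ...] = BASE_FEATURE_TYPES
                    ) -> AblationReport:
    full = evaluate(loso_cv(dataset, spec, seed=seed))
    entries = [ablate_feature(dataset, ft, spec, seed=seed, full_metrics=full)
               for ft in feature_types]
    return AblationReport(full_metrics=full, entries=entries)


# ---------------------------------------------------------------------------
# feature sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSetReport:
    """LOSO metrics per canonical feature subset."""

    metrics: dict[str, ClassificationMetrics]
    dimensions: dict[str, int]


def compare_feature_sets(dataset: pd.DataFrame, spec: RegressorSpec,
                         seed: int = 0) -> FeatureSetReport:
    metrics, dims = {}, {}
    meta = [c for c in ("subject_id", "trial_index", "mmse")
            if c in dataset.columns]
    for name, cols in FEATURE_SETS.items():
        sub = dataset[meta + list(cols)]
        metrics[name] = evaluate(loso_cv(sub, spec, seed=seed))
        dims[name] = len(cols)
    return FeatureSetReport(metrics=metrics, dimensions=dims)


# ---------------------------------------------------------------------------
# trial groups
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialGroupResult:
    trial_range: tuple[int, int]
    n_trials: int
    metrics: ClassificationMetrics
    importance: dict[str, float]
    physical_means: dict[str, float]


@dataclass(frozen=True)
class GroupTransitionReport:
    groups: list[TrialGroupResult]
    n_subjects: int


def trial_group_analysis(dataset: pd.DataFrame, spec: RegressorSpec,
                         seed: int = 0, min_trials: int = 100,
                         strict: bool = False) -> GroupTransitionReport:
    """Per-trial-group metrics for well-practised subjects.

    Subjects are retained when their trial count reaches ``min_trials``
    (``strict=True`` demands strictly more).  Their trials up to index 100
    are split into the five canonical 20-trial groups; LOSO metrics,
    importance scores and physical-feature means are computed per group.
    """
    counts = dataset.groupby("subject_id")["trial_index"].count()
    keep = counts[counts > min_trials].index if strict \
        else counts[counts >= min_trials].index
    if len(keep) < 2:
        raise ValidationError(
            f"fewer than 2 subjects reach {min_trials} trials")
    df = dataset[dataset["subject_id"].isin(keep)]
    groups = []
    for lo, hi in TRIAL_GROUPS:
        sub = df[(df["trial_index"] >= lo) & (df["trial_index"] <= hi)]
        result = loso_cv(sub, spec, seed=seed)
        imp = feature_importance(sub, spec, seed=seed, result=result)
        phys = {c: float(sub[c].mean()) for c in PHYSICAL_FEATURES
                if c in sub.columns}
        groups.append(TrialGroupResult(
            trial_range=(lo, hi), n_trials=len(sub),
            metrics=evaluate(result), importance=imp.scores,
            physical_means=phys))
    return GroupTransitionReport(groups=groups, n_subjects=len(keep))


# ---------------------------------------------------------------------------
# experience contrasts
# ---------------------------------------------------------------------------

#: Measures contrasted between the first trial and experienced trials.
CONTRAST_MEASURES = {
    "step_interval_single": "single_step_interval_mean",
    "step_interval_dual": "dual_step_interval_mean",
    "knee_amplitude_single": "single_knee_amplitude_mean",
    "knee_amplitude_dual": "dual_knee_amplitude_mean",
}


@dataclass(frozen=True)
class ContrastReport:
    """First-trial vs experienced contrasts with Bonferroni correction.

    ``table`` has one row per (stratum, measure) with group means, the t
    statistic, raw and adjusted p-values and significance flags at 0.05 and
    0.001; ``n_tests`` is the Bonferroni family size (all contrasts of one
    invocation).
    """

    table: pd.DataFrame
    n_tests: int


def experience_contrast(dataset: pd.DataFrame, experienced_from: int = 41,
                        equal_var: bool = False) -> ContrastReport:
    """Compare first-trial behaviour with well-experienced behaviour.

    For each MMSE stratum (<24 vs >=24) and each of the four gait measures,
    a two-sample two-tailed t-test (Welch's by default; ``equal_var=True``
    pools variances) compares subjects' first-trial values against their
    per-subject means over trials >= ``experienced_from``.  Adjusted
    p-values are ``min(1, m * p)`` with m the number of computed contrasts.
    A stratum with fewer than 2 subjects in either group is flagged
    undefined (NaN statistics).
    """
    rows = []
    strata = {"low": dataset["mmse"] < MMSE_THRESHOLD,
              "high": dataset["mmse"] >= MMSE_THRESHOLD}
    for stratum, mask in strata.items():
        sub = dataset[mask]
        first = sub[sub["trial_index"] == 1]
        exp = (sub[sub["trial_index"] >= experienced_from]
               .groupby("subject_id").mean(numeric_only=True))
        for measure, col in CONTRAST_MEASURES.items():
            a = first[col].to_numpy(dtype=float)
            b = exp[col].to_numpy(dtype=float)
            row = {"stratum": stratum, "measure": measure,
                   "n_first": len(a), "n_experienced": len(b),
                   "mean_first": float(np.mean(a)) if len(a) else np.nan,
                   "mean_experienced": float(np.mean(b)) if len(b) else np.nan}
            if len(a) >= 2 and len(b) >= 2:
                t, p = stats.ttest_ind(b, a, equal_var=equal_var)
                row.update(t_stat=float(t), p_raw=float(p))
            else:
                row.update(t_stat=np.nan, p_raw=np.nan)
            rows.append(row)
    table = pd.DataFrame(rows)
    n_tests = int(table["p_raw"].notna().sum())
    table["p_adjusted"] = np.minimum(1.0, table["p_raw"] * max(n_tests, 1))
    table["significant_05"] = table["p_adjusted"] < 0.05
    table["significant_001"] = table["p_adjusted"] < 0.001
    return ContrastReport(table=table, n_tests=n_tests)


def bonferroni(p_raw: float, n_tests: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    return min(1.0, n_tests * p_raw)
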