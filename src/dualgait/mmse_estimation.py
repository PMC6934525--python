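"""MMSE estimation: regression from the 12 features, then thresholding.

The screening problem (flag subjects scoring below 24) is solved by first
regressing the MMSE score on the feature vector and thresholding the
estimate — regression-then-threshold discriminates better than direct
binary classification on this task.  Three regressor families are offered:

* ``linear_svr`` — epsilon-insensitive linear support-vector regression
  (L2-regularized, L1 loss), features standardized on training-fold
  statistics;
* ``random_forest`` — 500 trees, p/3 features per split, no scaling;
* ``bayes_nn`` — the Bayesian-regularized one-hidden-layer network of
  :mod:`dualgait.bayes_nn`, with the hidden-layer width chosen from a small
  grid (1-3 by default) by an inner 10-fold cross-validated RMSE search
  within the training data.

Generalization is measured by leave-one-subject-out cross-validation
(LOSO): each fold holds out *all* trials of one subject, so a subject never
informs its own prediction.  Predictions are clipped to [0, 30]; recall is
computed with the low-MMSE class (< 24) as positive, specificity on the
high class, per trial.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.compose import TransformedTargetRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVR

from .bayes_nn import BayesianRegularizedNN
from .errors import (ConfigurationError, DegenerateFitError, SchemaError,
                     ValidationError)
from .types import (CLASS_HIGH, CLASS_LOW, FEATURE_NAMES,
                    ClassificationMetrics, mmse_class)

META_COLUMNS = ("subject_id", "trial_index", "mmse")

LINEAR_SVR = "linear_svr"
RANDOM_FOREST = "random_forest"
BAYES_NN = "bayes_nn"
FAMILIES = (LINEAR_SVR, RANDOM_FOREST, BAYES_NN)


@dataclass(frozen=True)
class RegressorSpec:
    """Which regressor family to fit, and its knobs."""

    family: str = BAYES_NN
    # linear_svr
    c: float = 1.0
    epsilon: float = 0.1
    # random_forest
    n_trees: int = 500
    max_features: float = 1.0 / 3.0
    # bayes_nn
    neuron_grid: tuple[int, ...] = (1, 2, 3)
    inner_cv_folds: int = 10
    nn_max_iter: int = 15
    nn_inner_max_iter: int = 8  # ranking widths needs fewer LM iterations

    def validate(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown regressor family {self.family!r}")
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if not self.neuron_grid:
            raise ConfigurationError("neuron_grid must be non-empty")
        if self.inner_cv_folds < 2:
            raise ConfigurationError("inner_cv_folds must be >= 2")


@dataclass
class EstimationResult:
    """Per-trial cross-validated predictions plus binary labels."""

    table: pd.DataFrame  # subject_id, trial_index, true_mmse, predicted_mmse,
    #                      true_class, predicted_class

    def to_subject_level(self) -> "EstimationResult":
        """Aggregate to one row per subject by majority vote of the
        predicted class (mean prediction as the score)."""

        def agg(g: pd.DataFrame) -> pd.Series:
            votes_low = (g["predicted_class"] == CLASS_LOW).mean()
            pred = float(g["predicted_mmse"].mean())
            return pd.Series({
                "trial_index": 0,
                "true_mmse": g["true_mmse"].iloc[0],
                "predicted_mmse": pred,
                "true_class": g["true_class"].iloc[0],
                "predicted_class": CLASS_LOW if votes_low > 0.5 else CLASS_HIGH,
            })

        out = (self.table.groupby("subject_id", sort=True)
               .apply(agg, include_groups=False).reset_index())
        return EstimationResult(table=out)


def _check_matrix(X: np.ndarray, y: np.ndarray | None = None) -> None:
    if not np.all(np.isfinite(X)):
        raise ValidationError("feature matrix contains non-finite values")
    if y is not None:
        if not np.all(np.isfinite(y)):
            raise ValidationError("targets contain non-finite values")
        if np.unique(y).size < 2:
            raise DegenerateFitError("need >= 2 distinct target values")


def _select_n_hidden(spec: RegressorSpec, X: np.ndarray, y: np.ndarray,
                     seed: int) -> int:
    """Grid-search the hidden-layer width by inner k-fold CV RMSE."""
    grid = sorted(spec.neuron_grid)
    if len(grid) == 1 or X.shape[0] < 2 * spec.inner_cv_folds:
        return grid[0]
    folds = min(spec.inner_cv_folds, X.shape[0])
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed % (2 ** 31))
    splits = list(kf.split(X))
    best_h, best_rmse = grid[0], np.inf
    for h in grid:
        sq_errs = []
        for j, (tr, va) in enumerate(splits):
            if np.unique(y[tr]).size < 2:
                continue
            net = BayesianRegularizedNN(
                n_hidden=h, max_iter=spec.nn_inner_max_iter,
                random_state=(seed + 7 * h + j) % (2 ** 31))
            net.fit(X[tr], y[tr])
            sq_errs.append(float(np.mean((net.predict(X[va]) - y[va]) ** 2)))
        if not sq_errs:
            continue
        rmse = float(np.sqrt(np.mean(sq_errs)))
        if rmse < best_rmse - 1e-12:
            best_rmse, best_h = rmse, h
    return best_h


def fit_regressor(spec: RegressorSpec, X: np.ndarray, y: np.ndarray,
                  rng: np.random.Generator):
    """Fit one regressor on a feature matrix; returns a predict-capable model."""
    spec.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_matrix(X, y)
    seed = int(rng.integers(0, 2 ** 31 - 1))
    if spec.family == LINEAR_SVR:
        # target standardized too: liblinear regularizes the intercept, so
        # raw 0-30 targets would be under-fitted
        model = TransformedTargetRegressor(
            regressor=make_pipeline(
                StandardScaler(),
                LinearSVR(C=spec.c, epsilon=spec.epsilon,
                          loss="epsilon_insensitive", max_iter=20000,
                          random_state=seed)),
            transformer=StandardScaler())
        model.fit(X, y.reshape(-1))
        return model
    if spec.family == RANDOM_FOREST:
        model = RandomForestRegressor(
            n_estimators=spec.n_trees, max_features=spec.max_features,
            random_state=seed, n_jobs=1)
        model.fit(X, y)
        return model
    h = _select_n_hidden(spec, X, y, seed)
    net = BayesianRegularizedNN(n_hidden=h, max_iter=spec.nn_max_iter,
                                random_state=(seed + 1) % (2 ** 31))
    net.fit(X, y)
    return net


def predict_scores(model, X: np.ndarray) -> np.ndarray:
    """Predict MMSE scores, clipped to the valid [0, 30] range."""
    X = np.asarray(X, dtype=float)
    n_expected = getattr(model, "n_features_in_", None)
    if n_expected is None and hasattr(model, "steps"):  # sklearn pipeline
        n_expected = model.steps[0][1].n_features_in_
    if n_expected is not None and (X.ndim != 2 or X.shape[1] != n_expected):
        raise SchemaError(f"expected {n_expected} feature columns")
    return np.clip(model.predict(X), 0.0, 30.0)


def feature_columns(dataset: pd.DataFrame) -> list[str]:
    """Feature columns of a table: canonical 12 first, extras after."""
    canonical = [c for c in FEATURE_NAMES if c in dataset.columns]
    extras = [c for c in dataset.columns
              if c not in FEATURE_NAMES and c not in META_COLUMNS]
    return canonical + extras


def _subject_seed(master_seed: int, subject_id: str) -> int:
    return (master_seed * 1_000_003
            + zlib.crc32(str(subject_id).encode("utf-8"))) % (2 ** 31)


def loso_cv(dataset: pd.DataFrame, spec: RegressorSpec,
            seed: int = 0) -> EstimationResult:
    """Leave-one-subject-out cross-validated predictions.

    One fold per subject; every trial receives exactly one prediction and a
    subject's trials never appear in its own training set.  The dataset is
    canonically sorted and per-fold randomness is keyed on
    ``(seed, subject_id)``, so trial order in the input is irrelevant.
    """
    required = {"subject_id", "mmse"}
    if not required.issubset(dataset.columns):
        raise ValidationError(f"dataset must contain columns {sorted(required)}")
    df = dataset.sort_values(
        ["subject_id", "trial_index"] if "trial_index" in dataset.columns
        else ["subject_id"], kind="mergesort").reset_index(drop=True)
    cols = feature_columns(df)
    if not cols:
        raise ValidationError("dataset has no feature columns")
    X = df[cols].to_numpy(dtype=float)
    y = df["mmse"].to_numpy(dtype=float)
    subjects = np.asarray(sorted(df["subject_id"].unique()))
    if subjects.size < 2:
        raise ValidationError("LOSO requires >= 2 subjects")
    _check_matrix(X, y)
    preds = np.empty(len(df))
    for subject in subjects:
        test = (df["subject_id"] == subject).to_numpy()
        train = ~test
        rng = np.random.default_rng(_subject_seed(seed, subject))
        model = fit_regressor(spec, X[train], y[train], rng)
        preds[test] = predict_scores(model, X[test])
    table = pd.DataFrame({
        "subject_id": df["subject_id"],
        "trial_index": df.get("trial_index", pd.Series(np.arange(1, len(df) + 1))),
        "true_mmse": y,
        "predicted_mmse": preds,
        "true_class": [mmse_class(v) for v in y],
        "predicted_class": [mmse_class(v) for v in preds],
    })
    return EstimationResult(table=table)


def evaluate(result: EstimationResult) -> ClassificationMetrics:
    """Recall (positive = low MMSE), specificity and their sum, per trial.

    A metric whose truth class is absent is NaN (undefined), not zero.
    """
    t = result.table
    if len(t) == 0:
        raise ValidationError("empty estimation result")
    truth_low = t["true_class"] == CLASS_LOW
    pred_low = t["predicted_class"] == CLASS_LOW
    tp = int((truth_low & pred_low).sum())
    fn = int((truth_low & ~pred_low).sum())
    tn = int((~truth_low & ~pred_low).sum())
    fp = int((~truth_low & pred_low).sum())
    recall = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return ClassificationMetrics(recall=recall, specificity=specificity)
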