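"""Per-day classification study: morphology-only vs morphology+mechanics.

Protocol: for each of ``n_runs`` runs, reshuffle a stratified ``n_folds``
split; in every outer fold, standardize features on the training portion
only, select RBF-SVM hyperparameters by exhaustive grid search with an
inner stratified cross-validation on the training portion, refit on the
full training portion, and score the held-out fold.  With the default
100 runs x 10 folds, 1000 models are trained per feature set; the report
carries the mean test accuracy and its standard error over those 1000
fold accuracies, plus recall/precision/F1 for the cancer class pooled
over all held-out predictions.

Ties in the grid search are broken by declared grid order (first best
entry wins).  No held-out sample influences scaling or hyperparameter
selection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features_mech import FEATURE_COLUMNS_MECH, FEATURE_COLUMNS_MORPH
from .io import ConfigurationError, MechSpheroidError

log = logging.getLogger("mechspheroid")

FEATURE_SETS = {
    "morphology_only": FEATURE_COLUMNS_MORPH,
    "combined": FEATURE_COLUMNS_MORPH + FEATURE_COLUMNS_MECH,
}

POSITIVE_CLASS = "cancer"


@dataclass(frozen=True)
class ExperimentConfig:
    """Protocol parameters for one classification experiment."""
    feature_set: str = "combined"
    n_runs: int = 100
    n_folds: int = 10
    inner_folds: int = 5
    C_grid: tuple = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple = (0.001, 0.01, 0.1, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.feature_set not in FEATURE_SETS:
            raise ConfigurationError(
                f"feature_set must be one of {sorted(FEATURE_SETS)}")
        if self.n_runs < 1 or self.n_folds < 2 or self.inner_folds < 2:
            raise ConfigurationError("invalid protocol sizes")

    @property
    def n_models(self) -> int:
        return self.n_runs * self.n_folds


@dataclass
class ClassificationReport:
    """Outcome of one experiment (one day, one feature set)."""
    feature_set: str
    day: int | None
    fold_accuracies: np.ndarray
    recall: float | None
    precision: float | None
    f1: float | None
    n_models: int = field(init=False)
    mean_accuracy: float = field(init=False)
    sem_accuracy: float = field(init=False)

    def __post_init__(self):
        acc = np.asarray(self.fold_accuracies, dtype=float)
        self.n_models = acc.size
        self.mean_accuracy = float(acc.mean())
        self.sem_accuracy = float(acc.std(ddof=1) / math.sqrt(acc.size))


# ---------------------------------------------------------------------------
# Protocol building blocks
# ---------------------------------------------------------------------------

def stratified_fold_indices(labels, n_folds: int, seed: int) -> np.ndarray:
    """Fold assignment (0..n_folds-1 per sample) of a shuffled stratified
    K-fold split; deterministic for a given seed."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        raise ConfigurationError(
            f"smallest class ({counts.min()}) has fewer members than "
            f"n_folds ({n_folds})")
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True,
                               random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(
            splitter.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold
    return assignment


def standardize(train_features, apply_to):
    """Remove the mean and scale to unit variance, fitted on training rows
    only and applied to both partitions.

    Zero-variance training features map to 0 (logged).  Returns
    ``(train_scaled, applied_scaled, scaler)``.
    """
    train = np.asarray(train_features, dtype=float)
    other = np.asarray(apply_to, dtype=float)
    if train.ndim == 1:
        train = train[:, None]
    if other.ndim == 1:
        other = other[:, None]
    if train.shape[0] < 2:
        raise MechSpheroidError("standardization needs >= 2 training rows")
    scaler = StandardScaler().fit(train)
    zero_var = np.flatnonzero(scaler.var_ == 0)
    if zero_var.size:
        log.warning("zero-variance feature column(s) %s map to 0",
                    zero_var.tolist())
    return scaler.transform(train), scaler.transform(other), scaler


def _grid_search_rbf(X, y, config: ExperimentConfig, seed: int):
    """Exhaustive (C, gamma) search by inner stratified CV accuracy.

    Ties broken by declared grid order: the first grid entry attaining the
    best mean inner accuracy wins.
    """
    inner = StratifiedKFold(n_splits=config.inner_folds, shuffle=True,
                            random_state=seed)
    splits = list(inner.split(X, y))
    best_score, best_params = -1.0, None
    for C in config.C_grid:
        for gamma in config.gamma_grid:
            scores = []
            for tr, va in splits:
                clf = SVC(C=C, gamma=gamma, kernel="rbf")
                clf.fit(X[tr], y[tr])
                scores.append(clf.score(X[va], y[va]))
            mean_score = float(np.mean(scores))
            if mean_score > best_score:       # strict: first entry wins ties
                best_score, best_params = mean_score, (C, gamma)
    return best_params


def run_experiment(features: pd.DataFrame,
                   config: ExperimentConfig,
                   day: int | None = None) -> ClassificationReport:
    """Run the full repeated nested-CV protocol on one day's features.

    ``features`` must carry a ``label`` (or ``line``) column with values
    'normal'/'cancer' and the feature columns of the chosen set; if
    ``day`` is given the table is filtered to that day first.
    """
    df = features
    if day is not None:
        df = df[df["day"] == day]
    label_col = "label" if "label" in df.columns else "line"
    cols = FEATURE_SETS[config.feature_set]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ConfigurationError(f"features table missing columns {missing}")
    if df[cols].isna().any().any():
        raise MechSpheroidError("features table contains missing values")
    X_all = df[cols].to_numpy(dtype=float)
    y_all = df[label_col].to_numpy()
    _, counts = np.unique(y_all, return_counts=True)
    if counts.min() < config.n_folds:
        raise ConfigurationError("each class needs >= n_folds members")

    accuracies = []
    pooled_truth, pooled_pred = [], []
    for run in range(config.n_runs):
        run_seed = (config.seed + 1009 * run) % (2 ** 31)
        folds = stratified_fold_indices(y_all, config.n_folds, run_seed)
        for fold in range(config.n_folds):
            test = folds == fold
            train = ~test
            if len(np.unique(y_all[train])) < 2:
                log.warning("run %d fold %d skipped: single-class training "
                            "fold", run, fold)
                continue
            X_train, X_test, _ = standardize(X_all[train], X_all[test])
            params = _grid_search_rbf(X_train, y_all[train], config,
                                      seed=run_seed + fold)
            clf = SVC(C=params[0], gamma=params[1], kernel="rbf")
            clf.fit(X_train, y_all[train])
            pred = clf.predict(X_test)
            accuracies.append(float(np.mean(pred == y_all[test])))
            pooled_truth.extend(y_all[test])
            pooled_pred.extend(pred)

    metrics = classification_metrics(pooled_truth, pooled_pred)
    return ClassificationReport(
        feature_set=config.feature_set, day=day,
        fold_accuracies=np.asarray(accuracies),
        recall=metrics["recall"], precision=metrics["precision"],
        f1=metrics["f1"],
    )


def run_study(features: pd.DataFrame, config: ExperimentConfig,
              days=None, feature_sets=("morphology_only", "combined")
              ) -> list[ClassificationReport]:
    """Run the experiment for each day and each feature set."""
    from dataclasses import replace
    if days is None:
        days = sorted(features["day"].unique())
    reports = []
    for day in days:
        for fs in feature_sets:
            cfg = replace(config, feature_set=fs)
            reports.append(run_experiment(features, cfg, day=day))
    return reports


# ---------------------------------------------------------------------------
# Metric calculus
# ---------------------------------------------------------------------------

def classification_metrics(truth, predictions,
                           positive_class: str = POSITIVE_CLASS) -> dict:
    """Recall, precision and F1 for the positive (cancer) class.

    recall = TP/(TP+FN); precision = TP/(TP+FP); f1 = 2PR/(P+R).
    Zero-denominator cases are reported as ``None`` (undefined), never 0.
    """
    truth = np.asarray(truth)
    predictions = np.asarray(predictions)
    if truth.size == 0:
        raise MechSpheroidError("empty inputs")
    if truth.shape != predictions.shape:
        raise MechSpheroidError("truth/prediction length mismatch")
    tp = int(np.sum((truth == positive_class) & (predictions == positive_class)))
    fn = int(np.sum((truth == positive_class) & (predictions != positive_class)))
    fp = int(np.sum((truth != positive_class) & (predictions == positive_class)))
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    f1 = f1_from_recall_precision(recall, precision)
    return {"recall": recall, "precision": precision, "f1": f1}


def f1_from_recall_precision(recall: float | None,
                             precision: float | None) -> float | None:
    """Harmonic mean of recall and precision; None if either is undefined
    or both are zero."""
    if recall is None or precision is None:
        return None
    if recall + precision == 0:
        return None
    return 2.0 * precision * recall / (precision + recall)


def train_val_test_counts(n: int) -> tuple[int, int, int]:
    """Split a sample count 7:1:2 into (train, validation, test).

    test = round(0.2 n), validation = floor(0.1 n), train = the rest;
    reproduces (118, 16, 34) at n = 168.
    """
    if n < 10:
        raise MechSpheroidError("n must be >= 10 for a 7:1:2 split")
    test = int(round(0.2 * n))
    val = int(math.floor(0.1 * n))
    train = n - val - test
    return train, val, test
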