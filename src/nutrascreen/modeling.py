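"""Seeded model tuning, out-of-fold prediction, evaluation, calibration.

For each scaffold-split seed the combined train+val subset drives a
randomized hyperparameter search (stratified 5-fold CV, ROC-AUC objective,
25 sampled configurations by default); the winning configuration is refit on
all train+val rows and evaluated once on the held-out test set. Decision
thresholds are derived from out-of-fold predictions only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import loguniform
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    average_precision_score,
    balanced_accuracy_score,
    matthews_corrcoef,
    roc_auc_score,
)
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold, cross_val_predict
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "ModelConfig",
    "TunedModel",
    "UNDEFINED",
    "tune_and_fit",
    "oof_predict",
    "evaluate",
    "calibrate",
    "select_threshold",
    "threshold_metrics",
    "aggregate_seeds",
    "make_estimator",
    "default_search_space",
]

# Marker for metrics that are undefined when only one class is present.
UNDEFINED = None

MODEL_FAMILIES = (
    "random_forest",
    "logistic_regression",
    "gradient_boosting",
    "neural_network",
    "xgboost",
)


@dataclass
class ModelConfig:
    """Search settings for one model family and split seed."""

    family: str = "random_forest"
    search_space: dict | None = None
    n_iter: int = 25
    cv_folds: int = 5
    seed: int = 1

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.n_iter < 1 or self.cv_folds < 2:
            raise ValueError("n_iter must be ≥1 and cv_folds ≥2")
        if self.search_space is None:
            self.search_space = default_search_space(self.family)


@dataclass
class TunedModel:
    """Fitted best model plus the search record for one (family, seed)."""

    model: object
    best_params: dict
    best_cv_auc: float
    config: ModelConfig


def default_search_space(family: str) -> dict:
    """Randomized-search distributions per family.

    The tuned dimensions follow standard practice for fingerprint QSAR:
    ensemble size / depth / split constraints / feature subsampling for
    forests; regularization strength and penalty for logistic regression;
    stages, learning rate and depth for boosting; architecture and
    regularization for the small feed-forward net.
    """
    if family == "random_forest":
        return {
            "n_estimators": [100, 200, 300, 500],
            "max_depth": [None, 8, 16, 32],
            "min_samples_split": [2, 5, 10],
            "min_samples_leaf": [1, 2, 4],
            "max_features": ["sqrt", "log2", 0.1],
        }
    if family == "logistic_regression":
        return {
            "clf__C": loguniform(1e-3, 1e2),
            "clf__l1_ratio": [0.0, 1.0],  # ridge vs lasso penalty
        }
    if family == "gradient_boosting":
        return {
            "n_estimators": [100, 200, 300],
            "learning_rate": loguniform(1e-2, 3e-1),
            "max_depth": [2, 3, 4],
            "subsample": [0.7, 0.85, 1.0],
        }
    if family == "neural_network":
        return {
            "clf__hidden_layer_sizes": [(64,), (128,), (64, 32)],
            "clf__alpha": loguniform(1e-5, 1e-1),
            "clf__learning_rate_init": loguniform(1e-4, 1e-2),
            "clf__batch_size": [32, 64, 128],
        }
    if family == "xgboost":
        return {
            "max_depth": [3, 4, 6, 8],
            "learning_rate": loguniform(1e-2, 3e-1),
            "subsample": [0.7, 0.85, 1.0],
            "colsample_bytree": [0.5, 0.75, 1.0],
            "reg_lambda": loguniform(1e-2, 1e1),
            "n_estimators": [100, 200, 300],
        }
    raise ValueError(f"unknown model family {family!r}")


def make_estimator(family: str, seed: int):
    """Probability-outputting estimator for a family, seeded.

    Logistic regression and the neural net standardize the binary fingerprint
    inputs inside a pipeline so the scaler is refit per CV fold.
    """
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if family == "logistic_regression":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(solver="saga", max_iter=2000, random_state=seed)),
            ]
        )
    if family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed)
    if family == "neural_network":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", MLPClassifier(max_iter=300, random_state=seed)),
            ]
        )
    if family == "xgboost":
        try:
            from xgboost import XGBClassifier
        except ImportError as exc:  # family is optional
            raise ImportError("xgboost is not installed; choose another family") from exc
        return XGBClassifier(eval_metric="logloss", random_state=seed, n_jobs=1)
    raise ValueError(f"unknown model family {family!r}")


def _check_two_classes(labels) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def tune_and_fit(features: np.ndarray, labels: np.ndarray, config: ModelConfig) -> TunedModel:
    """Randomized search over ``config.search_space``; refit best on all rows.

    Search, CV shuffling, and the estimator itself are all seeded with the
    split seed, so identical inputs reproduce identical best parameters.
    """
    labels = np.asarray(labels)
    _check_two_classes(labels)
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    search = RandomizedSearchCV(
        make_estimator(config.family, config.seed),
        config.search_space,
        n_iter=config.n_iter,
        scoring="roc_auc",
        cv=cv,
        random_state=config.seed,
        refit=True,
        n_jobs=1,
    )
    search.fit(features, labels)
    return TunedModel(
        model=search.best_estimator_,
        best_params=dict(search.best_params_),
        best_cv_auc=float(search.best_score_),
        config=config,
    )


def oof_predict(
    features: np.ndarray, labels: np.ndarray, tuned: TunedModel
) -> np.ndarray:
    """Out-of-fold positive-class probabilities over the tuning rows.

    Every row is predicted exactly once, by the fold model that excluded it,
    using the same seeded stratified folds as the search.
    """
    labels = np.asarray(labels)
    _check_two_classes(labels)
    cv = StratifiedKFold(
        n_splits=tuned.config.cv_folds, shuffle=True, random_state=tuned.config.seed
    )
    probs = cross_val_predict(
        clone(tuned.model), features, labels, cv=cv, method="predict_proba", n_jobs=1
    )
    return probs[:, 1]


def evaluate(probabilities, labels, threshold: float = 0.5) -> dict:
    """Discrimination and threshold metrics for one prediction set.

    AUC/AP are reported as the undefined marker (None) when only one class is
    present. A probability equal to the threshold predicts positive.
    """
    probs = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    single_class = len(np.unique(y)) < 2
    pred = (probs >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    return {
        "auc": UNDEFINED if single_class else float(roc_auc_score(y, probs)),
        "ap": UNDEFINED if single_class else float(average_precision_score(y, probs)),
        "mcc": float(matthews_corrcoef(y, pred)),
        "balanced_accuracy": float(balanced_accuracy_score(y, pred)),
        "confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        "threshold_used": float(threshold),
        "n": int(len(y)),
    }


def calibrate(probabilities, labels) -> dict:
    """Reliability curve over ten equal-width bins in [0,1], plus Brier score.

    Probabilities of exactly 1.0 fall in the last bin. Empty bins are omitted
    from the curve but bin counts always sum to n.
    """
    probs = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if probs.size == 0:
        raise ValueError("need at least one prediction")
    edges = np.linspace(0.0, 1.0, 11)
    idx = np.minimum((probs * 10).astype(int), 9)
    curve = []
    counts = []
    for b in range(10):
        mask = idx == b
        counts.append(int(mask.sum()))
        if mask.any():
            curve.append(
                {
                    "bin": b,
                    "lo": float(edges[b]),
                    "hi": float(edges[b + 1]),
                    "mean_predicted": float(probs[mask].mean()),
                    "observed_positive_fraction": float(y[mask].mean()),
                    "n": int(mask.sum()),
                }
            )
    return {
        "bin_edges": edges.tolist(),
        "bin_counts": counts,
        "curve": curve,
        "brier": float(np.mean((probs - y) ** 2)),
    }


def threshold_metrics(probabilities, labels, threshold: float) -> dict:
    """MCC, balanced accuracy, precision, recall, F1, specificity at a threshold."""
    probs = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = (probs >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    return {
        "threshold": float(threshold),
        "mcc": float(matthews_corrcoef(y, pred)),
        "balanced_accuracy": float(balanced_accuracy_score(y, pred)),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "specificity": specificity,
        "confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    }


def select_threshold(oof_probabilities, labels, criterion: str = "mcc") -> dict:
    """Pick the decision threshold maximizing MCC (or balanced accuracy) on OOF.

    Candidates are the midpoints between consecutive sorted unique OOF
    probabilities, plus 0 and 1; ties go to the smallest candidate. The
    returned threshold is meant to be applied unchanged to test predictions.
    """
    if criterion not in {"mcc", "balanced_accuracy"}:
        raise ValueError("criterion must be 'mcc' or 'balanced_accuracy'")
    probs = np.asarray(oof_probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_two_classes(y)
    uniq = np.unique(probs)
    candidates = np.concatenate(([0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]))
    candidates = np.unique(candidates)
    best_thr, best_score = None, -np.inf
    for thr in candidates:  # ascending, so first max wins → smallest on ties
        score = threshold_metrics(probs, y, thr)[criterion]
        if score > best_score:
            best_score, best_thr = score, float(thr)
    return {"threshold": best_thr, "criterion": criterion, "oof_score": float(best_score)}


def aggregate_seeds(evaluations: pd.DataFrame) -> pd.DataFrame:
    """Cross-seed mean and sample SD per model, ranked by mean test AUC.

    ``evaluations`` is long-format with columns ``model``, ``seed`` and metric
    columns. Sample SD uses n−1; a single seed reports SD 0 with
    ``single_seed=True``. Ranking ties break on mean test AP.
    """
    if evaluations.empty:
        raise ValueError("no evaluations to aggregate")
    metric_cols = [
        c for c in evaluations.columns
        if c not in {"model", "seed"} and pd.api.types.is_numeric_dtype(evaluations[c])
    ]
    rows = []
    for model, grp in evaluations.groupby("model", sort=False):
        row = {"model": model, "n_seeds": int(grp["seed"].nunique())}
        for col in metric_cols:
            vals = grp[col].astype(float)
            row[f"{col}_mean"] = float(vals.mean())
            row[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        row["single_seed"] = len(grp) == 1
        rows.append(row)
    out = pd.DataFrame(rows)
    sort_keys = [k for k in ("test_auc_mean", "test_ap_mean") if k in out.columns]
    if sort_keys:
        out = out.sort_values(sort_keys, ascending=False, kind="mergesort")
    out = out.reset_index(drop=True)
    out.insert(1, "rank", np.arange(1, len(out) + 1))
    return out
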