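"""Bagged decision-tree classification with stratified cross-validation.

The classifier is an ensemble of CART trees (Gini splits, depth-limited, no
further pruning) fitted on bootstrap resamples of the training set — 31
estimators of maximum depth 38 by default, the configuration found adequate
for the two-class pressure-response problem at n = 40 samples. Evaluation is
stratified 5-fold cross-validation: every sample receives exactly one
out-of-fold score and the pooled scores feed a single ROC curve; per-fold
AUCs are retained as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "BaggingConfig",
    "ROCResult",
    "MetricsReport",
    "CrossValidationResult",
    "fit_bagging",
    "predict_scores",
    "cross_validate",
    "roc_auc",
    "classification_metrics",
    "auc_band",
]


@dataclass(frozen=True)
class BaggingConfig:
    """Hyperparameters of the bagged-tree model and its cross-validation."""

    n_estimators: int = 31
    max_depth: int = 38
    k_folds: int = 5
    seed: int = 0
    score_rule: str = "mean_probability"
    threshold: float = 0.5

    def __post_init__(self):
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        if self.score_rule not in ("mean_probability", "vote_fraction"):
            raise ValueError(f"unknown score_rule {self.score_rule!r}")


@dataclass
class ROCResult:
    """ROC operating points and trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    @property
    def band(self) -> str:
        return auc_band(self.auc)


@dataclass
class MetricsReport:
    """Confusion counts and threshold metrics at one operating point."""

    TP: int
    FP: int
    FN: int
    TN: int
    precision: float
    recall: float
    f1: float
    no_positive_predictions: bool = False


@dataclass
class CrossValidationResult:
    """Pooled out-of-fold scores plus the fold assignment and per-fold AUCs."""

    scores: np.ndarray
    fold_of_sample: np.ndarray
    per_fold_auc: list = field(default_factory=list)


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=int)
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in y")
    return X, y


def fit_bagging(X, y, config: BaggingConfig = BaggingConfig()) -> BaggingClassifier:
    """Fit the bagged CART ensemble (bootstrap resamples of size n, with replacement)."""
    X, y = _check_xy(X, y)
    model = BaggingClassifier(
        estimator=DecisionTreeClassifier(criterion="gini", max_depth=config.max_depth),
        n_estimators=config.n_estimators,
        bootstrap=True,
        max_samples=1.0,
        random_state=config.seed,
    )
    model.fit(X, y)
    return model


def predict_scores(model, X, score_rule: str = "mean_probability") -> np.ndarray:
    """Class-1 score in [0, 1] for each row of X.

    ``mean_probability`` averages the leaf class-1 probabilities over trees;
    ``vote_fraction`` is the fraction of trees whose hard prediction is 1.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"X has {X.shape[1]} features but the model was trained with {model.n_features_in_}"
        )
    if score_rule == "mean_probability":
        pos = int(np.flatnonzero(model.classes_ == 1)[0])
        return model.predict_proba(X)[:, pos]
    if score_rule == "vote_fraction":
        votes = np.stack([est.predict(X) for est in model.estimators_])
        classes = model.classes_
        return (classes[votes.astype(int)] == 1).mean(axis=0)
    raise ValueError(f"unknown score_rule {score_rule!r}")


def cross_validate(
    X, y, config: BaggingConfig = BaggingConfig(), groups=None
) -> CrossValidationResult:
    """Stratified k-fold CV: one out-of-fold score per sample, pooled.

    Folds are shuffled by the config seed; each fold's model is seeded
    deterministically from it as well. Per-fold AUCs are computed on each
    fold's own out-of-fold scores when both classes are present in the fold.

    When ``groups`` is given (typically the subject IDs), folds are group-
    aware: a subject's baseline and post-release samples stay in the same
    fold. Splitting a pair across folds lets deep trees memorise the
    near-duplicate twin with the opposite label, which biases the pooled
    AUC *below* chance on null data.
    """
    X, y = _check_xy(X, y)
    counts = np.bincount(y)
    if counts[counts > 0].min() < config.k_folds:
        raise ValueError(
            f"every class needs at least k_folds={config.k_folds} members, got {counts}"
        )
    if groups is None:
        skf = StratifiedKFold(n_splits=config.k_folds, shuffle=True, random_state=config.seed)
        split = skf.split(X, y)
    else:
        sgk = StratifiedGroupKFold(
            n_splits=config.k_folds, shuffle=True, random_state=config.seed
        )
        split = sgk.split(X, y, groups=np.asarray(groups))
    scores = np.full(len(y), np.nan)
    fold_of_sample = np.full(len(y), -1, dtype=int)
    per_fold = []
    for k, (train, test) in enumerate(split):
        cfg = BaggingConfig(
            n_estimators=config.n_estimators,
            max_depth=config.max_depth,
            k_folds=config.k_folds,
            seed=config.seed + 1009 * (k + 1),
            score_rule=config.score_rule,
            threshold=config.threshold,
        )
        model = fit_bagging(X[train], y[train], cfg)
        scores[test] = predict_scores(model, X[test], config.score_rule)
        fold_of_sample[test] = k
        if len(np.unique(y[test])) == 2:
            per_fold.append(roc_auc(scores[test], y[test]).auc)
        else:
            per_fold.append(float("nan"))
    return CrossValidationResult(scores, fold_of_sample, per_fold)


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve over all distinct score thresholds and its trapezoidal AUC.

    Tied scores receive half credit, so the trapezoidal area equals the
    pairwise-concordance (Mann-Whitney) estimator.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    return ROCResult(fpr, tpr, thr, float(_trapezoid_auc(fpr, tpr)))


def classification_metrics(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Confusion counts and precision/recall/F1 at ``score >= threshold``.

    Precision is reported as 0 with a warning flag when nothing is predicted
    positive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    pred = scores >= threshold
    TP = int(np.sum(pred & (labels == 1)))
    FP = int(np.sum(pred & (labels == 0)))
    FN = int(np.sum(~pred & (labels == 1)))
    TN = int(np.sum(~pred & (labels == 0)))
    no_pos = (TP + FP) == 0
    precision = 0.0 if no_pos else TP / (TP + FP)
    recall = TP / (TP + FN) if (TP + FN) else 0.0
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return MetricsReport(TP, FP, FN, TN, precision, recall, f1, no_positive_predictions=no_pos)


#: The seven AUC interpretation bands, from ideal down to worse-than-random.
_AUC_BANDS = (
    "Ideal classification model",
    "Very good performance and practical classification model",
    "Good classification model",
    "Acceptable classification model",
    "Low performance classification model",
    "Random classification model",
    "Classification model with high misclassification rate",
)


def auc_band(auc: float) -> str:
    """Map an AUC value to its qualitative interpretation band."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    if auc == 1.0:
        return _AUC_BANDS[0]
    if auc >= 0.9:
        return _AUC_BANDS[1]
    if auc >= 0.8:
        return _AUC_BANDS[2]
    if auc >= 0.7:
        return _AUC_BANDS[3]
    if auc > 0.5:
        return _AUC_BANDS[4]
    if auc == 0.5:
        return _AUC_BANDS[5]
    return _AUC_BANDS[6]
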