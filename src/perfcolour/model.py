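"""Model/Results interface over the classification and statistics layers.

:class:`PressureResponseModel` is built from a feature table (or directly
from a DataFrame or a simulator configuration); ``fit()`` standardizes the
components, runs the bagged-tree classifier under stratified k-fold
cross-validation, and computes the class-comparison statistics and
redundancy analyses, returning a :class:`PressureResponseResults` with the
pooled ROC/AUC, threshold metrics, per-component paired tests, the Pearson
matrix, the PCA spectrum and (optionally) CV permutation importances, plus a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .classify import (
    BaggingConfig,
    CrossValidationResult,
    MetricsReport,
    ROCResult,
    classification_metrics,
    cross_validate,
    fit_bagging,
    roc_auc,
)
from .features import FeatureTable, standardize
from .synthetic import FeatureSimParams, simulate_feature_dataset

__all__ = ["PressureResponseModel", "PressureResponseResults", "cv_permutation_importance"]


def cv_permutation_importance(
    X, y, config: BaggingConfig, *, metric: str = "auc", n_repeats: int = 30, seed: int = 0,
    feature_names=None, groups=None,
) -> pd.DataFrame:
    """Permutation importance evaluated out-of-fold.

    For each CV fold the model is trained on the training split and the
    importances are measured on the held-out split, so a redundant or
    uninformative feature scores near zero instead of inheriting the
    in-sample fit. Fold results are pooled: means averaged over folds, SDs
    combined over all repeats.
    """
    from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if groups is None:
        skf = StratifiedKFold(n_splits=config.k_folds, shuffle=True, random_state=config.seed)
        split = skf.split(X, y)
    else:
        sgk = StratifiedGroupKFold(n_splits=config.k_folds, shuffle=True, random_state=config.seed)
        split = sgk.split(X, y, groups=np.asarray(groups))
    per_fold = []
    for k, (train, test) in enumerate(split):
        if len(np.unique(y[test])) < 2:
            continue
        model = fit_bagging(X[train], y[train], config)
        imp = stats.permutation_importance(
            model, X[test], y[test], metric=metric, n_repeats=n_repeats, seed=seed + k
        )
        per_fold.append(imp)
    mean = pd.concat([f["importance_mean"] for f in per_fold], axis=1).mean(axis=1)
    sd = pd.concat([f["importance_sd"] for f in per_fold], axis=1).pow(2).mean(axis=1).pow(0.5)
    out = pd.DataFrame({"importance_mean": mean, "importance_sd": sd})
    if feature_names is not None:
        out.index = list(feature_names)
    return out


class PressureResponseModel:
    """Two-class pressure-response model over ROI colour components.

    Parameters
    ----------
    table : FeatureTable
        One row per (subject, class) sample. Standardized internally at fit
        time if not already (pooled over classes; a ``scale_within_fold``
        fit option refits the scaling inside each CV fold instead).
    components : sequence of str, optional
        The explanatory components; defaults to every component column.
    config : BaggingConfig
        Classifier and cross-validation hyperparameters.
    """

    def __init__(self, table: FeatureTable, components=None, config: BaggingConfig = BaggingConfig()):
        self.table = table
        self.components = list(components) if components is not None else table.components
        missing = [c for c in self.components if c not in table.data.columns]
        if missing:
            raise ValueError(f"components {missing} not present in the table")
        self.config = config

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, components=None, config: BaggingConfig = BaggingConfig()):
        """Build from a raw DataFrame with subject_id/label/component columns."""
        return cls(FeatureTable(df.copy()), components=components, config=config)

    @classmethod
    def from_simulation(
        cls, params: FeatureSimParams = FeatureSimParams(), components=None,
        config: BaggingConfig = BaggingConfig(),
    ):
        """Build from a freshly drawn synthetic feature table."""
        return cls(simulate_feature_dataset(params), components=components, config=config)

    def fit(
        self, *, scale_within_fold: bool = False, with_importance: bool = True,
        importance_repeats: int = 30, group_by_subject: bool = True,
    ) -> "PressureResponseResults":
        """Run CV classification plus the statistical evaluation.

        ``group_by_subject`` keeps each subject's paired samples in the same
        CV fold (recommended: splitting a pair across folds biases the AUC).
        """
        table = self.table if self.table.standardized else standardize(self.table)
        y = table.y
        groups = table.data["subject_id"].to_numpy() if group_by_subject else None
        if scale_within_fold:
            cv = self._cv_scaled_within_fold(y, groups)
        else:
            cv = cross_validate(table.X(self.components), y, self.config, groups=groups)
        roc = roc_auc(cv.scores, y)
        metrics = classification_metrics(cv.scores, y, self.config.threshold)
        comp_stats = {}
        for c in self.components:
            x0, x1 = table.class_values(c)
            try:
                comp_stats[c] = stats.paired_class_comparison(x0, x1)
            except ValueError:
                comp_stats[c] = None
        pearson = stats.pearson_matrix(table.data[self.components]) if len(self.components) > 1 else None
        if pearson is not None:
            eig, ratios = stats.pca_explained(pearson)
        else:
            eig, ratios = np.array([1.0]), np.array([1.0])
        importance = None
        if with_importance and len(self.components) > 1:
            importance = cv_permutation_importance(
                table.X(self.components), y, self.config,
                n_repeats=importance_repeats, seed=self.config.seed,
                feature_names=self.components, groups=groups,
            )
        return PressureResponseResults(
            model=self, table=table, cv=cv, roc=roc, metrics=metrics,
            component_stats=comp_stats, pearson=pearson,
            pca_eigenvalues=eig, pca_ratios=ratios, importance=importance,
        )

    def _cv_scaled_within_fold(self, y, groups=None) -> CrossValidationResult:
        """Leakage-free variant: z-scoring refit on each training split."""
        from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

        from .classify import predict_scores

        X = self.table.X(self.components)
        if groups is None:
            skf = StratifiedKFold(
                n_splits=self.config.k_folds, shuffle=True, random_state=self.config.seed
            )
            split = skf.split(X, y)
        else:
            sgk = StratifiedGroupKFold(
                n_splits=self.config.k_folds, shuffle=True, random_state=self.config.seed
            )
            split = sgk.split(X, y, groups=np.asarray(groups))
        scores = np.full(len(y), np.nan)
        fold_of_sample = np.full(len(y), -1, dtype=int)
        per_fold = []
        for k, (train, test) in enumerate(split):
            mu = X[train].mean(axis=0)
            sd = X[train].std(axis=0, ddof=1)
            if np.any(sd == 0):
                raise ValueError("constant component inside a training fold")
            model = fit_bagging((X[train] - mu) / sd, y[train], self.config)
            scores[test] = predict_scores(model, (X[test] - mu) / sd, self.config.score_rule)
            fold_of_sample[test] = k
            per_fold.append(
                roc_auc(scores[test], y[test]).auc if len(np.unique(y[test])) == 2 else float("nan")
            )
        return CrossValidationResult(scores, fold_of_sample, per_fold)


@dataclass
class PressureResponseResults:
    """Fitted estimates, diagnostics and report accessors."""

    model: PressureResponseModel
    table: FeatureTable
    cv: CrossValidationResult
    roc: ROCResult
    metrics: MetricsReport
    component_stats: dict
    pearson: pd.DataFrame | None
    pca_eigenvalues: np.ndarray
    pca_ratios: np.ndarray
    importance: pd.DataFrame | None = None
    _stats_frame: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def auc(self) -> float:
        return self.roc.auc

    @property
    def auc_band(self) -> str:
        return self.roc.band

    @property
    def per_fold_auc(self) -> list:
        return self.cv.per_fold_auc

    def stats_frame(self) -> pd.DataFrame:
        """Per-component Shapiro-Wilk, paired t and Cohen's d as a DataFrame."""
        if self._stats_frame is None:
            rows = {}
            for c, r in self.component_stats.items():
                if r is None:
                    continue
                rows[c] = {
                    "shapiro_W_class0": r.shapiro_W_class0,
                    "shapiro_p_class0": r.shapiro_p_class0,
                    "shapiro_W_class1": r.shapiro_W_class1,
                    "shapiro_p_class1": r.shapiro_p_class1,
                    "t": r.t, "df": r.df, "p": r.p, "d": r.d,
                }
            self._stats_frame = pd.DataFrame(rows).T
        return self._stats_frame

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = []
        comps = ", ".join(self.model.components)
        cfg = self.model.config
        lines.append("Pressure-response classification (bagged decision trees)")
        lines.append("=" * 72)
        lines.append(f"Components:      {comps}")
        lines.append(
            f"Samples:         {len(self.table.data)} "
            f"({(self.table.y == 0).sum()} baseline / {(self.table.y == 1).sum()} post-release)"
        )
        lines.append(
            f"Model:           {cfg.n_estimators} trees, max depth {cfg.max_depth}, "
            f"{cfg.k_folds}-fold stratified CV (seed {cfg.seed})"
        )
        lines.append("-" * 72)
        lines.append(f"Pooled AUC:      {self.auc:.3f}   [{self.auc_band}]")
        folds = ", ".join(f"{a:.2f}" for a in self.per_fold_auc)
        lines.append(f"Per-fold AUC:    {folds}")
        m = self.metrics
        lines.append(
            f"At threshold {cfg.threshold:.2f}: precision {m.precision:.2f}, "
            f"recall {m.recall:.2f}, F1 {m.f1:.2f} "
            f"(TP {m.TP}, FP {m.FP}, FN {m.FN}, TN {m.TN})"
        )
        sf = self.stats_frame()
        if len(sf):
            lines.append("-" * 72)
            lines.append("Paired class comparison (standardized values, class 0 - class 1):")
            lines.append(f"{'component':<10}{'t':>9}{'df':>5}{'p':>12}{'d':>8}")
            for c, row in sf.iterrows():
                p = row["p"]
                ptxt = "<0.001" if p < 0.001 else f"{p:.3f}"
                lines.append(f"{c:<10}{row['t']:>9.2f}{int(row['df']):>5}{ptxt:>12}{row['d']:>8.2f}")
        if self.pearson is not None:
            top2 = float(self.pca_ratios[:2].sum())
            lines.append("-" * 72)
            lines.append(f"PCA: top-two components explain {100 * top2:.1f}% of variance")
        if self.importance is not None:
            order = self.importance["importance_mean"].sort_values(ascending=False)
            ranked = ", ".join(f"{k} ({v:+.3f})" for k, v in order.items())
            lines.append(f"Permutation importance (out-of-fold AUC drop): {ranked}")
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """Plot the pooled ROC curve; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.roc.fpr, self.roc.tpr, label=f"AUC = {self.auc:.2f}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend(loc="lower right")
        return ax
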