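"""Class-comparison statistics and feature-redundancy analyses.

Per component the two classes (baseline vs post-release) are compared with a
Shapiro-Wilk normality check, a paired two-sample t-test on the standardized
values, and the paired Cohen's d (the d_z form: mean of the per-subject
differences over their SD, so that d = t / sqrt(n) exactly).

Redundancy among components is assessed three ways: the pairwise Pearson
correlation matrix, PCA of the correlation matrix (eigenvalue spectrum and
explained-variance ratios), and seeded permutation importance of a fitted
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.inspection import permutation_importance as _sk_permutation_importance

__all__ = [
    "PairedTestResult",
    "shapiro_wilk",
    "paired_t_test",
    "cohens_d_paired",
    "paired_class_comparison",
    "pearson_matrix",
    "pca_explained",
    "permutation_importance",
]


@dataclass
class PairedTestResult:
    """Normality checks plus paired t-test and effect size for one component."""

    shapiro_W_class0: float
    shapiro_p_class0: float
    shapiro_W_class1: float
    shapiro_p_class1: float
    t: float
    df: int
    p: float
    d: float


def _check_sample(x, name="x") -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if np.ptp(x) == 0:
        raise ValueError(f"{name} is constant")
    return x


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and approximate p-value (3 <= n <= 5000)."""
    x = _check_sample(x)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def _paired_diffs(x0, x1) -> np.ndarray:
    x0 = np.asarray(x0, dtype=float).ravel()
    x1 = np.asarray(x1, dtype=float).ravel()
    if len(x0) != len(x1):
        raise ValueError("paired samples must have equal length")
    if len(x0) < 2:
        raise ValueError("paired test requires n >= 2")
    d = x0 - x1
    if np.ptp(d) == 0:
        raise ValueError("paired differences are constant; t is undefined")
    return d


def paired_t_test(x0, x1) -> tuple[float, int, float]:
    """Paired two-sample t-test on the class-0 minus class-1 differences.

    Returns ``(t, df, p)`` with ``t = mean(diff) / (sd(diff)/sqrt(n))``
    (SD with n-1) and a two-sided p from the t distribution with df = n-1.
    """
    diff = _paired_diffs(x0, x1)
    n = len(diff)
    t = diff.mean() / (diff.std(ddof=1) / np.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def cohens_d_paired(x0, x1, *, pooled: bool = False) -> float:
    """Paired Cohen's d.

    Default is the d_z form, ``mean(diff) / sd(diff)``, which satisfies
    ``d = t / sqrt(n)`` exactly. With ``pooled=True`` the denominator is the
    pooled within-class SD instead (Cohen's d_av-style alternative).
    """
    diff = _paired_diffs(x0, x1)
    if pooled:
        x0 = np.asarray(x0, dtype=float).ravel()
        x1 = np.asarray(x1, dtype=float).ravel()
        sd = np.sqrt((x0.var(ddof=1) + x1.var(ddof=1)) / 2.0)
    else:
        sd = diff.std(ddof=1)
    return float(diff.mean() / sd)


def paired_class_comparison(x0, x1) -> PairedTestResult:
    """Full per-component comparison: Shapiro-Wilk per class, paired t, d_z."""
    W0, p0 = shapiro_wilk(x0)
    W1, p1 = shapiro_wilk(x1)
    t, df, p = paired_t_test(x0, x1)
    d = cohens_d_paired(x0, x1)
    return PairedTestResult(W0, p0, W1, p1, t, df, p, d)


def pearson_matrix(X) -> pd.DataFrame:
    """Pairwise Pearson correlations (symmetric, unit diagonal).

    Accepts an (n, p) array or DataFrame; returns a labelled DataFrame.
    Constant columns are an error (their correlation is undefined).
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(arr.shape[1])]
    if arr.shape[0] < 2:
        raise ValueError("Pearson correlation requires at least 2 rows")
    sd = arr.std(axis=0)
    if np.any(sd == 0):
        bad = [names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant columns {bad}; correlation undefined")
    r = np.corrcoef(arr, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=names, columns=names)


def pca_explained(X) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalue spectrum and explained-variance ratios.

    ``X`` may be a symmetric (correlation) matrix, or a data table — in the
    latter case its Pearson correlation matrix is decomposed, matching PCA
    on standardized features. Returns ``(eigenvalues, ratios)``, both sorted
    nonincreasing; the ratios sum to 1.
    """
    arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D array")
    if arr.shape[0] == arr.shape[1] and np.allclose(np.diag(arr), 1.0):
        if not np.allclose(arr, arr.T, atol=1e-8):
            raise ValueError("matrix input must be symmetric")
        corr = (arr + arr.T) / 2.0
    else:
        corr = pearson_matrix(pd.DataFrame(arr)).to_numpy()
    eig = np.linalg.eigvalsh(corr)[::-1]
    if eig.min() < -1e-9:
        raise ValueError("correlation matrix is not positive semidefinite")
    ratios = eig / eig.sum()
    return eig, ratios


def permutation_importance(
    model, X, y, *, metric: str = "auc", n_repeats: int = 30, seed: int = 0
) -> pd.DataFrame:
    """Per-feature mean and SD of the metric drop under column shuffling.

    Each feature column is permuted ``n_repeats`` times (seeded); the
    importance is ``baseline metric - permuted metric``, so redundant
    features (whose information survives in a correlated partner) score
    near 0 even when they are predictive on their own.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    scoring = {"auc": "roc_auc", "accuracy": "accuracy"}.get(metric)
    if scoring is None:
        raise ValueError("metric must be 'auc' or 'accuracy'")
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(arr.shape[1])]
    res = _sk_permutation_importance(
        model, arr, np.asarray(y, dtype=int), scoring=scoring,
        n_repeats=n_repeats, random_state=seed,
    )
    return pd.DataFrame(
        {"importance_mean": res.importances_mean, "importance_sd": res.importances_std},
        index=names,
    )
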