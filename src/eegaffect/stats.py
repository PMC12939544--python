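"""Statistical machinery: rank tests for feature screening, the DeLong
comparison of correlated ROC curves, and permutation feature importance.

Screening is diagnostic, not a filter: channels that miss the 0.05
threshold stay in the model; the screening table just reports where the
class difference is significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FAMILIES, FEATURE_COLUMNS

ALPHA_LEVEL = 0.05


# ---------------------------------------------------------------------------
# Two-sample tests (thin wrappers pinning the conventions)

def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    U counts pairs with x_i > y_j plus half the ties. The p-value is exact
    (full enumeration) when n_x + n_y <= 12 and there are no ties, else the
    normal approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) + len(y) <= 12 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def t_test_ind(x, y) -> tuple[float, float]:
    """Welch two-sample t-test (unequal variances), two-sided.

    Degenerate path: zero variance in both samples with equal means gives
    t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need n >= 2")
    if np.var(x) == 0 and np.var(y) == 0 and np.mean(x) == np.mean(y):
        return 0.0, 1.0
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Feature screening

@dataclass(frozen=True)
class ScreenResult:
    """Per-(family, channel) screening outcome at alpha = 0.05."""

    channel: str
    feature_family: str
    statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA_LEVEL


def screen_features(
    X,
    labels,
    test: str = "mwu",
    correction: str | None = None,
) -> list[ScreenResult]:
    """Run the two-sample screen on every feature column.

    ``test`` is ``"mwu"`` (Mann-Whitney U) or ``"ttest"`` (Welch t).
    No multiple-testing correction is applied by default; pass
    ``correction="bh"`` for Benjamini-Hochberg adjusted p-values.
    A constant column yields p = 1 with a warning-level statistic of 0.
    """
    X = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X
    columns = (
        list(X.columns) if isinstance(X, pd.DataFrame) else list(FEATURE_COLUMNS)
    )
    values = X.to_numpy() if isinstance(X, pd.DataFrame) else X
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for screening")
    if test not in ("mwu", "ttest"):
        raise ValueError(f"unknown test {test!r}")
    g1 = values[labels == 1]
    g0 = values[labels == 0]
    results: list[ScreenResult] = []
    for j, name in enumerate(columns):
        family, _, channel = name.partition("_")
        if family not in FAMILIES:
            family, channel = "feature", name
        col1, col0 = g1[:, j], g0[:, j]
        if np.var(np.concatenate([col1, col0])) == 0:
            warnings.warn(
                f"feature {name!r} is constant; screen reports p = 1",
                RuntimeWarning,
                stacklevel=2,
            )
            stat, p = 0.0, 1.0
        elif test == "mwu":
            stat, p = mann_whitney_u(col1, col0)
        else:
            stat, p = t_test_ind(col1, col0)
        results.append(
            ScreenResult(channel=channel, feature_family=family, statistic=stat, p_value=p)
        )
    if correction == "bh":
        ps = np.array([r.p_value for r in results])
        order = np.argsort(ps)
        n = len(ps)
        adj = np.empty(n)
        running = 1.0
        for rank in range(n - 1, -1, -1):
            i = order[rank]
            running = min(running, ps[i] * n / (rank + 1))
            adj[i] = running
        results = [
            ScreenResult(r.channel, r.feature_family, r.statistic, float(adj[i]))
            for i, r in enumerate(results)
        ]
    return results


def screening_table(results: list[ScreenResult]) -> pd.DataFrame:
    """Screening results as a tidy DataFrame (one row per family/channel)."""
    return pd.DataFrame(
        {
            "feature_family": [r.feature_family for r in results],
            "channel": [r.channel for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    )


# ---------------------------------------------------------------------------
# DeLong test for correlated ROC curves

@dataclass(frozen=True)
class DeLongResult:
    auc1: float
    auc2: float
    z: float
    p_value: float


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _auc_structural(scores: np.ndarray, labels: np.ndarray):
    """Mid-rank AUC and its DeLong structural components (V10, V01)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    # structural components: per-positive and per-negative placement values
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return float(auc), v10, v01


def roc_auc_score_rank(scores, labels) -> float:
    """Mid-rank (Mann-Whitney) AUC estimate; equals U / (n_pos * n_neg)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc, _, _ = _auc_structural(scores, labels)
    return auc


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """DeLong comparison of two correlated AUCs on the same instances.

    z = (AUC_a - AUC_b) / SE(diff) with the covariance estimated from the
    structural components; two-sided p from the standard normal. Identical
    score vectors give z = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != labels.shape or scores_b.shape != labels.shape:
        raise ValueError("scores and labels must be paired on the same instances")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    auc_a, v10_a, v01_a = _auc_structural(scores_a, labels)
    auc_b, v10_b, v01_b = _auc_structural(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    v10 = np.vstack([v10_a, v10_b])
    v01 = np.vstack([v01_a, v01_b])
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        z = 0.0
        p = 1.0
    else:
        z = (auc_a - auc_b) / np.sqrt(var_diff)
        p = float(2 * sps.norm.sf(abs(z)))
    return DeLongResult(auc1=float(auc_a), auc2=float(auc_b), z=float(z), p_value=p)


# ---------------------------------------------------------------------------
# Permutation feature importance

def feature_importance(
    model,
    X,
    labels,
    seed: int = 0,
    n_repeats: int = 20,
) -> pd.Series:
    """Permutation importance (held-out accuracy drop, averaged over
    ``n_repeats`` column permutations), min-max normalized so the top
    feature scores 1.0. Deterministic under ``seed``.
    """
    from sklearn.inspection import permutation_importance
    from sklearn.utils.validation import check_is_fitted

    check_is_fitted(model)
    columns = (
        list(X.columns) if isinstance(X, pd.DataFrame) else list(FEATURE_COLUMNS[: np.asarray(X).shape[1]])
    )
    values = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    if values.shape[1] != len(columns):
        columns = [f"f{j}" for j in range(values.shape[1])]
    res = permutation_importance(
        model,
        values,
        np.asarray(labels, dtype=int),
        scoring="accuracy",
        n_repeats=n_repeats,
        random_state=seed,
    )
    raw = res.importances_mean
    lo, hi = raw.min(), raw.max()
    norm = np.zeros_like(raw) if hi == lo else (raw - lo) / (hi - lo)
    return pd.Series(norm, index=columns).sort_values(ascending=False)
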