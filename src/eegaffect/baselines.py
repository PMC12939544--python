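"""Reference classifiers: nested-CV SVM, gradient-boosted trees, RNN.

All baselines evaluate on the identical stratified folds as the attention
network (same fold object, same seed), so model comparisons are paired —
a requirement of the DeLong test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .networks import RecurrentBaselineClassifier
from .report import (
    EvalReport,
    cross_validate_model,
    evaluate_scores,
    shared_folds,
)


@dataclass(frozen=True)
class SvmSearchSpace:
    """Grid for the RBF-SVM nested cross-validation: outer 5-fold
    generalization loop, inner 3-fold selection of (C, gamma)."""

    C_grid: tuple = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple = (0.001, 0.01, 0.1, 1.0)
    outer_k: int = 5
    inner_k: int = 3

    def validate(self) -> None:
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("C and gamma grids must be non-empty")
        if any(c <= 0 for c in self.C_grid) or any(g <= 0 for g in self.gamma_grid):
            raise ValueError("C and gamma must be positive")
        if self.outer_k < 2 or self.inner_k < 2:
            raise ValueError("outer and inner fold counts must be >= 2")


@dataclass
class NestedCVResult:
    reports: list[EvalReport]
    chosen_params: list[dict]
    #: per outer fold: (outer_train_idx, outer_test_idx, list of inner
    #: (train, val) index pairs in GLOBAL coordinates) — the leakage audit trail
    audit: list[tuple] = field(default_factory=list)


def _svc_pipeline(C: float, gamma: float) -> Pipeline:
    # standardization is fitted inside each training split only
    return Pipeline([
        ("scale", StandardScaler()),
        ("svc", SVC(kernel="rbf", C=C, gamma=gamma)),
    ])


def svm_nested_cv(
    X,
    y,
    space: SvmSearchSpace = SvmSearchSpace(),
    seed: int = 0,
    model_tag: str = "svm_nested",
    feature_subset: str = "fusion24",
) -> NestedCVResult:
    """RBF-SVM with nested cross-validation.

    The inner 3-fold grid search selects (C, gamma) by mean validation
    accuracy using only the outer-training split; the outer test fold is
    never touched during selection. Decision scores are retained for
    ROC/DeLong. The returned audit trail lists every inner index in global
    coordinates so the no-leakage property is assertable.
    """
    space.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    outer = shared_folds(y, k=space.outer_k, seed=seed)
    inner = StratifiedKFold(n_splits=space.inner_k, shuffle=True, random_state=seed + 1)
    reports, chosen, audit = [], [], []
    for fold, (train_idx, test_idx) in enumerate(outer.split(X, y)):
        Xtr, ytr = X[train_idx], y[train_idx]
        inner_pairs_global = [
            (train_idx[itr], train_idx[ival]) for itr, ival in inner.split(Xtr, ytr)
        ]
        best, best_acc = None, -np.inf
        for C in space.C_grid:
            for gamma in space.gamma_grid:
                accs = []
                for g_tr, g_val in inner_pairs_global:
                    model = _svc_pipeline(C, gamma)
                    model.fit(X[g_tr], y[g_tr])
                    accs.append(model.score(X[g_val], y[g_val]))
                acc = float(np.mean(accs))
                if acc > best_acc:
                    best, best_acc = {"C": C, "gamma": gamma}, acc
        model = _svc_pipeline(best["C"], best["gamma"])
        model.fit(Xtr, ytr)
        raw = model.decision_function(X[test_idx])
        scores = 1.0 / (1.0 + np.exp(-raw))
        rep = evaluate_scores(
            y[test_idx], scores,
            fold_id=fold, model_tag=model_tag, feature_subset=feature_subset,
            test_index=test_idx, train_index=train_idx,
        )
        rep.extra["chosen_C"] = best["C"]
        rep.extra["chosen_gamma"] = best["gamma"]
        reports.append(rep)
        chosen.append(best)
        audit.append((train_idx, test_idx, inner_pairs_global))
    return NestedCVResult(reports=reports, chosen_params=chosen, audit=audit)


def xgb_cv(
    X,
    y,
    seed: int = 0,
    k: int = 5,
    model_tag: str = "xgboost",
    feature_subset: str = "fusion24",
    **overrides,
) -> list[EvalReport]:
    """Gradient-boosted trees with the logistic objective, stratified
    k-fold. Pinned defaults: depth 3, 200 rounds, learning rate 0.1."""
    from xgboost import XGBClassifier

    params = dict(
        max_depth=3,
        n_estimators=200,
        learning_rate=0.1,
        objective="binary:logistic",
        eval_metric="logloss",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        verbosity=0,
    )
    params.update(overrides)
    return cross_validate_model(
        XGBClassifier(**params), X, y, k=k, seed=seed,
        model_tag=model_tag, feature_subset=feature_subset,
    )


def rnn_cv(
    X,
    y,
    seed: int = 0,
    k: int = 5,
    model_tag: str = "rnn",
    feature_subset: str = "fusion24",
    **overrides,
) -> list[EvalReport]:
    """Vanilla-RNN baseline over channel-ordered features, stratified
    k-fold with the shared splits."""
    model = RecurrentBaselineClassifier(random_state=seed, **overrides)
    return cross_validate_model(
        model, X, y, k=k, seed=seed,
        model_tag=model_tag, feature_subset=feature_subset,
    )
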