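"""Evaluation: confusion-matrix metrics, ROC/AUC, and the shared
cross-validation harness.

``compute_metrics`` is the single metrics implementation used by every
model in the package. The positive class is depression (label 1), so the
headline precision/recall/F1 are the depression-detection values;
per-class and macro values are always emitted alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts; positive class = depression."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self):
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        )


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def compute_metrics(counts: ConfusionCounts) -> dict:
    """Accuracy and per-class precision/recall/F1 from confusion counts.

    Zero-denominator precision or recall is reported as 0 with an
    ``undefined`` flag listing the affected metrics. ``|fp - fn|`` is
    included as a class-bias diagnostic (never asserted).
    """
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    undefined: list[str] = []
    acc = (counts.tp + counts.tn) / counts.total

    prec_pos, u1 = _safe_div(counts.tp, counts.tp + counts.fp)
    rec_pos, u2 = _safe_div(counts.tp, counts.tp + counts.fn)
    prec_neg, u3 = _safe_div(counts.tn, counts.tn + counts.fn)
    rec_neg, u4 = _safe_div(counts.tn, counts.tn + counts.fp)
    for flag, name in zip(
        (u1, u2, u3, u4),
        ("precision_depression", "recall_depression",
         "precision_negative_emotion", "recall_negative_emotion"),
    ):
        if flag:
            undefined.append(name)

    def f1(p, r):
        return 0.0 if p + r == 0 else 2 * p * r / (p + r)

    f1_pos, f1_neg = f1(prec_pos, rec_pos), f1(prec_neg, rec_neg)
    return {
        "accuracy": acc,
        # headline metrics refer to the depression (positive) class
        "precision": prec_pos,
        "recall": rec_pos,
        "f1": f1_pos,
        "precision_depression": prec_pos,
        "recall_depression": rec_pos,
        "f1_depression": f1_pos,
        "precision_negative_emotion": prec_neg,
        "recall_negative_emotion": rec_neg,
        "f1_negative_emotion": f1_neg,
        "precision_macro": (prec_pos + prec_neg) / 2,
        "recall_macro": (rec_pos + rec_neg) / 2,
        "f1_macro": (f1_pos + f1_neg) / 2,
        "fp_fn_gap": abs(counts.fp - counts.fn),
        "undefined": undefined,
    }


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) by threshold sweep and trapezoidal AUC.

    Tied scores collapse to one threshold step (mid-rank consistent), so
    the trapezoidal area equals the rank-based AUC exactly. The curve
    starts at (0, 0) and ends at (1, 1) and is monotone in both axes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


@dataclass
class EvalReport:
    """Fold-level (or aggregate) evaluation record."""

    confusion: ConfusionCounts
    metrics: dict
    auc: float
    roc: np.ndarray
    fold_id: int = -1
    model_tag: str = ""
    feature_subset: str = "fusion24"
    scores: np.ndarray | None = None
    y_true: np.ndarray | None = None
    test_index: np.ndarray | None = None
    train_index: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fold_id": self.fold_id,
            "model_tag": self.model_tag,
            "feature_subset": self.feature_subset,
            "confusion": {
                "tn": self.confusion.tn, "fp": self.confusion.fp,
                "fn": self.confusion.fn, "tp": self.confusion.tp,
            },
            "auc": self.auc,
            **{k: v for k, v in self.metrics.items() if k != "undefined"},
            **self.extra,
        }


def evaluate_scores(
    y_true, scores, threshold: float = 0.5, **kwargs
) -> EvalReport:
    """Build an :class:`EvalReport` from held-out scores in [0, 1]."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    y_pred = (scores >= threshold).astype(int)
    counts = ConfusionCounts.from_predictions(y_true, y_pred)
    roc, auc = roc_auc(scores, y_true)
    return EvalReport(
        confusion=counts,
        metrics=compute_metrics(counts),
        auc=auc,
        roc=roc,
        scores=scores,
        y_true=y_true,
        **kwargs,
    )


def shared_folds(y, k: int = 5, seed: int = 0):
    """The stratified fold object every model shares, so that comparisons
    are paired (a requirement of the DeLong test)."""
    return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)


def cross_validate_model(
    estimator,
    X,
    y,
    k: int = 5,
    seed: int = 0,
    model_tag: str = "",
    feature_subset: str = "fusion24",
) -> list[EvalReport]:
    """Stratified k-fold evaluation of a sklearn-style classifier.

    The estimator is cloned per fold; any per-fold preprocessing the
    estimator performs (e.g. z-scoring) is fitted on the training split
    only, because the clone never sees the test split. Per-fold seeds are
    derived deterministically from ``seed``. Decision scores are retained
    for ROC and DeLong comparisons.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) < k:
        raise ValueError(f"need at least k={k} samples")
    skf = shared_folds(y, k=k, seed=seed)
    fold_seeds = np.random.SeedSequence(seed).generate_state(k, dtype=np.uint32)
    reports = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        model = clone(estimator)
        if "random_state" in model.get_params():
            model.set_params(random_state=int(fold_seeds[fold]))
        model.fit(X[train_idx], y[train_idx])
        if hasattr(model, "predict_proba"):
            scores = model.predict_proba(X[test_idx])[:, 1]
        else:
            raw = model.decision_function(X[test_idx])
            scores = 1.0 / (1.0 + np.exp(-raw))
        rep = evaluate_scores(
            y[test_idx], scores,
            fold_id=fold, model_tag=model_tag, feature_subset=feature_subset,
            test_index=test_idx, train_index=train_idx,
        )
        if hasattr(model, "mean_"):
            rep.extra["train_mean"] = np.asarray(model.mean_)
        reports.append(rep)
    return reports


def pool_scores(reports: list[EvalReport]) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate held-out scores and labels across folds, ordered by the
    original sample index (valid for paired DeLong comparisons when both
    models used the same folds)."""
    idx = np.concatenate([r.test_index for r in reports])
    scores = np.concatenate([r.scores for r in reports])
    y = np.concatenate([r.y_true for r in reports])
    order = np.argsort(idx)
    return scores[order], y[order]


def aggregate_reports(reports: list[EvalReport]) -> dict:
    """Mean +/- SD of the fold metrics, plus pooled confusion counts."""
    keys = ("accuracy", "precision", "recall", "f1", "precision_macro",
            "recall_macro", "f1_macro")
    out: dict = {"n_folds": len(reports)}
    for key in keys:
        vals = np.array([r.metrics[key] for r in reports])
        out[f"{key}_mean"] = float(vals.mean())
        out[f"{key}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    aucs = np.array([r.auc for r in reports])
    out["auc_mean"] = float(aucs.mean())
    out["auc_sd"] = float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0
    pooled = ConfusionCounts(
        tn=sum(r.confusion.tn for r in reports),
        fp=sum(r.confusion.fp for r in reports),
        fn=sum(r.confusion.fn for r in reports),
        tp=sum(r.confusion.tp for r in reports),
    )
    out["pooled_confusion"] = {
        "tn": pooled.tn, "fp": pooled.fp, "fn": pooled.fn, "tp": pooled.tp,
    }
    out["pooled_accuracy"] = compute_metrics(pooled)["accuracy"]
    return out
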