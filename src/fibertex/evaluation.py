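"""One-vs-rest classifier evaluation: confusion metrics, CV ROC, aggregation.

Each tissue class gets a binary one-vs-rest classifier (Wilks'-lambda forward
selection followed by pooled-covariance LDA).  ROC curves are built under
stratified five-fold cross-validation with the whole pipeline — selection,
standardization and LDA — refit inside every training fold (no leakage), and
the held-out positive-class posteriors pooled into a single curve; AUROC is
the trapezoid area.  Accuracy and F1 are reported on the 0-100 scale.

Because the earliest precursor class is rare, an aggregated binary model
(normal vs pooled precursors) is also provided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import StratifiedKFold

from .discriminant import (
    PooledCovarianceLDA,
    WilksLambdaSelector,
    canonical_variables,
    forward_select,
)
from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "ROCCurve",
    "ovr_metrics",
    "cv_roc",
    "ovr_suite",
    "aggregate_precursor",
    "permutation_auroc_pvalue",
]

_POS = "__positive__"
_REST = "__rest__"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auroc: float
    seed: int
    fold_assignment: np.ndarray = field(default_factory=lambda: np.array([]))
    scores: np.ndarray = field(default_factory=lambda: np.array([]))
    is_positive: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if not (0.0 <= self.auroc <= 1.0):
            raise ValueError("AUROC must lie in [0, 1]")


def confusion_counts(labels, predictions, positive_class) -> ConfusionCounts:
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    if positive_class not in labels:
        raise ValueError(f"positive class {positive_class!r} absent from labels")
    pos = labels == positive_class
    pred_pos = predictions == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos & pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
    )


def ovr_metrics(labels, predictions, positive_class) -> Dict[str, float]:
    """Accuracy, precision, recall and F1 of one one-vs-rest classifier.

    Precision = TP/(TP+FP) and recall = TP/(TP+FN) on the unit scale; F1
    (their harmonic mean) and accuracy = (TP+TN)/n are reported on the 0-100
    scale.  F1 := 0 when there are no true positives.
    """
    c = confusion_counts(labels, predictions, positive_class)
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    if c.tp == 0:
        logger.info("no true positives for %r: F1 set to 0 by convention", positive_class)
        f1 = 0.0
    else:
        f1 = 200.0 * precision * recall / (precision + recall)
    return {
        "accuracy": 100.0 * (c.tp + c.tn) / c.n,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn,
    }


def _make_pipeline(alpha_enter: float, selected: Optional[Sequence[int]] = None):
    """Selector + LDA; a fixed column subset replaces the selector in
    'outside' selection mode."""
    from sklearn.pipeline import Pipeline

    steps = []
    if selected is None:
        steps.append(("select", WilksLambdaSelector(alpha_enter=alpha_enter)))
    steps.append(("lda", PooledCovarianceLDA()))
    return Pipeline(steps)


def cv_roc(
    X,
    y,
    positive_class,
    k: int = 5,
    seed: int = 0,
    alpha_enter: float = 0.35,
    selection: str = "inside",
) -> Tuple[ROCCurve, np.ndarray]:
    """Pooled k-fold cross-validated ROC of one one-vs-rest classifier.

    The problem is binarized (positive class vs rest) and split with
    stratified folds.  ``selection='inside'`` refits the forward selection
    within each training fold (leak-free, the default); ``'outside'`` selects
    once on the full data, mirroring a single global selected-feature set,
    and cross-validates only the classifier.

    Returns the ROC (held-out scores of all folds pooled, trapezoid AUROC)
    and the pooled held-out class predictions aligned with ``y``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    y_bin = np.where(y == positive_class, _POS, _REST)
    n_pos = int(np.sum(y_bin == _POS))
    n_rest = len(y) - n_pos
    if n_pos < k or n_rest < k:
        raise ValueError(
            f"cannot stratify {k} folds with class counts ({n_pos}, {n_rest}); "
            f"use a smaller k"
        )
    if selection not in ("inside", "outside"):
        raise ValueError("selection must be 'inside' or 'outside'")

    cols: Optional[np.ndarray] = None
    if selection == "outside":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = forward_select(X, y_bin, alpha_enter=alpha_enter,
                                 feature_names=[f"x{j}" for j in range(X.shape[1])])
        cols = np.array([int(nm[1:]) for nm in res.entered], dtype=int)
        if cols.size == 0:
            cols = np.arange(X.shape[1])

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    preds = np.empty(len(y), dtype=y_bin.dtype)
    fold_of = np.empty(len(y), dtype=int)
    for fold, (tr, te) in enumerate(skf.split(X, y_bin)):
        Xtr, Xte = X[tr], X[te]
        if selection == "inside":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = forward_select(Xtr, y_bin[tr], alpha_enter=alpha_enter,
                                     feature_names=[f"x{j}" for j in range(X.shape[1])])
            fold_cols = np.array([int(nm[1:]) for nm in res.entered], dtype=int)
            if fold_cols.size == 0:
                fold_cols = np.arange(X.shape[1])
        else:
            fold_cols = cols
        lda = PooledCovarianceLDA().fit(Xtr[:, fold_cols], y_bin[tr])
        proba = lda.predict_proba(Xte[:, fold_cols])
        pos_col = int(np.where(lda.classes_ == _POS)[0][0])
        scores[te] = proba[:, pos_col]
        preds[te] = lda.predict(Xte[:, fold_cols])
        fold_of[te] = fold

    fpr, tpr, thr = roc_curve(y_bin == _POS, scores)
    curve = ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auroc=float(auc(fpr, tpr)),
                     seed=seed, fold_assignment=fold_of, scores=scores,
                     is_positive=(y_bin == _POS))
    pred_labels = np.where(preds == _POS, positive_class, _REST)
    return curve, pred_labels


def _complete_matrix(table: pd.DataFrame, groups: Sequence[str]) -> Tuple[np.ndarray, np.ndarray]:
    sub = table[table["label"].isin(groups)]
    if "complete" in sub.columns:
        sub = sub[sub["complete"]]
    feats = [f for f in FEATURE_NAMES if f in sub.columns]
    sub = sub.dropna(subset=feats)
    return sub[feats].to_numpy(dtype=float), sub["label"].to_numpy()


def ovr_suite(
    table: pd.DataFrame,
    groups: Sequence[str] = ("distal_normal", "p53_signature", "STIC"),
    k: int = 5,
    seed: int = 0,
    alpha_enter: float = 0.35,
    selection: str = "inside",
) -> Dict[str, object]:
    """Per-class one-vs-rest metrics, ROC curves and canonical scatter data.

    Classes too small to stratify ``k`` folds get fit-only (resubstitution)
    metrics with an explicit caveat instead of a cross-validated ROC.
    """
    groups = [g for g in groups if g in set(table["label"])]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups present in the table")
    X, y = _complete_matrix(table, groups)

    rows = []
    rocs: Dict[str, ROCCurve] = {}
    for cls in groups:
        n_pos = int(np.sum(y == cls))
        if n_pos >= k and len(y) - n_pos >= k:
            curve, preds = cv_roc(X, y, cls, k=k, seed=seed,
                                  alpha_enter=alpha_enter, selection=selection)
            y_bin = np.where(y == cls, cls, _REST)
            m = ovr_metrics(y_bin, preds, cls)
            m.update({"group": cls, "n": n_pos, "auroc": curve.auroc, "cv": True})
            rocs[cls] = curve
        else:
            logger.warning("class %r (n=%d) too small for stratified %d-fold CV: "
                           "reporting fit-only metrics", cls, n_pos, k)
            y_bin = np.where(y == cls, cls, _REST)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pipe = _make_pipeline(alpha_enter).fit(X, y_bin)
            m = ovr_metrics(y_bin, pipe.predict(X), cls)
            m.update({"group": cls, "n": n_pos, "auroc": np.nan, "cv": False})
        rows.append(m)

    # global selection + multiclass LDA for the canonical-variable scatter
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sel = forward_select(X, y, alpha_enter=alpha_enter,
                             feature_names=[f"x{j}" for j in range(X.shape[1])])
    cols = np.array([int(nm[1:]) for nm in sel.entered], dtype=int)
    if cols.size == 0:
        cols = np.arange(X.shape[1])
    lda = PooledCovarianceLDA().fit(X[:, cols], y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        proj, ellipses = canonical_variables(lda, X[:, cols], y)

    metrics = pd.DataFrame(rows)[
        ["group", "n", "accuracy", "precision", "recall", "f1", "auroc", "cv",
         "tp", "fp", "fn", "tn"]
    ]
    return {
        "metrics": metrics,
        "roc": rocs,
        "selection": sel,
        "canonical": {"projections": proj, "labels": y, "ellipses": ellipses},
    }


def aggregate_precursor(
    table: pd.DataFrame,
    normal_class: str = "distal_normal",
    precursor_classes: Sequence[str] = ("p53_signature", "STIC"),
    k: int = 5,
    seed: int = 0,
    alpha_enter: float = 0.35,
    selection: str = "inside",
) -> Dict[str, object]:
    """Binary normal-vs-precursor model with the precursor classes pooled."""
    present = set(table["label"])
    if normal_class not in present or not any(c in present for c in precursor_classes):
        raise ValueError("both the normal class and at least one precursor class "
                         "must be present")
    sub = table[table["label"].isin([normal_class, *precursor_classes])].copy()
    sub["label"] = np.where(sub["label"] == normal_class, normal_class, "precursor")
    X, y = _complete_matrix(sub, [normal_class, "precursor"])
    curve, preds = cv_roc(X, y, "precursor", k=k, seed=seed,
                          alpha_enter=alpha_enter, selection=selection)
    y_bin = np.where(y == "precursor", "precursor", _REST)
    m = ovr_metrics(y_bin, preds, "precursor")
    m["auroc"] = curve.auroc
    return {"metrics": m, "roc": curve,
            "counts": {normal_class: int(np.sum(y == normal_class)),
                       "precursor": int(np.sum(y == "precursor"))}}


def permutation_auroc_pvalue(
    X, y, positive_class, n_perm: int = 59, k: int = 5, seed: int = 0,
    alpha_enter: float = 0.35, selection: str = "inside",
) -> Tuple[float, float, np.ndarray]:
    """One-sided permutation p-value for a cross-validated AUROC.

    Recomputes the full CV pipeline on label permutations; returns
    (observed AUROC, p-value, null AUROCs).  p = (1 + #null >= obs)/(1 + n_perm).
    """
    rng = np.random.default_rng(seed)
    obs, _ = cv_roc(X, y, positive_class, k=k, seed=seed,
                    alpha_enter=alpha_enter, selection=selection)
    null = np.empty(n_perm)
    y = np.asarray(y)
    for i in range(n_perm):
        perm = rng.permutation(y)
        c, _ = cv_roc(X, perm, positive_class, k=k, seed=seed,
                      alpha_enter=alpha_enter, selection=selection)
        null[i] = c.auroc
    p = (1.0 + float(np.sum(null >= obs.auroc))) / (1.0 + n_perm)
    return obs.auroc, p, null
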