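"""Evaluation protocol: stratified k-fold CV, ROC/AUC, confusion metrics,
fixed-specificity operating points and top-k% retrieval.

Predicted scores are thresholded (positive iff score >= threshold) into
a confusion matrix from which sensitivity, specificity, precision, F1
and the Matthews correlation coefficient are computed:

    Sn  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    Pre = TP / (TP + FP)
    F1  = 2 * Pre * Sn / (Pre + Sn)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC equals the phi (Pearson) coefficient of the binary label/prediction
pair, which makes it robust to the heavy class imbalance of per-kinase
datasets.  Degenerate denominators return 0 with a warning.

Fixed-specificity operating points select the smallest threshold whose
specificity meets the target (maximal sensitivity subject to the
specificity bound) — the convention used for the "medium" (90%) and
"high" (95%) stringency reports.  Cross-validation is stratified and
seeded; out-of-fold scores are pooled before the ROC and threshold
analyses by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from . import easymkl, svm
from .data_io import KinaseDataset
from .features import FeatureViews
from .kernels import DEFAULT_BETAS, build_kernel_set

logger = logging.getLogger(__name__)

DEFAULT_SPECIFICITY_TARGETS = (0.95, 0.90)
DEFAULT_TOPK_FRACTIONS = (0.01, 0.02, 0.05, 0.10, 0.20)


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int


@dataclass
class MetricsReport:
    Sn: float
    Sp: float
    Pre: float
    F1: float
    MCC: float
    operating_threshold: float
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        return {
            "Sn": self.Sn,
            "Sp": self.Sp,
            "Pre": self.Pre,
            "F1": self.F1,
            "MCC": self.MCC,
            "threshold": self.operating_threshold,
            "TP": self.counts.TP,
            "TN": self.counts.TN,
            "FP": self.counts.FP,
            "FN": self.counts.FN,
        }


@dataclass
class CVResult:
    fold_assignments: np.ndarray  # fold index per sample
    scores: np.ndarray  # pooled out-of-fold scores
    seed: int
    per_fold: list[dict] = field(default_factory=list)


def confusion(labels: np.ndarray, scores: np.ndarray, threshold: float) -> ConfusionCounts:
    """Tally the confusion matrix; a sample is called positive iff its
    score is >= threshold."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0 or labels.shape != scores.shape:
        raise ValueError("labels and scores must be equal-length and non-empty")
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    pred = scores >= threshold
    pos, neg = labels == 1, labels == -1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        TN=int(np.sum(~pred & neg)),
        FP=int(np.sum(pred & neg)),
        FN=int(np.sum(~pred & pos)),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("degenerate denominator in %s; returning 0", name)
        return 0.0
    return num / den


def metrics(counts: ConfusionCounts, threshold: float = float("nan")) -> MetricsReport:
    """Sensitivity, specificity, precision, F1 and MCC from counts."""
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    sn = _safe_div(tp, tp + fn, "Sn")
    sp = _safe_div(tn, tn + fp, "Sp")
    pre = _safe_div(tp, tp + fp, "Pre")
    f1 = _safe_div(2 * pre * sn, pre + sn, "F1")
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _safe_div(tp * tn - fp * fn, denom, "MCC")
    return MetricsReport(
        Sn=sn, Sp=sp, Pre=pre, F1=f1, MCC=mcc,
        operating_threshold=threshold, counts=counts,
    )


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC curve (threshold sweep over the unique scores, ties stepped
    simultaneously) and trapezoid AUC.

    Returns (fpr, tpr, thresholds, auc).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return fpr, tpr, thresholds, float(_trapezoid_auc(fpr, tpr))


def threshold_at_specificity(
    labels: np.ndarray, scores: np.ndarray, target_sp: float
) -> tuple[float, MetricsReport]:
    """Smallest threshold whose specificity meets ``target_sp``.

    This maximizes sensitivity subject to the specificity bound; exact
    equality may be unattainable on finite data, so the achieved Sp
    (>= target) is part of the returned report.
    """
    if not 0.0 < target_sp <= 1.0:
        raise ValueError("target specificity must be in (0, 1]")
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    neg = scores[labels == -1]
    if neg.size == 0:
        raise ValueError("no negatives: specificity target is undefined")
    candidates = np.unique(scores)
    # one threshold above everything guarantees Sp = 1 is always attainable
    candidates = np.append(candidates, candidates[-1] + 1.0)
    for thr in candidates:  # ascending: first hit is the smallest threshold
        sp = np.mean(neg < thr)
        if sp >= target_sp:
            return float(thr), metrics(confusion(labels, scores, thr), float(thr))
    raise AssertionError("unreachable: sentinel threshold always attains Sp = 1")


def topk_retrieval(
    labels: np.ndarray,
    scores: np.ndarray,
    fractions: tuple[float, ...] = DEFAULT_TOPK_FRACTIONS,
) -> list[dict]:
    """Positives found among the top ceil(fraction * n) scores.

    Samples are ranked by descending score with ties broken stably by
    input order, so the table is reproducible.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    n_pos = int(np.sum(labels == 1))
    order = np.argsort(-scores, kind="stable")
    rows = []
    for frac in fractions:
        if not 0.0 < frac <= 1.0:
            raise ValueError("fractions must lie in (0, 1]")
        top = order[: math.ceil(frac * n)]
        tp = int(np.sum(labels[top] == 1))
        rows.append(
            {
                "fraction": frac,
                "n_top": len(top),
                "TP_in_top": tp,
                "fraction_of_positives": tp / n_pos if n_pos else 0.0,
            }
        )
    return rows


def make_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Stratified fold assignment (fold index per sample)."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = {int(c): int(n) for c, n in zip(*np.unique(labels, return_counts=True))}
    small = {c: n for c, n in counts.items() if n < k}
    if small:
        raise ValueError(
            f"classes with fewer than k={k} members: {small}; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold
    return assignment


def run_folds(
    view_matrices: dict[str, np.ndarray],
    labels: np.ndarray,
    fold_assignments: np.ndarray,
    betas: tuple[float, ...] = DEFAULT_BETAS,
    lambda_reg: float = easymkl.DEFAULT_LAMBDA,
    C: float = svm.DEFAULT_C,
) -> tuple[np.ndarray, list[dict]]:
    """Fit the MKL+SVM pipeline per fold and score the held-out rows.

    Kernels (and hence feature counts |F_n|) are built from training
    rows only; held-out rows enter solely through cross-kernels, so
    test labels can never influence their own scores.
    """
    labels = np.asarray(labels)
    scores = np.full(len(labels), np.nan)
    per_fold = []
    for fold in np.unique(fold_assignments):
        test = fold_assignments == fold
        train = ~test
        train_mats = {v: m[train] for v, m in view_matrices.items()}
        test_mats = {v: m[test] for v, m in view_matrices.items()}
        kernel_set = build_kernel_set(train_mats, betas)
        mkl = easymkl.fit_easymkl(kernel_set, labels[train], lambda_reg)
        model = svm.train_svm(mkl.combined, labels[train], C)
        cross = easymkl.combine_cross_kernels(kernel_set, mkl.weights, test_mats)
        scores[test] = svm.decision_scores(model, cross)
        per_fold.append(
            {
                "fold": int(fold),
                "n_train": int(train.sum()),
                "n_test": int(test.sum()),
                "eta": mkl.weights.eta.tolist(),
            }
        )
    assert not np.isnan(scores).any()
    return scores, per_fold


def cross_validate(
    dataset: KinaseDataset,
    views: FeatureViews,
    view_names: tuple[str, ...] = ("seq", "func"),
    betas: tuple[float, ...] = DEFAULT_BETAS,
    lambda_reg: float = easymkl.DEFAULT_LAMBDA,
    C: float = svm.DEFAULT_C,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold CV of the full pipeline for one kinase.

    Every sample is scored exactly once out-of-fold; the pooled score
    vector feeds the ROC / operating-point / top-k analyses.
    """
    matrices = views.matrices(view_names)
    folds = make_folds(dataset.labels, k, seed)
    scores, per_fold = run_folds(matrices, dataset.labels, folds, betas, lambda_reg, C)
    return CVResult(fold_assignments=folds, scores=scores, seed=seed, per_fold=per_fold)


def evaluate_scores(
    labels: np.ndarray,
    scores: np.ndarray,
    specificity_targets: tuple[float, ...] = DEFAULT_SPECIFICITY_TARGETS,
    topk_fractions: tuple[float, ...] = DEFAULT_TOPK_FRACTIONS,
) -> dict:
    """Full report: AUC, metrics at each specificity target, top-k table."""
    fpr, tpr, thresholds, auc_value = roc_auc(labels, scores)
    at_specificity = {}
    for target in specificity_targets:
        thr, report = threshold_at_specificity(labels, scores, target)
        at_specificity[f"{target:.2f}"] = report.to_dict()
    return {
        "auc": auc_value,
        "roc": {
            "fpr": fpr.tolist(),
            "tpr": tpr.tolist(),
            "thresholds": thresholds.tolist(),
        },
        "at_specificity": at_specificity,
        "topk": topk_retrieval(labels, scores, topk_fractions),
    }
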