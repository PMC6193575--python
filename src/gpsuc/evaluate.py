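"""Performance evaluation: confusion-based metrics and ROC/AUC.

Threshold-dependent metrics follow the standard confusion-matrix
definitions:

    Ac  = (nTP + nTN) / (nTP + nTN + nFP + nFN)
    Sp  = nTN / (nTN + nFP)
    Sn  = nTP / (nTP + nFN)
    MCC = (nTP*nTN - nFP*nFN) / sqrt((nTN+nFN)(nTP+nFP)(nTP+nFN)(nTN+nFP))

with any zero denominator mapping the metric to 0. A score tied with the
cutoff counts as a positive call (``score >= cutoff``). The ROC curve is
a threshold sweep over the unique scores (simultaneous steps at ties)
and AUC is its trapezoidal area, which equals the Mann-Whitney
concordance U / (n_pos * n_neg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn import metrics as skm

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "RocCurve",
    "CVReport",
    "confusion_at_cutoff",
    "metrics",
    "roc_auc",
    "cross_validated_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    nTP: int
    nTN: int
    nFP: int
    nFN: int

    @property
    def total(self) -> int:
        return self.nTP + self.nTN + self.nFP + self.nFN


@dataclass(frozen=True)
class MetricReport:
    Ac: float
    Sp: float
    Sn: float
    MCC: float
    cutoff: float


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _validate(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.size == 0:
        raise ValueError("scores and labels must be non-empty and aligned")
    return scores, labels


def confusion_at_cutoff(
    scores: Sequence[float], labels: Sequence[int], cutoff: float
) -> ConfusionCounts:
    """Count the confusion matrix at a cutoff (ties call positive)."""
    scores, labels = _validate(scores, labels)
    calls = scores >= cutoff
    pos = labels == 1
    return ConfusionCounts(
        nTP=int((calls & pos).sum()),
        nTN=int((~calls & ~pos).sum()),
        nFP=int((calls & ~pos).sum()),
        nFN=int((~calls & pos).sum()),
    )


def metrics(counts: ConfusionCounts, cutoff: float = 0.5) -> MetricReport:
    """Accuracy, specificity, sensitivity and MCC from confusion counts."""
    if counts.total == 0:
        raise ValueError("no samples")
    tp, tn, fp, fn = counts.nTP, counts.nTN, counts.nFP, counts.nFN

    def _ratio(num: float, den: float) -> float:
        return num / den if den else 0.0

    ac = (tp + tn) / counts.total
    sp = _ratio(tn, tn + fp)
    sn = _ratio(tp, tp + fn)
    denom = math.sqrt((tn + fn) * (tp + fp) * (tp + fn) * (tn + fp))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return MetricReport(Ac=ac, Sp=sp, Sn=sn, MCC=mcc, cutoff=cutoff)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC curve and AUC over a ranked score list."""
    scores, labels = _validate(scores, labels)
    pos = labels == 1
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, _ = skm.roc_curve(pos.astype(int), scores, drop_intermediate=False)
    auc = float(skm.auc(fpr, tpr))
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc)


@dataclass(frozen=True)
class CVReport:
    """Per-fold and averaged cross-validation performance."""

    fold_metrics: tuple[MetricReport, ...]
    fold_auc: tuple[float, ...]
    mean: MetricReport
    mean_auc: float
    fold_assignment: np.ndarray


def cross_validated_report(
    matrix,
    labels=None,
    folds: int = 10,
    seed: int = 0,
    top_n=None,
    n_trees: int = 500,
    cutoff: float = 0.5,
    fusion_mode: str = "oof",
    inner_folds: int = 3,
) -> CVReport:
    """Stratified k-fold evaluation of the full training pipeline.

    Within every training fold the whole chain is refitted from scratch:
    feature selection, the five random-forest channels, and the fusion
    regression (on inner out-of-fold scores when ``fusion_mode='oof'``,
    on the training fold's own scores when ``'resub'``). Held-out rows
    are then scored once each; metrics and AUC are reported per fold and
    averaged.
    """
    from sklearn.model_selection import StratifiedKFold

    from .model import _fit_fold_channels, _score_channels, fit_fusion, out_of_fold_scores

    labels = matrix.labels if labels is None else np.asarray(labels)
    if labels is None:
        raise ValueError("labels are required")
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_metrics: list[MetricReport] = []
    fold_auc: list[float] = []
    assignment = np.full(matrix.n_samples, -1)
    for fold, (train_idx, test_idx) in enumerate(
        splitter.split(np.zeros(matrix.n_samples), labels)
    ):
        train = matrix.subset_rows(train_idx)
        y_train = labels[train_idx]
        plan, channels = _fit_fold_channels(
            train, y_train, top_n, n_trees, seed, fold
        )
        if fusion_mode == "oof":
            inner_scores, _ = out_of_fold_scores(
                train, y_train, folds=inner_folds,
                seed=seed + 7919 * (fold + 1), top_n=top_n, n_trees=n_trees,
            )
        elif fusion_mode == "resub":
            inner_scores = _score_channels(train, plan, channels)
        else:
            raise ValueError(f"unknown fusion_mode {fusion_mode!r}")
        fusion = fit_fusion(inner_scores, y_train)
        test = matrix.subset_rows(test_idx)
        fused = fusion.predict_proba(_score_channels(test, plan, channels))
        y_test = labels[test_idx]
        fold_metrics.append(metrics(confusion_at_cutoff(fused, y_test, cutoff), cutoff))
        fold_auc.append(roc_auc(fused, y_test).auc)
        assignment[test_idx] = fold
    mean = MetricReport(
        Ac=float(np.mean([m.Ac for m in fold_metrics])),
        Sp=float(np.mean([m.Sp for m in fold_metrics])),
        Sn=float(np.mean([m.Sn for m in fold_metrics])),
        MCC=float(np.mean([m.MCC for m in fold_metrics])),
        cutoff=cutoff,
    )
    return CVReport(
        fold_metrics=tuple(fold_metrics),
        fold_auc=tuple(fold_auc),
        mean=mean,
        mean_auc=float(np.mean(fold_auc)),
        fold_assignment=assignment,
    )
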