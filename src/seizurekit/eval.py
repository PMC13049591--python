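"""Metrics, classification reports, and leakage-controlled stratified 5-fold
cross-validation.

Per-class precision/recall/F1 are computed one-vs-rest from the confusion
matrix (a class never predicted gets precision 0 with a warning); overall
accuracy is the trace over the total. Macro ROC-AUC is the unweighted mean of
one-vs-rest AUCs, each computed by the rank statistic with ties contributing
one half. Cross-validation summaries aggregate folds as mean plus
*population* standard deviation (divide by k).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .normalize import apply_stats, fit_stats
from .types import EpochSet

__all__ = [
    "ConfusionMatrix",
    "Report",
    "CVSummary",
    "confusion",
    "metrics_from_confusion",
    "macro_roc_auc",
    "iter_cv_folds",
    "run_stratified_cv",
    "mean_and_population_sd",
]


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.counts, fmt="%d", delimiter=",")


@dataclass
class Report:
    """Per-class and averaged classification metrics."""

    per_class: dict[int, dict[str, float]]
    accuracy: float
    macro_avg: dict[str, float]
    weighted_avg: dict[str, float]
    macro_roc_auc: float | None = None

    def to_dict(self) -> dict:
        d = {
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "accuracy": self.accuracy,
            "macro_avg": self.macro_avg,
            "weighted_avg": self.weighted_avg,
        }
        if self.macro_roc_auc is not None:
            d["macro_roc_auc"] = self.macro_roc_auc
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_text(self, digits: int = 2) -> str:
        """Aligned classification-report style table, rounded for display."""
        lines = [f"{'':>12} {'precision':>9} {'recall':>9} {'f1-score':>9} {'support':>9}"]
        for label, m in sorted(self.per_class.items()):
            lines.append(
                f"{label:>12} {m['precision']:>9.{digits}f} {m['recall']:>9.{digits}f} "
                f"{m['f1']:>9.{digits}f} {int(m['support']):>9d}"
            )
        total = int(sum(m["support"] for m in self.per_class.values()))
        lines.append("")
        lines.append(f"{'accuracy':>12} {'':>9} {'':>9} {self.accuracy:>9.{digits}f} {total:>9d}")
        for name, avg in (("macro avg", self.macro_avg), ("weighted avg", self.weighted_avg)):
            lines.append(
                f"{name:>12} {avg['precision']:>9.{digits}f} {avg['recall']:>9.{digits}f} "
                f"{avg['f1']:>9.{digits}f} {total:>9d}"
            )
        if self.macro_roc_auc is not None:
            lines.append(f"{'macro AUC':>12} {self.macro_roc_auc:>9.{digits + 2}f}")
        return "\n".join(lines)


@dataclass
class CVSummary:
    """Per-fold metrics plus mean and population SD."""

    fold_accuracy: list[float]
    fold_roc_auc: list[float]
    mean_accuracy: float = field(init=False)
    sd_accuracy: float = field(init=False)
    mean_roc_auc: float = field(init=False)
    sd_roc_auc: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.fold_accuracy) < 2:
            raise ValueError("need at least 2 folds")
        self.mean_accuracy, self.sd_accuracy = mean_and_population_sd(self.fold_accuracy)
        if self.fold_roc_auc:
            self.mean_roc_auc, self.sd_roc_auc = mean_and_population_sd(self.fold_roc_auc)
        else:
            self.mean_roc_auc = self.sd_roc_auc = float("nan")


def mean_and_population_sd(values: list[float] | np.ndarray) -> tuple[float, float]:
    """Mean and population SD (ddof=0), the aggregation used for CV tables."""
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=0))


def confusion(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int | None = None) -> ConfusionMatrix:
    """Tally ``counts[i, j] = #{true i, predicted j}``."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    k = n_classes if n_classes is not None else int(max(y_true.max(), y_pred.max())) + 1
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def metrics_from_confusion(cm: ConfusionMatrix) -> Report:
    """One-vs-rest precision/recall/F1 per class, macro and support-weighted
    averages, and overall accuracy, all straight from the count matrix."""
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    per_class: dict[int, dict[str, float]] = {}
    for i in range(cm.n_classes):
        tp = counts[i, i]
        fn = counts[i, :].sum() - tp
        fp = counts[:, i].sum() - tp
        support = int(counts[i, :].sum())
        if tp + fp == 0:
            warnings.warn(f"class {i} never predicted; precision set to 0", stacklevel=2)
            precision = 0.0
        else:
            precision = tp / (tp + fp)
        recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
        if (tp + fn) == 0:
            warnings.warn(f"class {i} absent from true labels; recall set to 0", stacklevel=2)
        f1 = (
            2.0 * precision * recall / (precision + recall)
            if (precision + recall) > 0
            else 0.0
        )
        per_class[i] = {
            "precision": float(precision),
            "recall": float(recall),
            "f1": float(f1),
            "support": support,
        }
    accuracy = float(np.trace(counts) / total)
    supports = np.array([per_class[i]["support"] for i in range(cm.n_classes)], dtype=float)
    macro = {
        key: float(np.mean([per_class[i][key] for i in range(cm.n_classes)]))
        for key in ("precision", "recall", "f1")
    }
    weighted = {
        key: float(
            np.sum([per_class[i][key] * supports[i] for i in range(cm.n_classes)]) / total
        )
        for key in ("precision", "recall", "f1")
    }
    return Report(per_class, accuracy, macro, weighted)


def _binary_auc(y_pos: np.ndarray, scores: np.ndarray) -> float:
    """Rank-statistic AUC (Mann-Whitney; ties contribute one half)."""
    n_pos = int(y_pos.sum())
    n_neg = y_pos.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: one side empty")
    ranks = rankdata(scores)  # average ranks on ties => tie contributes 1/2
    return float((ranks[y_pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def macro_roc_auc(y_true: np.ndarray, probs: np.ndarray) -> float:
    """One-vs-rest AUC per class, averaged unweighted over the classes
    present in ``y_true`` (absent classes are excluded with a warning).

    Binary inputs may pass a 1-D vector of positive-class probabilities.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    probs = np.asarray(probs, dtype=float)
    if not np.isfinite(probs).all():
        raise ValueError("probabilities must be finite")
    if probs.ndim == 1:
        return _binary_auc(y_true == 1, probs)
    if len(np.unique(y_true)) < 2:
        raise ValueError("need at least two classes in y_true")
    aucs = []
    for i in range(probs.shape[1]):
        mask = y_true == i
        if not mask.any():
            warnings.warn(f"class {i} absent from y_true; excluded from macro AUC", stacklevel=2)
            continue
        aucs.append(_binary_auc(mask, probs[:, i]))
    return float(np.mean(aucs))


def iter_cv_folds(y: np.ndarray, k: int = 5, seed: int = 0):
    """Yield (train_idx, test_idx) for seeded stratified k-fold splitting."""
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    yield from skf.split(np.zeros(len(y)), y)


def run_stratified_cv(
    data: EpochSet,
    spec,
    k: int = 5,
    seed: int = 0,
    val_fraction: float = 0.1,
    patience: int = 10,
) -> CVSummary:
    """Leakage-controlled stratified k-fold cross-validation.

    Per fold: normalization statistics are fitted on the k-1 training folds
    only and applied to both partitions, the model is rebuilt from scratch
    (fresh weight init), trained with early stopping on a train-only
    validation split, and scored on the held-out fold (accuracy and macro
    ROC-AUC).
    """
    from .models import predict, train_model

    counts = np.bincount(data.y)
    present = counts[counts > 0]
    if (present < k).any():
        raise ValueError(f"every class needs >= {k} members for {k}-fold stratification")
    accs, aucs = [], []
    for fold, (tr_idx, te_idx) in enumerate(iter_cv_folds(data.y, k, seed)):
        train = data.subset(tr_idx)
        test = data.subset(te_idx)
        stats = fit_stats(train)  # train folds only: no leakage
        train_std = apply_stats(train, stats)
        test_std = apply_stats(test, stats)
        trained = train_model(
            spec,
            train_std,
            val_fraction=val_fraction,
            early_stopping=("val_loss", patience),
            seed=seed + 1000 * (fold + 1),
            norm_stats=stats,
        )
        labels, probs = predict(trained, test_std)
        accs.append(float(np.mean(labels == test_std.y)))
        aucs.append(macro_roc_auc(test_std.y, probs))
    return CVSummary(accs, aucs)
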