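"""Confusion matrices, one-vs-rest class metrics, ROC/AUC, and k-fold runs.

Per-class rates follow the binary one-vs-rest reduction: precision
TP/(TP+FP), sensitivity TP/(TP+FN), specificity TN/(FP+TN), F-score
2TP/(2TP+FP+FN), accuracy (TP+TN)/total. Note the per-class accuracy is
the *binary* accuracy of that reduction, distinct from the multiclass
trace accuracy; both are exposed under different names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import cnn


def confusion(y_true, y_pred, n_classes: int) -> np.ndarray:
    """n x n count matrix, rows = true class, columns = predicted class."""
    t = np.asarray(y_true, np.int64)
    p = np.asarray(y_pred, np.int64)
    if t.shape != p.shape:
        raise ValueError("label arrays must have equal length")
    if t.size and (t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes):
        raise ValueError("labels outside [0, n_classes)")
    cm = np.zeros((n_classes, n_classes), np.int64)
    np.add.at(cm, (t, p), 1)
    return cm


def normalize_confusion(cm: np.ndarray) -> np.ndarray:
    """Row-normalized (true-class) confusion matrix."""
    totals = cm.sum(axis=1, keepdims=True).astype(float)
    totals[totals == 0] = 1.0
    return cm / totals


def trace_accuracy(cm: np.ndarray) -> float:
    """Multiclass accuracy: trace / total."""
    total = cm.sum()
    return float(np.trace(cm) / total) if total else 0.0


@dataclass
class ClassMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    sensitivity: float
    specificity: float
    f_score: float
    binary_accuracy: float
    degenerate: bool = False  # a 0/0 rate was defined as 0


def _rate(num: int, den: int) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def class_metrics(cm: np.ndarray, class_i: int) -> ClassMetrics:
    """One-vs-rest metrics for one class of a count confusion matrix."""
    tp = int(cm[class_i, class_i])
    fp = int(cm[:, class_i].sum()) - tp
    fn = int(cm[class_i, :].sum()) - tp
    tn = int(cm.sum()) - tp - fp - fn
    precision, d1 = _rate(tp, tp + fp)
    sensitivity, d2 = _rate(tp, tp + fn)
    specificity, d3 = _rate(tn, fp + tn)
    f_score, d4 = _rate(2 * tp, 2 * tp + fp + fn)
    accuracy, d5 = _rate(tp + tn, tp + fp + fn + tn)
    return ClassMetrics(
        tp, fp, fn, tn, precision, sensitivity, specificity, f_score, accuracy,
        degenerate=any([d1, d2, d3, d4, d5]),
    )


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    degenerate: bool = False


def roc_auc(y_true, probs, class_i: int) -> ROCCurve:
    """One-vs-rest ROC by threshold sweep with tie grouping; trapezoid AUC.

    Single-class truth (no positives or no negatives) is undefined and
    returned flagged with auc = nan.
    """
    t = np.asarray(y_true, np.int64) == class_i
    s = np.asarray(probs, np.float64)
    if s.ndim == 2:
        s = s[:, class_i]
    n_pos = int(t.sum())
    n_neg = int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        return ROCCurve(
            np.array([0.0, 1.0]), np.array([0.0, 1.0]), np.array([np.inf, -np.inf]),
            float("nan"), degenerate=True,
        )
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    t_sorted = t[order]
    # group equal thresholds: staircase over distinct score values
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cut = np.concatenate([distinct, [len(s_sorted) - 1]])
    tps = np.cumsum(t_sorted)[cut]
    fps = np.cumsum(~t_sorted)[cut]
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    thresholds = np.concatenate([[np.inf], s_sorted[cut]])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr, tpr, thresholds, auc)


def macro_auc(y_true, probs, n_classes: int) -> float:
    """Mean one-vs-rest AUC over classes represented in the truth."""
    aucs = [
        roc_auc(y_true, probs, i).auc
        for i in range(n_classes)
        if (np.asarray(y_true) == i).any()
    ]
    aucs = [a for a in aucs if np.isfinite(a)]
    return float(np.mean(aucs)) if aucs else float("nan")


@dataclass
class CrossValReport:
    fold_train_error: list[float] = field(default_factory=list)
    fold_eval_error: list[float] = field(default_factory=list)
    fold_confusions: list[np.ndarray] = field(default_factory=list)
    fold_auc: list[float] = field(default_factory=list)
    histories: list[cnn.TrainHistory] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return 1.0 - float(np.mean(self.fold_eval_error))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_eval_error))

    def summary(self) -> dict:
        return {
            "fold_train_error": self.fold_train_error,
            "fold_eval_error": self.fold_eval_error,
            "fold_auc": self.fold_auc,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "seeds": self.seeds,
            "confusions": [cm.tolist() for cm in self.fold_confusions],
        }


def cross_validate(ds, plan, spec: cnn.NetworkSpec, config: cnn.TrainConfig) -> CrossValReport:
    """Train one model per fold and evaluate it on that fold's validation
    set; reports per-fold errors, confusion matrices, macro AUC, and the
    mean +/- sd accuracy."""
    if plan.k < 2:
        raise ValueError("k-fold evaluation requires k >= 2")
    report = CrossValReport()
    for j in range(plan.k):
        tr = plan.train_indices(j)
        va = plan.val_indices[j]
        fold_seed = config.seed + j
        fold_cfg = cnn.TrainConfig(
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            weight_decay=config.weight_decay,
            epochs=config.epochs,
            momentum=config.momentum,
            seed=fold_seed,
        )
        params, history = cnn.train(ds.X[tr], ds.y[tr], spec, fold_cfg)
        preds, probs = cnn.predict(spec, params, ds.X[va])
        cm = confusion(ds.y[va], preds, spec.n_classes)
        report.fold_train_error.append(
            history.train_error[-1] if history.train_error else float("nan")
        )
        report.fold_eval_error.append(1.0 - trace_accuracy(cm))
        report.fold_confusions.append(cm)
        report.fold_auc.append(macro_auc(ds.y[va], probs, spec.n_classes))
        report.histories.append(history)
        report.seeds.append(fold_seed)
    return report
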