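"""Classification metrics and the model-comparison test.

Metrics mirror the standard 4-class motor-imagery report: confusion matrix
(rows = true class, columns = predicted), accuracy, Cohen's kappa
``(p_o - p_e) / (1 - p_e)``, per-class precision/recall, their unweighted
macro averages, and an F1 score taken as the harmonic mean of macro
precision and macro recall (per-class F1 and its macro average are also
exposed).  For a balanced 4-class problem with uniform predicted marginals
kappa reduces to ``(accuracy - 1/4) / (3/4)``.

The model-comparison test is the two-sided Wilcoxon signed-rank test on
paired per-subject scores: exact null distribution (all 2^n sign
assignments, average ranks for tied magnitudes) for n <= 25, a normal
approximation with continuity and tie correction above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .containers import TrialSet
from .model import Model, export_features, predict

__all__ = ["MetricsReport", "confusion_matrix", "cohen_kappa",
           "precision_recall_f1", "wilcoxon_signed_rank", "evaluate",
           "format_report", "export_features"]

CLASS_NAMES_4 = ("LH", "RH", "F", "Tou")


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Count matrix; entry (i, j) = trials with true class i predicted as j."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} true vs {y_pred.shape} predicted")
    if y_true.size and (min(y_true.min(), y_pred.min()) < 0
                        or max(y_true.max(), y_pred.max()) >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    conf = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(conf, (y_true, y_pred), 1)
    return conf


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e)."""
    conf = np.asarray(confusion, dtype=np.float64)
    total = conf.sum()
    if total <= 0:
        raise ValueError("confusion matrix must contain at least one trial")
    p_o = np.trace(conf) / total
    p_e = float((conf.sum(axis=1) * conf.sum(axis=0)).sum()) / total ** 2
    if p_e >= 1.0:
        warnings.warn("degenerate confusion matrix (chance agreement 1); kappa set to 0")
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def precision_recall_f1(confusion: np.ndarray) -> dict:
    """Per-class precision/recall/F1 plus macro averages.

    Classes with an empty column (never predicted) or empty row (never
    present) contribute 0 with a warning.  The headline ``f1`` is the
    harmonic mean of macro precision and macro recall; ``macro_f1`` (the
    unweighted mean of per-class F1) is also reported.
    """
    conf = np.asarray(confusion, dtype=np.float64)
    diag = np.diag(conf)
    col = conf.sum(axis=0)
    row = conf.sum(axis=1)
    if np.any(col == 0) or np.any(row == 0):
        warnings.warn("zero-denominator class treated as precision/recall 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, diag / np.maximum(col, 1e-300), 0.0)
        recall = np.where(row > 0, diag / np.maximum(row, 1e-300), 0.0)
        per_class_f1 = np.where(precision + recall > 0,
                                2 * precision * recall / np.maximum(precision + recall, 1e-300),
                                0.0)
    macro_p = float(precision.mean())
    macro_r = float(recall.mean())
    f1 = 2 * macro_p * macro_r / (macro_p + macro_r) if macro_p + macro_r > 0 else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "per_class_f1": per_class_f1,
        "macro_precision": macro_p,
        "macro_recall": macro_r,
        "macro_f1": float(per_class_f1.mean()),
        "f1": float(f1),
    }


@dataclass
class MetricsReport:
    """Full performance report of one model on one trial set."""

    confusion: np.ndarray
    accuracy: float
    kappa: float
    precision: np.ndarray
    recall: np.ndarray
    per_class_f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    f1: float

    @classmethod
    def from_predictions(cls, y_true, y_pred, n_classes: int) -> "MetricsReport":
        conf = confusion_matrix(y_true, y_pred, n_classes)
        prf = precision_recall_f1(conf)
        return cls(confusion=conf,
                   accuracy=float(np.trace(conf) / conf.sum()),
                   kappa=cohen_kappa(conf),
                   precision=prf["precision"], recall=prf["recall"],
                   per_class_f1=prf["per_class_f1"],
                   macro_precision=prf["macro_precision"],
                   macro_recall=prf["macro_recall"],
                   macro_f1=prf["macro_f1"], f1=prf["f1"])

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "per_class_f1": self.per_class_f1.tolist(),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "f1": self.f1,
        }


def evaluate(model: Model, testset: TrialSet) -> MetricsReport:
    """Inference-mode evaluation of a trained model on held-out trials."""
    y_pred, _ = predict(model, testset)
    return MetricsReport.from_predictions(testset.labels, y_pred, model.n_classes)


def format_report(report: MetricsReport, class_names=None) -> str:
    """Plain-text table in the per-class layout of a 4-class study report."""
    k = report.confusion.shape[0]
    names = list(class_names or (CLASS_NAMES_4 if k == 4 else [f"c{i}" for i in range(k)]))
    lines = [
        f"Accuracy (%)  {100 * report.accuracy:.2f}",
        f"K value       {report.kappa:.3f}",
        f"F1 score      {report.f1:.3f}",
        "Precision",
    ]
    for name, p in zip(names, report.precision):
        lines.append(f"  {name:<4} {p:.3f}")
    lines.append(f"  Avg. {report.macro_precision:.3f}")
    lines.append("Recall")
    for name, r in zip(names, report.recall):
        lines.append(f"  {name:<4} {r:.3f}")
    lines.append(f"  Avg. {report.macro_recall:.3f}")
    return "\n".join(lines)


def _exact_wilcoxon_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p via the null distribution of W+ over all sign
    assignments (subset-sum generating function on doubled ranks)."""
    r2 = np.round(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts += shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    lo = counts[:w2 + 1].sum()       # P(W+ <= w_plus)
    hi = counts[w2:].sum()           # P(W+ >= w_plus)
    return float(min(1.0, 2 * min(lo, hi)))


def wilcoxon_signed_rank(per_subject_a, per_subject_b) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped; tied magnitudes receive average ranks.
    Returns ``(statistic, p)`` where the statistic is min(W+, W-).  All
    differences zero gives p = 1.
    """
    a = np.asarray(per_subject_a, dtype=np.float64)
    b = np.asarray(per_subject_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    stat = min(w_plus, w_minus)
    if n <= 25:
        return stat, _exact_wilcoxon_p(ranks, w_plus)
    # normal approximation with continuity and tie corrections
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts) / 48.0).sum())
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    z = (stat - mu + 0.5) / sigma
    return stat, float(min(1.0, 2 * norm.cdf(z)))
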