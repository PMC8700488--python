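"""Score-averaging ensemble and the binary-classification metric suite.

The ensemble combines two classifier branches by arithmetic averaging
of their per-image confidence scores.  Metrics follow the standard
definitions with OKC as the positive class:

* accuracy  = (TP + TN) / (TP + TN + FP + FN)
* precision = TP / (TP + FP)
* recall    = TP / (TP + FN)
* F1        = harmonic mean of precision and recall

Per-class rows are obtained by swapping the positive class; the macro
average is the unweighted mean of the per-class values and the
weighted average is support-proportional.  ROC points are computed at
every distinct score threshold and the AUC by trapezoidal
integration.

Conventions: a sample is predicted positive when ``p_okc >= 0.5``
(ties go positive); a metric whose denominator is zero is reported as
0 with a logged flag.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .models import PredictionScore
from .synthdata import NON_OKC, OKC

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.5


def ensemble_average(
    scores_a: list[PredictionScore], scores_b: list[PredictionScore]
) -> list[PredictionScore]:
    """Average two branches' confidence scores per image.

    Both lists must carry the same ids in the same order; the result
    is again a valid probability pair.
    """
    if len(scores_a) != len(scores_b):
        raise ValueError(f"branch lengths differ: {len(scores_a)} vs {len(scores_b)}")
    out = []
    for a, b in zip(scores_a, scores_b):
        if a.id != b.id:
            raise ValueError(f"branch ids misaligned: {a.id!r} vs {b.id!r}")
        p = (a.p_okc + b.p_okc) / 2.0
        out.append(PredictionScore(id=a.id, p_okc=p, p_nonokc=1.0 - p))
    return out


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with OKC as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: str = OKC

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def actual_positives(self) -> int:
        return self.tp + self.fn

    @property
    def actual_negatives(self) -> int:
        return self.tn + self.fp

    def swapped(self) -> "ConfusionMatrix":
        """The same table with the positive class exchanged."""
        return ConfusionMatrix(
            tp=self.tn, fp=self.fn, tn=self.tp, fn=self.fp, positive_class=NON_OKC
        )


def confusion(
    labels: list[int],
    scores: list[PredictionScore],
    threshold: float = DEFAULT_THRESHOLD,
) -> ConfusionMatrix:
    """Tally the confusion matrix; predicted positive iff p_okc >= threshold."""
    if len(labels) != len(scores):
        raise ValueError(f"length mismatch: {len(labels)} labels vs {len(scores)} scores")
    tp = fp = tn = fn = 0
    for y, s in zip(labels, scores):
        pred = 1 if s.p_okc >= threshold else 0
        if pred and y:
            tp += 1
        elif pred and not y:
            fp += 1
        elif not pred and not y:
            tn += 1
        else:
            fn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reported as 0", what)
        return 0.0
    return num / den


def _prf(cm: ConfusionMatrix) -> tuple[float, float, float]:
    precision = _safe_div(cm.tp, cm.tp + cm.fp, "precision")
    recall = _safe_div(cm.tp, cm.tp + cm.fn, "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1")
    return precision, recall, f1


@dataclass
class MetricsReport:
    """Full per-class metric report with macro/weighted aggregates."""

    cm: ConfusionMatrix
    accuracy: float
    per_class: dict[str, dict[str, float]]  # class -> precision/recall/f1/support
    macro_avg: dict[str, float]
    weighted_avg: dict[str, float]
    auc: float | None = None
    roc_points: list[tuple[float, float]] = field(default_factory=list)

    def summary(self) -> str:
        """Classification-report style text table."""
        lines = [f"{'':>12}  precision  recall  f1-score  support"]
        for cls in (OKC, NON_OKC):
            m = self.per_class[cls]
            lines.append(
                f"{cls:>12}  {m['precision']:>9.4f}  {m['recall']:>6.4f}"
                f"  {m['f1']:>8.4f}  {int(m['support']):>7d}"
            )
        lines.append("")
        lines.append(f"{'accuracy':>12}  {'':>9}  {'':>6}  {self.accuracy:>8.4f}  {self.cm.total:>7d}")
        for name, m in (("macro avg", self.macro_avg), ("weighted avg", self.weighted_avg)):
            lines.append(
                f"{name:>12}  {m['precision']:>9.4f}  {m['recall']:>6.4f}"
                f"  {m['f1']:>8.4f}  {self.cm.total:>7d}"
            )
        if self.auc is not None:
            lines.append(f"{'AUC':>12}  {self.auc:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "confusion": {
                "tp": self.cm.tp,
                "fp": self.cm.fp,
                "tn": self.cm.tn,
                "fn": self.cm.fn,
            },
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "macro_avg": self.macro_avg,
            "weighted_avg": self.weighted_avg,
            "auc": self.auc,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, per-class precision/recall/F1 and their aggregates."""
    if cm.total <= 0:
        raise ValueError("confusion matrix is empty")
    accuracy = (cm.tp + cm.tn) / cm.total

    per_class = {}
    for cls, view, support in (
        (OKC, cm, cm.actual_positives),
        (NON_OKC, cm.swapped(), cm.actual_negatives),
    ):
        p, r, f1 = _prf(view)
        per_class[cls] = {"precision": p, "recall": r, "f1": f1, "support": support}

    supports = np.array([per_class[c]["support"] for c in (OKC, NON_OKC)], dtype=float)
    macro, weighted = {}, {}
    for key in ("precision", "recall", "f1"):
        vals = np.array([per_class[c][key] for c in (OKC, NON_OKC)])
        macro[key] = float(vals.mean())
        weighted[key] = float(
            _safe_div((vals * supports).sum(), supports.sum(), f"weighted {key}")
        )
    return MetricsReport(
        cm=cm,
        accuracy=accuracy,
        per_class=per_class,
        macro_avg=macro,
        weighted_avg=weighted,
    )


def roc_auc(labels: list[int], p_okc: list[float]) -> tuple[list[tuple[float, float]], float]:
    """ROC points at every distinct threshold and the trapezoidal AUC.

    Requires at least one positive and one negative label.  Returns
    ``(points, auc)`` with points as (FPR, TPR) pairs ordered from
    (0, 0) to (1, 1).
    """
    y = np.asarray(labels)
    s = np.asarray(p_okc, dtype=np.float64)
    if len(y) != len(s):
        raise ValueError("length mismatch")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative sample")

    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep only the last index of each tied score block (one point per threshold)
    distinct = np.nonzero(np.diff(s_sorted, append=-np.inf))[0]
    tpr = np.concatenate([[0.0], tps[distinct] / n_pos])
    fpr = np.concatenate([[0.0], fps[distinct] / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    points = list(zip(fpr.tolist(), tpr.tolist()))
    return points, auc


def evaluate_scores(
    labels: list[int],
    scores: list[PredictionScore],
    threshold: float = DEFAULT_THRESHOLD,
) -> MetricsReport:
    """Confusion matrix, metric suite, and ROC/AUC in one report."""
    cm = confusion(labels, scores, threshold)
    report = metrics(cm)
    try:
        points, auc = roc_auc(labels, [s.p_okc for s in scores])
        report.roc_points = points
        report.auc = auc
    except ValueError:
        logger.warning("single-class input; ROC/AUC omitted from report")
    return report
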