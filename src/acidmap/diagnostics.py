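"""Diagnostic statistics for pH-based tumor discrimination.

The full metric battery used to judge a pH map as a classifier of tumor vs
para-tumor tissue: ROC analysis with the Youden-optimal threshold,
confusion-matrix metrics with Clopper-Pearson confidence intervals,
Cohen's kappa, and R-squared / SSE for regression comparisons.

Orientation convention (fixed throughout the package): tumor mucosa is the
*less acidic* class, so a point is called tumor when its pH is **greater
than or equal to** the threshold. The trapezoid AUC over the resulting ROC
equals the Mann-Whitney probability that a random tumor point has higher pH
than a random para-tumor point (ties counted half).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.stats import beta

__all__ = [
    "RocCurve",
    "ConfusionMatrix",
    "MetricReport",
    "roc_curve",
    "youden_threshold",
    "confusion",
    "metric_report",
    "regression_compare",
    "reconstruct_confusion",
    "mann_whitney_auc",
]


@dataclass(frozen=True)
class RocCurve:
    """ROC sweep: one operating point per candidate threshold.

    ``thresholds`` are sorted descending, starting with a +inf sentinel
    (call nothing positive); ``fpr``/``tpr`` are nondecreasing along the
    sweep. Positive call: score >= threshold.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with tumor as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one count")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (beta-quantile) binomial confidence interval."""
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.isf(alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass
class MetricReport:
    """Point estimates, 95% CIs and agreement statistics for one matrix."""

    cm: ConfusionMatrix
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float
    kappa: float | None
    ci_95: dict[str, tuple[float, float]] = field(default_factory=dict)
    auc: float | None = None
    optimal_threshold: float | None = None
    r_squared: float | None = None
    sse: float | None = None

    def to_dict(self) -> dict[str, Any]:
        return {
            "confusion": {
                "tp": self.cm.tp,
                "fp": self.cm.fp,
                "tn": self.cm.tn,
                "fn": self.cm.fn,
            },
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "ci_95": {k: list(v) for k, v in self.ci_95.items()},
            "auc": self.auc,
            "optimal_threshold": self.optimal_threshold,
            "r_squared": self.r_squared,
            "sse": self.sse,
        }

    def summary(self) -> str:
        def fmt(x, pct=True):
            if x is None:
                return "   --"
            return f"{100 * x:6.2f}%" if pct else f"{x:7.4f}"

        cm = self.cm
        lines = [
            "Diagnostic performance (positive class: tumor, call: pH >= thr)",
            "=" * 63,
            f"counts        tp={cm.tp}  fp={cm.fp}  tn={cm.tn}  fn={cm.fn}"
            f"  (n={cm.total})",
            f"sensitivity   {fmt(self.sensitivity)}   {self._ci('sensitivity')}",
            f"specificity   {fmt(self.specificity)}   {self._ci('specificity')}",
            f"PPV           {fmt(self.ppv)}   {self._ci('ppv')}",
            f"NPV           {fmt(self.npv)}   {self._ci('npv')}",
            f"accuracy      {fmt(self.accuracy)}   {self._ci('accuracy')}",
            f"Cohen's kappa {fmt(self.kappa, pct=False)}",
        ]
        if self.auc is not None:
            lines.append(f"AUC           {fmt(self.auc)}")
        if self.optimal_threshold is not None:
            lines.append(f"optimal thr   {self.optimal_threshold:7.3f} pH")
        if self.r_squared is not None:
            lines.append(f"R-squared     {fmt(self.r_squared, pct=False)}")
        if self.sse is not None:
            lines.append(f"SSE           {self.sse:9.2f}")
        return "\n".join(lines)

    def _ci(self, name: str) -> str:
        if name not in self.ci_95:
            return ""
        lo, hi = self.ci_95[name]
        return f"(95% CI {lo:.4f}-{hi:.4f})"


def roc_curve(labels, scores) -> RocCurve:
    """ROC over all candidate thresholds with a score >= threshold call.

    ``labels`` are binary (1 = tumor); ``scores`` are the pH values. The
    trapezoid AUC equals the Mann-Whitney estimate exactly, ties counted
    half.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValueError("labels and scores must be 1-D arrays of equal length")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC analysis needs both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    # Collapse tied scores: one operating point per distinct threshold.
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores)), sorted_scores.size - 1]
    tp_cum = np.cumsum(sorted_labels)[distinct]
    fp_cum = np.cumsum(1 - sorted_labels)[distinct]
    tpr = np.r_[0.0, tp_cum / n_pos]
    fpr = np.r_[0.0, fp_cum / n_neg]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def mann_whitney_auc(labels, scores) -> float:
    """Rank-based AUC: P(score_pos > score_neg) + 0.5 P(tie).

    Independent of the ROC sweep; used as its cross-check.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need both classes")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def youden_threshold(roc: RocCurve) -> tuple[float, float]:
    """Threshold maximising Youden's J = TPR - FPR.

    Ties are broken toward higher specificity (lower FPR), then toward the
    lower threshold. Any cut in the half-open gap between the optimal
    candidate score and the next lower distinct score classifies
    identically (the call is pH >= threshold); the returned value is the
    midpoint of that gap, so for perfectly separated classes it is the
    midpoint between the two class extremes.

    Returns ``(threshold, J)``.
    """
    j = roc.tpr - roc.fpr
    best = int(np.lexsort((roc.thresholds, roc.fpr, -j))[0])
    thr = float(roc.thresholds[best])
    if best + 1 < roc.thresholds.size:
        thr = 0.5 * (thr + float(roc.thresholds[best + 1]))
    return thr, float(j[best])


def confusion(labels, predictions) -> ConfusionMatrix:
    """Cross-tabulate binary labels against binary predictions."""
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    if labels.shape != predictions.shape or labels.ndim != 1:
        raise ValueError(
            f"length mismatch: {labels.shape} labels vs "
            f"{predictions.shape} predictions"
        )
    if labels.size < 1:
        raise ValueError("need at least one point")
    return ConfusionMatrix(
        tp=int(np.sum((labels == 1) & (predictions == 1))),
        fp=int(np.sum((labels == 0) & (predictions == 1))),
        tn=int(np.sum((labels == 0) & (predictions == 0))),
        fn=int(np.sum((labels == 1) & (predictions == 0))),
    )


def reconstruct_confusion(
    n_pos: int, n_neg: int, sensitivity: float, specificity: float
) -> ConfusionMatrix:
    """Nearest-integer confusion matrix from class sizes and printed
    sensitivity/specificity — the standard way to recover counts from a
    published report."""
    tp = int(round(sensitivity * n_pos))
    tn = int(round(specificity * n_neg))
    return ConfusionMatrix(tp=tp, fn=n_pos - tp, tn=tn, fp=n_neg - tn)


def metric_report(
    cm: ConfusionMatrix,
    auc: float | None = None,
    optimal_threshold: float | None = None,
) -> MetricReport:
    """All confusion-matrix metrics with exact 95% CIs.

    Metrics with a zero denominator are reported absent (``None``), never
    NaN. Kappa uses the unweighted binary form with chance agreement from
    the marginal products.
    """
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    total = cm.total
    ci: dict[str, tuple[float, float]] = {}

    def ratio(k: int, n: int, name: str) -> float | None:
        if n == 0:
            return None
        ci[name] = _clopper_pearson(k, n)
        return k / n

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    ppv = ratio(tp, tp + fp, "ppv")
    npv = ratio(tn, tn + fn, "npv")
    accuracy = (tp + tn) / total
    ci["accuracy"] = _clopper_pearson(tp + tn, total)
    p_o = accuracy
    p_pos = (tp + fn) / total
    p_call = (tp + fp) / total
    p_e = p_pos * p_call + (1 - p_pos) * (1 - p_call)
    kappa = None if p_e == 1.0 else (p_o - p_e) / (1 - p_e)
    return MetricReport(
        cm=cm,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        accuracy=accuracy,
        kappa=kappa,
        ci_95=ci,
        auc=auc,
        optimal_threshold=optimal_threshold,
    )


def regression_compare(predicted, reference) -> tuple[float | None, float]:
    """SSE and R-squared of predicted pH against reference pH.

    ``sse = sum (pred - ref)^2``; ``r_squared = 1 - sse / sum (ref -
    mean(ref))^2``. With zero reference variance R-squared is undefined and
    reported absent.
    """
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape or predicted.ndim != 1:
        raise ValueError("sequences must be 1-D and of equal length")
    if predicted.size < 2:
        raise ValueError("need at least 2 points")
    sse = float(np.sum((predicted - reference) ** 2))
    sst = float(np.sum((reference - reference.mean()) ** 2))
    r2 = None if sst == 0.0 else 1.0 - sse / sst
    return r2, sse
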