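"""Stiffness as a binary marker of driver-mutation status.

ROC analysis of mean ROI stiffness against molecular labels, Youden-optimal
threshold selection, confusion metrics at fixed clinical cut-offs (803 kPa
for any KRAS/NRAS/BRAF driver mutation, 850 kPa for KRAS), the
morphology-as-marker baselines, and per-case discordance reports for
heterogeneous tumors. The positive rule throughout is strict: a call is
positive when stiffness is *above* the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .config import ClassifierConfig
from .exceptions import InputError
from .cohort import PATTERNS

__all__ = [
    "ROCResult",
    "ConfusionMetrics",
    "CaseReport",
    "roc_curve",
    "youden_threshold",
    "metrics_at_threshold",
    "pattern_marker_metrics",
    "flag_heterogeneous_cases",
    "StiffnessThresholdClassifier",
]


@dataclass
class ROCResult:
    """ROC sweep: ``thresholds`` descending from +inf so that (fpr, tpr)
    runs from (0, 0) to (1, 1); ``auc`` is the trapezoidal area."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    n_positive: int
    n_negative: int


@dataclass
class ConfusionMetrics:
    """Confusion counts and derived rates at one operating point.

    ``threshold`` is a stiffness cut-off (kPa) or a pattern label for the
    morphology-as-marker baselines. Rates are NaN when their denominator is
    zero (single-class input), flagged via ``degenerate``.
    """

    tp: int
    fn: int
    tn: int
    fp: int
    threshold: float | str
    degenerate: bool = False

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fn + self.tn + self.fp
        return (self.tp + self.tn) / total if total else float("nan")

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


@dataclass
class CaseReport:
    """Per-ROI threshold calls for one multi-ROI case."""

    case_id: int
    rois: list[dict] = field(default_factory=list)
    discordant_any_driver: bool = False
    discordant_kras: bool = False


def _as_bool_labels(labels) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.dtype == bool:
        return lab
    if lab.dtype.kind in "iuf":
        return lab != 0
    return np.isin(lab, ("positive", "pos", "mutant", "mut", "1", "True", "true"))


def roc_curve(values, labels) -> ROCResult:
    """ROC curve of "stiffness above threshold => positive".

    The sweep runs over all distinct observed values plus the +/-inf
    endpoints; tied values step simultaneously. AUC is the trapezoidal area
    under the (fpr, tpr) polyline and equals the midrank Mann-Whitney
    U / (n_pos * n_neg).
    """
    v = np.asarray(values, float)
    y = _as_bool_labels(labels)
    if v.shape != y.shape or v.ndim != 1:
        raise InputError("values and labels must be 1D of equal length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise InputError("roc_curve requires both classes present")
    thresholds = np.concatenate([[np.inf], np.unique(v)[::-1], [-np.inf]])
    tpr = np.array([(v[y] > t).mean() for t in thresholds])
    fpr = np.array([(v[~y] > t).mean() for t in thresholds])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(
        thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
        n_positive=n_pos, n_negative=n_neg,
    )


def youden_threshold(roc: ROCResult) -> tuple[float, float]:
    """Operating point maximizing Youden's J = sensitivity + specificity - 1.

    Ties break toward the smallest threshold. The returned cut-off is the
    midpoint between the optimal observed value and the next larger one, so
    it falls inside the empirical gap it separates; degenerate sweeps
    (all values equal) return that value with J = 0 and a warning.
    """
    j = roc.tpr - roc.fpr
    finite = np.isfinite(roc.thresholds)
    if not finite.any():
        raise InputError("ROC has no finite thresholds")
    idx_all = np.nonzero(finite)[0]
    best_j = j[idx_all].max()
    # smallest threshold among the maximizers (thresholds are descending)
    best_idx = idx_all[j[idx_all] >= best_j - 1e-12][-1]
    t = roc.thresholds[best_idx]
    if best_j <= 0:
        warnings.warn("degenerate ROC: Youden J = 0", stacklevel=2)
        return float(t), float(max(best_j, 0.0))
    larger = roc.thresholds[np.isfinite(roc.thresholds) & (roc.thresholds > t)]
    cut = float((t + larger.min()) / 2.0) if larger.size else float(t)
    return cut, float(best_j)


def metrics_at_threshold(values, labels, threshold: float) -> ConfusionMetrics:
    """Confusion counts and rates at a fixed stiffness cut-off (strict >)."""
    v = np.asarray(values, float)
    y = _as_bool_labels(labels)
    if v.shape != y.shape or v.ndim != 1:
        raise InputError("values and labels must be 1D of equal length")
    call = v > threshold
    tp = int((call & y).sum())
    fp = int((call & ~y).sum())
    fn = int((~call & y).sum())
    tn = int((~call & ~y).sum())
    degenerate = (tp + fn == 0) or (tn + fp == 0)
    if degenerate:
        warnings.warn("single-class input: some rates undefined", stacklevel=2)
    return ConfusionMetrics(tp=tp, fn=fn, tn=tn, fp=fp,
                            threshold=float(threshold), degenerate=degenerate)


def pattern_marker_metrics(cohort: pd.DataFrame, marker_pattern: str) -> ConfusionMetrics:
    """Morphology-as-marker baseline: positive call = ROI has the pattern."""
    if marker_pattern not in PATTERNS:
        raise InputError(f"unknown pattern {marker_pattern!r}")
    if not (cohort["pattern"] == marker_pattern).any():
        raise InputError(f"pattern {marker_pattern!r} absent from cohort")
    call = (cohort["pattern"] == marker_pattern).to_numpy()
    y = (cohort["mutation"] != "wt").to_numpy()
    tp = int((call & y).sum())
    fp = int((call & ~y).sum())
    fn = int((~call & y).sum())
    tn = int((~call & ~y).sum())
    return ConfusionMetrics(tp=tp, fn=fn, tn=tn, fp=fp, threshold=marker_pattern)


def flag_heterogeneous_cases(
    cohort: pd.DataFrame, config: ClassifierConfig | None = None
) -> list[CaseReport]:
    """Per-case threshold calls and discordance flags for multi-ROI cases.

    For each case with two or more ROIs, every ROI is called against the
    any-driver and KRAS thresholds; a case is flagged discordant when its
    ROIs disagree, which localizes putative intratumoral molecular
    heterogeneity. Single-ROI cases produce no report.
    """
    cfg = config or ClassifierConfig()
    reports: list[CaseReport] = []
    for case_id, grp in cohort.groupby("case_id", sort=True):
        if len(grp) < 2:
            continue
        rois = []
        for _, row in grp.iterrows():
            rois.append(
                {
                    "roi_id": row["roi_id"],
                    "pattern": row["pattern"],
                    "stiffness_kpa": float(row["stiffness_kpa"]),
                    "call_any_driver": bool(
                        row["stiffness_kpa"] > cfg.threshold_any_driver_kpa
                    ),
                    "call_kras": bool(row["stiffness_kpa"] > cfg.threshold_kras_kpa),
                    "mutation": row["mutation"],
                }
            )
        any_calls = {r["call_any_driver"] for r in rois}
        kras_calls = {r["call_kras"] for r in rois}
        reports.append(
            CaseReport(
                case_id=int(case_id),
                rois=rois,
                discordant_any_driver=len(any_calls) > 1,
                discordant_kras=len(kras_calls) > 1,
            )
        )
    return reports


class StiffnessThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Single-threshold stiffness classifier with ROC-derived cut-off.

    Parameters
    ----------
    threshold : float or None, default None
        Fixed stiffness cut-off in kPa (strict >). When None, ``fit``
        selects the Youden-optimal threshold from the training ROC.

    Attributes
    ----------
    threshold_ : float
        Operating cut-off after fitting.
    roc_ : ROCResult
        Training ROC sweep.
    auc_ : float
        Training area under the ROC curve.
    youden_j_ : float
        Youden J at the fitted threshold (only when selected from data).
    """

    def __init__(self, threshold: float | None = None):
        self.threshold = threshold

    def fit(self, X, y) -> "StiffnessThresholdClassifier":
        v = np.asarray(X, float)
        if v.ndim == 2 and v.shape[1] == 1:
            v = v[:, 0]
        if v.ndim != 1:
            raise InputError("X must be 1D stiffness values or a single column")
        yb = _as_bool_labels(y)
        self.classes_ = np.array([False, True])
        self.roc_ = roc_curve(v, yb)
        self.auc_ = self.roc_.auc
        if self.threshold is None:
            self.threshold_, self.youden_j_ = youden_threshold(self.roc_)
        else:
            self.threshold_ = float(self.threshold)
        self.n_features_in_ = 1
        return self

    def decision_function(self, X) -> np.ndarray:
        v = np.asarray(X, float)
        if v.ndim == 2 and v.shape[1] == 1:
            v = v[:, 0]
        return v - self.threshold_

    def predict(self, X) -> np.ndarray:
        return self.decision_function(X) > 0
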