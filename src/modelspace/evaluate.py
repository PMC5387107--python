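"""Regression error, remission classification, and ROC analysis.

The regression error is the cross-validated rms of Eq.-style form: the
square root of the per-subject-averaged squared prediction error, averaged
over all validation subject-courses.

Dichotomization uses the clinical remission thresholds on the *predicted*
continuous symptom score, with an optional nonnegative *critical value* c
subtracted from the point estimate first: a case is classified as
remission iff ``point_estimate - c <= threshold`` (boundary inclusive).
Raising c trades specificity for sensitivity; sweeping it generates a ROC
curve.  The sweep can parameterize c either additively (one scalar offset
for all cases) or through predictive quantiles (c_i is the half-width to
the predictive distribution's lower bound at a common confidence level, so
more uncertain predictions get larger offsets).  The quantile sweep is the
default, honoring the probabilistic reading of the critical value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from ._exceptions import ConfigurationError, DataError

__all__ = [
    "ConfusionMatrix",
    "OperatingPoint",
    "ROCCurve",
    "rms_error",
    "classify",
    "confusion_metrics",
    "roc_curve",
    "select_operating_point",
    "apply_operating_point",
    "null_model_rates",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of true/false positives/negatives (positive = remission)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DataError("confusion-matrix counts must be nonnegative")

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        t = np.asarray(y_true).astype(bool)
        p = np.asarray(y_pred).astype(bool)
        if t.shape != p.shape:
            raise DataError("label arrays differ in shape")
        return cls(
            tp=int(np.sum(t & p)),
            fp=int(np.sum(~t & p)),
            fn=int(np.sum(t & ~p)),
            tn=int(np.sum(~t & ~p)),
        )

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class OperatingPoint:
    """A classifier setting: remission threshold plus critical value.

    ``kind`` is "additive" (critical_value is a scalar score offset) or
    "quantile" (critical_value is a one-sided confidence level in [0.5, 1),
    converted per case to an offset via the predictive distribution).
    """

    critical_value: float
    threshold: float
    kind: str = "additive"

    def __post_init__(self) -> None:
        if self.critical_value < 0:
            raise ConfigurationError("critical_value must be nonnegative")
        if self.kind not in ("additive", "quantile"):
            raise ConfigurationError(f"unknown operating-point kind {self.kind!r}")


@dataclass
class ROCCurve:
    """ROC points (fpr, tpr) swept over a critical-value grid, plus AUC."""

    points: list[tuple[float, float]]
    auc: float
    grid: np.ndarray = field(default=None)  # type: ignore[assignment]
    kind: str = "additive"


def rms_error(results: Sequence[tuple[np.ndarray, np.ndarray]]) -> float:
    """Cross-validated rms error over subject-courses.

    ``results`` holds one ``(y_true, y_hat)`` pair of aligned arrays per
    validation subject-course (across all folds, so its length is the
    number of folds times the validation subjects per fold).  Each
    subject's squared errors are averaged over their own appointments
    before averaging across subject-courses, so subjects with long courses
    do not dominate; the square root is applied last.
    """
    results = list(results)
    if not results:
        raise DataError("rms_error needs at least one subject-course")
    per_subject = []
    for y_true, y_hat in results:
        y_true = np.asarray(y_true, float).ravel()
        y_hat = np.asarray(y_hat, float).ravel()
        if y_true.size == 0 or y_true.size != y_hat.size:
            raise DataError("each subject-course needs aligned, nonempty arrays")
        per_subject.append(float(np.mean((y_true - y_hat) ** 2)))
    return float(np.sqrt(np.mean(per_subject)))


def classify(point_estimate: float, op: OperatingPoint) -> int:
    """Remission (1) iff ``point_estimate - critical_value <= threshold``.

    Only valid for additive operating points; boundary ties label remission.
    """
    if op.kind != "additive":
        raise ConfigurationError("classify() needs an additive operating point; "
                                 "use apply_operating_point for quantile kind")
    return int(point_estimate - op.critical_value <= op.threshold)


def _case_offsets(
    grid_value: float,
    kind: str,
    n: int,
    scale_sq: np.ndarray | None,
    nu: np.ndarray | None,
) -> np.ndarray:
    if kind == "additive":
        return np.full(n, float(grid_value))
    if scale_sq is None or nu is None:
        raise ConfigurationError("quantile sweep needs per-case scale_sq and nu")
    return stats.t.ppf(float(grid_value), df=np.asarray(nu, float)) * np.sqrt(
        np.asarray(scale_sq, float)
    )


def _predict_remission(
    points: np.ndarray,
    threshold: float,
    grid_value: float,
    kind: str,
    scale_sq: np.ndarray | None,
    nu: np.ndarray | None,
) -> np.ndarray:
    c = _case_offsets(grid_value, kind, points.size, scale_sq, nu)
    return points - c <= threshold


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """SEN, SPC, BAC, PPV, NPV, accuracy, and Youden's J from counts.

    Metrics with a zero denominator are reported as None (never NaN).
    """
    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    sen = ratio(cm.tp, cm.tp + cm.fn)
    spc = ratio(cm.tn, cm.tn + cm.fp)
    bac = (sen + spc) / 2 if sen is not None and spc is not None else None
    return {
        "sen": sen,
        "spc": spc,
        "bac": bac,
        "ppv": ratio(cm.tp, cm.tp + cm.fp),
        "npv": ratio(cm.tn, cm.tn + cm.fn),
        "accuracy": ratio(cm.tp + cm.tn, cm.n),
        "youden_j": sen + spc - 1 if sen is not None and spc is not None else None,
    }


def _default_additive_grid(points: np.ndarray, threshold: float) -> np.ndarray:
    """Offsets hitting every achievable classification: midpoints between
    consecutive distinct values of (point - threshold) plus both extremes."""
    g = np.unique(np.asarray(points, float) - threshold)
    mids = (g[:-1] + g[1:]) / 2 if g.size > 1 else np.empty(0)
    return np.concatenate([[g[0] - 1.0], mids, [g[-1] + 1.0]])


def roc_curve(
    point_estimates: np.ndarray,
    labels: np.ndarray,
    threshold: float,
    grid: np.ndarray | None = None,
    kind: str = "quantile",
    scale_sq: np.ndarray | None = None,
    nu: np.ndarray | None = None,
) -> ROCCurve:
    """ROC curve from sweeping the critical value over a grid.

    ``kind`` "quantile" (default) sweeps one-sided confidence levels in
    (0, 1), converting each to per-case offsets from the predictive
    scale/dof; "additive" sweeps a common scalar offset (negative grid
    values are allowed so the sweep can reach both ROC corners).  AUC is
    the trapezoidal area over the sorted points with (0,0) and (1,1)
    appended.
    """
    points = np.asarray(point_estimates, float).ravel()
    y = np.asarray(labels).astype(bool).ravel()
    if points.size != y.size:
        raise DataError("point estimates and labels differ in length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("ROC needs both classes present")
    if grid is None:
        if kind == "additive":
            grid = _default_additive_grid(points, threshold)
        else:
            grid = np.linspace(0.005, 0.995, 199)
    grid = np.sort(np.asarray(grid, float).ravel())
    pts = []
    for c in grid:
        pred = _predict_remission(points, threshold, c, kind, scale_sq, nu)
        tpr = float(np.sum(y & pred)) / n_pos
        fpr = float(np.sum(~y & pred)) / n_neg
        pts.append((fpr, tpr))
    all_pts = sorted(set(pts) | {(0.0, 0.0), (1.0, 1.0)})
    fprs = np.array([p[0] for p in all_pts])
    tprs = np.array([p[1] for p in all_pts])
    auc = float(np.trapezoid(tprs, fprs))
    return ROCCurve(points=pts, auc=auc, grid=grid, kind=kind)


def select_operating_point(
    point_estimates: np.ndarray,
    labels: np.ndarray,
    threshold: float,
    grid: np.ndarray | None = None,
    kind: str = "quantile",
    scale_sq: np.ndarray | None = None,
    nu: np.ndarray | None = None,
) -> OperatingPoint:
    """Pick the critical value maximizing balanced accuracy on training data.

    The grid is restricted to nonnegative critical values (confidence
    levels >= 0.5 for the quantile sweep); ties break toward the smaller
    value.  Raises on single-class training labels.
    """
    points = np.asarray(point_estimates, float).ravel()
    y = np.asarray(labels).astype(bool).ravel()
    if y.all() or not y.any():
        raise DataError("operating-point selection needs both classes present")
    if grid is None:
        if kind == "additive":
            g = _default_additive_grid(points, threshold)
            grid = np.concatenate([[0.0], g[g > 0]])
        else:
            grid = np.linspace(0.5, 0.995, 100)
    grid = np.sort(np.asarray(grid, float).ravel())
    lo = 0.5 if kind == "quantile" else 0.0
    if np.any(grid < lo):
        raise ConfigurationError(f"operating-point grid must be >= {lo}")
    best_bac, best_c = -np.inf, None
    for c in grid:
        pred = _predict_remission(points, threshold, c, kind, scale_sq, nu)
        m = confusion_metrics(ConfusionMatrix.from_labels(y, pred))
        if m["bac"] is not None and m["bac"] > best_bac:
            best_bac, best_c = m["bac"], float(c)
    return OperatingPoint(critical_value=best_c, threshold=threshold, kind=kind)


def apply_operating_point(
    op: OperatingPoint,
    point_estimates: np.ndarray,
    scale_sq: np.ndarray | None = None,
    nu: np.ndarray | None = None,
) -> np.ndarray:
    """Binary remission predictions for a batch of cases under one setting."""
    points = np.asarray(point_estimates, float).ravel()
    return _predict_remission(
        points, op.threshold, op.critical_value, op.kind, scale_sq, nu
    ).astype(int)


def null_model_rates(prevalence: float) -> dict[str, float]:
    """Expected sensitivity/specificity of random guessing at the prevalence.

    A guesser predicting positive independently with probability q equal to
    the prevalence has expected sensitivity q and specificity 1 - q.
    """
    if not 0.0 < prevalence < 1.0:
        raise ConfigurationError(f"prevalence must be in (0, 1), got {prevalence}")
    return {"sen": float(prevalence), "spc": float(1.0 - prevalence)}
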