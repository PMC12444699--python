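"""Forecast evaluation: MAPE, interval coverage, ROC/AUC, Youden point.

MAPE here is the *median* of absolute percentage errors.  Count data have
zero days (about a fifth of days in the emulated admissions series), where
a percentage error is undefined; the default policy excludes those days
and reports how many were excluded, with a denominator-max-1 alternative.

AUC equals the Mann-Whitney U probability with half credit for ties; its
95% CI uses the DeLong variance estimator.  The ROC operating point is
chosen by Youden's J = sensitivity + specificity - 1, and the 2x2
confusion metrics (PPV, NPV, sensitivity, specificity) are reported both
at the Youden cut and at the 95th-percentile calibrated threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "MetricsReport",
    "RocCurve",
    "mape",
    "interval_coverage",
    "roc_curve",
    "auc",
    "youden_point",
    "confusion_metrics",
    "evaluate_forecasts",
]


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray  # descending; +inf first
    tpr: np.ndarray
    fpr: np.ndarray

    def __post_init__(self) -> None:
        if self.tpr[0] != 0.0 or self.fpr[0] != 0.0:
            raise ValueError("ROC curve must start at (0, 0)")
        if self.tpr[-1] != 1.0 or self.fpr[-1] != 1.0:
            raise ValueError("ROC curve must end at (1, 1)")
        if np.any(np.diff(self.tpr) < 0) or np.any(np.diff(self.fpr) < 0):
            raise ValueError("tpr and fpr must be non-decreasing")


@dataclass(frozen=True)
class MetricsReport:
    mape: float  # percent
    coverage: float  # percent
    ppv: float
    npv: float
    sensitivity: float
    specificity: float
    auc: float
    auc_lo: float
    auc_hi: float
    n_days: int
    zero_days_excluded: int
    youden_threshold: float = float("nan")
    calibrated_threshold: float = float("nan")
    ppv_calibrated: float = float("nan")
    npv_calibrated: float = float("nan")
    sens_calibrated: float = float("nan")
    spec_calibrated: float = float("nan")


def mape(points, actuals, zero_policy: str = "exclude") -> tuple[float, int]:
    """Median absolute percentage error, in percent.

    zero_policy 'exclude' drops zero-actual days (count returned);
    'denominator-max-1' uses max(actual, 1) as the denominator.
    """
    p = np.asarray(points, dtype=float)
    a = np.asarray(actuals, dtype=float)
    if len(p) != len(a) or len(p) == 0:
        raise ValueError("points and actuals must be equal, non-zero length")
    if zero_policy == "exclude":
        keep = a != 0
        n_excluded = int(np.sum(~keep))
        if not keep.any():
            raise ValueError("all days have zero actuals; no MAPE defined")
        ape = 100.0 * np.abs(p[keep] - a[keep]) / a[keep]
    elif zero_policy == "denominator-max-1":
        n_excluded = 0
        ape = 100.0 * np.abs(p - a) / np.maximum(a, 1.0)
    else:
        raise ValueError("zero_policy must be 'exclude' or 'denominator-max-1'")
    return float(np.median(ape)), n_excluded


def interval_coverage(lo, hi, actuals) -> float:
    """Percent of days whose interval contains the actual (inclusive)."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    a = np.asarray(actuals, dtype=float)
    if not (len(lo) == len(hi) == len(a)):
        raise ValueError("length mismatch")
    if np.any(lo > hi):
        raise ValueError("lo > hi for some interval")
    return float(100.0 * np.mean((lo <= a) & (a <= hi)))


def roc_curve(scores, labels) -> RocCurve:
    """Empirical ROC over all distinct score thresholds (predicate >=)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if len(s) != len(y):
        raise ValueError("length mismatch")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s) - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(~y_sorted)[distinct]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    tpr = np.r_[0.0, tps / n1]
    fpr = np.r_[0.0, fps / n0]
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr)


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def auc(scores, labels, level: float = 0.95) -> tuple[float, float, float]:
    """AUC (Mann-Whitney with half credit for ties) and DeLong 95% CI."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos = s[y]
    neg = s[~y]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    a = float((all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n))
    # DeLong structural components
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return a, max(0.0, a - half), min(1.0, a + half)


def youden_point(curve: RocCurve) -> tuple[float, float, float]:
    """Threshold maximizing J = sens + spec - 1.

    Ties break toward higher sensitivity, then lower threshold.  Returns
    (threshold, sensitivity, specificity).
    """
    j = curve.tpr - curve.fpr
    best = None
    for i in range(len(j)):
        key = (j[i], curve.tpr[i], -curve.thresholds[i])
        if best is None or key > best[0]:
            best = (key, i)
    i = best[1]
    return (
        float(curve.thresholds[i]),
        float(curve.tpr[i]),
        float(1.0 - curve.fpr[i]),
    )


def confusion_metrics(flags, labels) -> tuple[float, float, float, float]:
    """(PPV, NPV, sensitivity, specificity); NaN for empty denominators."""
    f = np.asarray(flags, dtype=bool)
    y = np.asarray(labels, dtype=bool)
    if len(f) != len(y):
        raise ValueError("length mismatch")
    tp = int(np.sum(f & y))
    fp = int(np.sum(f & ~y))
    fn = int(np.sum(~f & y))
    tn = int(np.sum(~f & ~y))

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return (
        ratio(tp, tp + fp),
        ratio(tn, tn + fn),
        ratio(tp, tp + fn),
        ratio(tn, tn + fp),
    )


def evaluate_forecasts(
    actuals,
    points,
    lo,
    hi,
    observed_thr: int,
    calibrated_thr: float | None = None,
    zero_policy: str = "exclude",
) -> MetricsReport:
    """Assemble the full per-model evaluation report.

    ROC scores are the continuous point forecasts; labels are observed
    count >= observed_thr.  PPV/NPV/sens/spec are reported at the
    Youden-optimal cut; if ``calibrated_thr`` is given, the same metrics
    at the 95th-percentile calibrated flag (strict >) are also included.
    """
    a = np.asarray(actuals, dtype=float)
    p = np.asarray(points, dtype=float)
    mape_val, n_excl = mape(p, a, zero_policy)
    cover = interval_coverage(lo, hi, a)
    labels = a >= observed_thr
    if labels.any() and not labels.all():
        auc_val, auc_lo, auc_hi = auc(p, labels)
        curve = roc_curve(p, labels)
        thr, sens, spec = youden_point(curve)
        flags = p >= thr
        ppv, npv, _, _ = confusion_metrics(flags, labels)
    else:
        auc_val = auc_lo = auc_hi = float("nan")
        thr = sens = spec = ppv = npv = float("nan")
    rep = dict(
        mape=mape_val,
        coverage=cover,
        ppv=ppv,
        npv=npv,
        sensitivity=sens,
        specificity=spec,
        auc=auc_val,
        auc_lo=auc_lo,
        auc_hi=auc_hi,
        n_days=len(a),
        zero_days_excluded=n_excl,
        youden_threshold=thr,
    )
    if calibrated_thr is not None:
        flags_c = p > calibrated_thr
        ppv_c, npv_c, sens_c, spec_c = confusion_metrics(flags_c, labels)
        rep.update(
            calibrated_threshold=float(calibrated_thr),
            ppv_calibrated=ppv_c,
            npv_calibrated=npv_c,
            sens_calibrated=sens_c,
            spec_calibrated=spec_c,
        )
    return MetricsReport(**rep)
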