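"""High-risk day calibration at the 95th percentile.

The observed threshold is the smallest integer count t such that at most
5% of historical days reached t or more admissions (for the emulated
series, t = 6).  Model predictions are continuous, so each model gets its
own threshold: the empirical 95th percentile (linear-interpolation
quantile) of its one-step-ahead predictions; days with predictions
strictly above it are flagged high-risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .series import DailySeries

__all__ = [
    "RiskCalibration",
    "observed_threshold",
    "prediction_threshold",
    "classify_days",
]


@dataclass(frozen=True)
class RiskCalibration:
    observed_threshold: int
    prediction_thresholds: dict[str, float] = field(default_factory=dict)
    percentile: float = 0.95

    def __post_init__(self) -> None:
        if self.observed_threshold < 1:
            raise ValueError("observed threshold must be >= 1")
        for name, thr in self.prediction_thresholds.items():
            if not np.isfinite(thr):
                raise ValueError(f"non-finite prediction threshold for {name}")


def observed_threshold(history: DailySeries | np.ndarray, percentile: float = 0.95) -> int:
    """Smallest integer t with fraction of days >= t at most (1 - percentile).

    Defined on the integer counts directly (no interpolation) so that a
    statement like "the top 5% of days had 6 or more admissions" is
    reproduced exactly.
    """
    counts = history.counts if isinstance(history, DailySeries) else np.asarray(history)
    if len(counts) == 0:
        raise ValueError("empty history")
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must be in (0, 1)")
    tail = 1.0 - percentile
    for t in range(1, int(counts.max()) + 2):
        if np.mean(counts >= t) <= tail:
            return t
    return int(counts.max()) + 1  # unreachable; loop always terminates above


def prediction_threshold(predicted, percentile: float = 0.95) -> float:
    """Empirical percentile (linear interpolation) of continuous predictions."""
    x = np.asarray(predicted, dtype=float)
    if len(x) < 20:
        raise ValueError("need at least 20 predicted values to calibrate")
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must be in (0, 1)")
    return float(np.quantile(x, percentile))


def classify_days(values, threshold: float, strict: bool = True) -> np.ndarray:
    """Flag days above the threshold.

    ``strict=True`` (>) is used for continuous predictions against their
    calibrated threshold; ``strict=False`` (>=) for integer counts against
    the observed threshold ("6 or more admissions").
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    x = np.asarray(values, dtype=float)
    return x > threshold if strict else x >= threshold
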