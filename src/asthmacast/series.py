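"""Core containers for daily admission-count series.

A :class:`DailySeries` is the y_t of every model in the package: a gap-free,
strictly increasing run of calendar dates with one non-negative integer
count per date.  :func:`summarize_structure` computes the descriptive
statistics (zero fraction, exceedance fractions, monthly / day-of-week /
yearly totals) used to characterise an admissions series and to calibrate
the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DailySeries", "StructureSummary", "summarize_structure"]


@dataclass(frozen=True)
class DailySeries:
    """Consecutive calendar dates with a non-negative integer count per day.

    Parameters
    ----------
    dates
        A ``pandas.DatetimeIndex`` of strictly increasing, gap-free calendar
        days (midnight timestamps, no timezone).
    counts
        Integer admissions per day, same length as ``dates``, all >= 0.
    """

    dates: pd.DatetimeIndex
    counts: np.ndarray

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        counts = np.asarray(self.counts)
        if len(dates) == 0:
            raise ValueError("DailySeries cannot be empty")
        if len(dates) != len(counts):
            raise ValueError(
                f"{len(dates)} dates but {len(counts)} counts"
            )
        diffs = np.diff(dates.view("int64"))
        one_day = 86_400_000_000_000
        if len(diffs) and not np.all(diffs == one_day):
            bad = int(np.flatnonzero(diffs != one_day)[0])
            raise ValueError(
                f"dates must be consecutive calendar days; gap or duplicate "
                f"after {dates[bad].date()}"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded):
                raise ValueError("counts must be integers")
            counts = rounded.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "counts", counts.astype(np.int64))

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def start(self) -> pd.Timestamp:
        return self.dates[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.dates[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "count": self.counts})

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.counts, index=self.dates, name="count")

    @classmethod
    def from_pandas(cls, s: pd.Series) -> "DailySeries":
        return cls(pd.DatetimeIndex(s.index), s.to_numpy())

    def window(self, start, end) -> "DailySeries":
        """Inclusive date-range slice."""
        start = pd.Timestamp(start)
        end = pd.Timestamp(end)
        mask = (self.dates >= start) & (self.dates <= end)
        if not mask.any():
            raise ValueError(f"no data in [{start.date()}, {end.date()}]")
        return DailySeries(self.dates[mask], self.counts[mask])

    def values(self) -> np.ndarray:
        return self.counts.astype(float)


@dataclass(frozen=True)
class StructureSummary:
    """Descriptive structure of a daily count series.

    ``monthly_totals`` is indexed Jan..Dec, ``dow_totals`` Mon..Sun,
    ``yearly_totals`` maps calendar year to its total.  All three
    decompositions conserve the grand total.
    """

    mean_daily: float
    zero_fraction: float
    monthly_totals: np.ndarray
    dow_totals: np.ndarray
    yearly_totals: dict[int, int]
    _exceedance: dict[int, float] = field(default_factory=dict, repr=False)

    def exceedance_fraction(self, t: int) -> float:
        """Fraction of days with count >= t."""
        return self._exceedance.get(int(t), 0.0)

    @property
    def total(self) -> int:
        return int(self.monthly_totals.sum())


def summarize_structure(series: DailySeries) -> StructureSummary:
    """Compute mean, zero fraction, exceedance fractions and totals.

    All quantities are exact functions of the counts; exceedance fractions
    are tabulated for every t from 1 to the maximum observed count.
    """
    counts = series.counts
    n = len(counts)
    mean_daily = float(counts.mean())
    zero_fraction = float(np.mean(counts == 0))
    df = series.to_frame()
    monthly = np.zeros(12, dtype=np.int64)
    by_month = df.groupby(df["date"].dt.month)["count"].sum()
    monthly[by_month.index.to_numpy() - 1] = by_month.to_numpy()
    dow = np.zeros(7, dtype=np.int64)
    by_dow = df.groupby(df["date"].dt.dayofweek)["count"].sum()
    dow[by_dow.index.to_numpy()] = by_dow.to_numpy()
    yearly = {
        int(y): int(v)
        for y, v in df.groupby(df["date"].dt.year)["count"].sum().items()
    }
    exceed = {
        t: float(np.mean(counts >= t)) for t in range(1, int(counts.max()) + 2)
    }
    return StructureSummary(
        mean_daily=mean_daily,
        zero_fraction=zero_fraction,
        monthly_totals=monthly,
        dow_totals=dow,
        yearly_totals=yearly,
        _exceedance=exceed,
    )
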