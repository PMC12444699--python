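"""Forecast container and the ensemble combiner.

A :class:`Forecast` is a per-date point estimate with a 95% interval.
The ensemble combines member model forecasts for the same date by
averaging points and averaging the lower and upper 95% limits, so the
ensemble interval width is exactly the mean of the member widths.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["Forecast", "ensemble_forecast"]


@dataclass(frozen=True)
class Forecast:
    date: pd.Timestamp
    point: float
    lo95: float
    hi95: float
    model_name: str

    def __post_init__(self) -> None:
        if not (self.lo95 <= self.point <= self.hi95):
            raise ValueError(
                f"forecast interval violated: lo95={self.lo95} "
                f"point={self.point} hi95={self.hi95}"
            )

    @property
    def width(self) -> float:
        return self.hi95 - self.lo95


def ensemble_forecast(forecasts: list[Forecast], name: str = "ensemble") -> Forecast:
    """Average member points and 95% limits for one date."""
    if len(forecasts) < 2:
        raise ValueError("ensemble needs at least 2 member forecasts")
    dates = {pd.Timestamp(f.date) for f in forecasts}
    if len(dates) != 1:
        raise ValueError(f"member forecasts are for different dates: {sorted(dates)}")
    k = len(forecasts)
    return Forecast(
        date=forecasts[0].date,
        point=sum(f.point for f in forecasts) / k,
        lo95=sum(f.lo95 for f in forecasts) / k,
        hi95=sum(f.hi95 for f in forecasts) / k,
        model_name=name,
    )
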