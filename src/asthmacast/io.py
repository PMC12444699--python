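"""Series/forecast CSV I/O and the declarative run configuration.

Formats are deliberately plain: the admissions series is a two-column CSV
``date,count`` with ISO-8601 dates; forecasts are
``date,model,point,lo95,hi95``; configuration round-trips through a flat
YAML document.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .series import DailySeries
from .synthetic import GeneratorConfig, reference_config

logger = logging.getLogger("asthmacast")

__all__ = [
    "read_admissions_csv",
    "write_admissions_csv",
    "read_forecasts_csv",
    "write_forecasts_csv",
    "RunConfig",
]


class CsvFormatError(ValueError):
    """Malformed input file; message carries line/date context."""


def read_admissions_csv(path, fill_zeros: bool = False) -> DailySeries:
    """Read a ``date,count`` CSV into a DailySeries.

    Duplicate dates are an error; gap dates are an error unless
    ``fill_zeros`` is set, in which case they are filled with 0 and
    logged.
    """
    df = pd.read_csv(path, dtype={"count": "object"})
    if list(df.columns[:2]) != ["date", "count"]:
        raise CsvFormatError(
            f"{path}: expected header 'date,count', got {list(df.columns)}"
        )
    try:
        dates = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise CsvFormatError(f"{path}: unparseable date ({exc})") from exc
    counts = pd.to_numeric(df["count"], errors="coerce")
    if counts.isna().any():
        line = int(counts.index[counts.isna()][0]) + 2  # header + 1-based
        raise CsvFormatError(f"{path}: unparseable count at line {line}")
    if (counts < 0).any():
        line = int(counts.index[counts < 0][0]) + 2
        raise CsvFormatError(f"{path}: negative count at line {line}")
    dup = dates[dates.duplicated()]
    if len(dup):
        raise CsvFormatError(f"{path}: duplicate date {dup.iloc[0].date()}")
    order = np.argsort(dates.to_numpy())
    dates = pd.DatetimeIndex(dates.to_numpy()[order])
    counts = counts.to_numpy()[order]
    full = pd.date_range(dates[0], dates[-1], freq="D")
    if len(full) != len(dates):
        if not fill_zeros:
            missing = full.difference(dates)
            raise CsvFormatError(
                f"{path}: {len(missing)} missing dates (first: "
                f"{missing[0].date()}); pass fill_zeros to fill with 0"
            )
        s = pd.Series(counts, index=dates).reindex(full, fill_value=0)
        logger.info("filled %d missing dates with 0", len(full) - len(dates))
        dates, counts = full, s.to_numpy()
    return DailySeries(dates, counts.astype(np.int64))


def write_admissions_csv(series: DailySeries, path) -> None:
    df = series.to_frame()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def write_forecasts_csv(frame: pd.DataFrame, path) -> None:
    """Write a backtest frame (date, model, point, lo95, hi95 [, actual])."""
    out = frame.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_forecasts_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"date", "model", "point", "lo95", "hi95"}
    missing = needed - set(df.columns)
    if missing:
        raise CsvFormatError(f"{path}: missing columns {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    return df


@dataclass
class RunConfig:
    """Single declarative document holding all module configurations."""

    generator: GeneratorConfig = field(default_factory=reference_config)
    start: str = "2016-01-01"
    end: str = "2023-12-31"
    validation_start: str = "2023-01-01"
    validation_end: str = "2023-12-31"
    training_years: int = 7
    window_policy: str = "sliding"
    models: tuple[str, ...] = ("arima", "ets", "prophet", "ensemble")
    risk_percentile: float = 0.95
    mape_zero_policy: str = "exclude"
    seed: int = 0

    def to_yaml(self, path=None) -> str:
        doc = {
            "generator": self.generator.to_dict(),
            "start": self.start,
            "end": self.end,
            "validation_start": self.validation_start,
            "validation_end": self.validation_end,
            "training_years": self.training_years,
            "window_policy": self.window_policy,
            "models": list(self.models),
            "risk_percentile": self.risk_percentile,
            "mape_zero_policy": self.mape_zero_policy,
            "seed": self.seed,
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    doc = yaml.safe_load(fh)
            except (OSError, FileNotFoundError):
                doc = yaml.safe_load(source)
        gen = GeneratorConfig.from_dict(doc.pop("generator", {}))
        doc["models"] = tuple(doc.get("models", ("arima", "ets", "prophet", "ensemble")))
        return cls(generator=gen, **doc)
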