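"""Rolling-origin validation with daily model refits.

The validation engine mimics deployment: model *structure* (ARIMA orders,
ETS form) is selected once on the initial training window; then, for every
validation day d, parameters are re-estimated on a window ending at d-1
(warm-started from the previous day) and a one-step forecast for d is
recorded.  No future observation ever enters a fit.

The training-window policy is explicit because the source protocol is
ambiguous about it: a sweep over 1-7-year initial windows is combined with
daily updates "on the most recent 365-day window".  ``sliding`` (default)
re-estimates on a sliding window whose length equals the initial training
window; ``sliding-365`` implements the literal most-recent-365-days rule;
``expanding`` grows the window from the initial training start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .arima import ArimaSpec, fit_arima, select_arima, forecast_arima
from .ets import EtsSpec, fit_ets, select_ets, forecast_ets, ets_candidates
from .forecast import Forecast, ensemble_forecast
from .metrics import evaluate_forecasts
from .prophet import ProphetSpec, fit_prophet, forecast_prophet
from .risk import observed_threshold, prediction_threshold
from .series import DailySeries

__all__ = [
    "BacktestConfig",
    "BacktestResult",
    "run_backtest",
    "evaluate_backtest",
    "sweep_training_windows",
    "covid_splits",
    "DEFAULT_ARIMA_CANDIDATES",
]

DEFAULT_ARIMA_CANDIDATES = [
    ArimaSpec(0, 1, 1),
    ArimaSpec(0, 1, 2),
    ArimaSpec(0, 1, 3),
    ArimaSpec(1, 1, 1),
    ArimaSpec(1, 1, 0),
    ArimaSpec(2, 1, 0),
]

WINDOW_POLICIES = ("sliding", "sliding-365", "expanding")


@dataclass(frozen=True)
class BacktestConfig:
    validation_start: pd.Timestamp
    validation_end: pd.Timestamp
    training_years: int = 1
    window_policy: str = "sliding"
    refit_cadence: int = 1
    horizon: int = 1
    models: tuple[str, ...] = ("arima", "ets", "prophet", "ensemble")
    arima_candidates: tuple[ArimaSpec, ...] = tuple(DEFAULT_ARIMA_CANDIDATES)
    ets_candidates: tuple[EtsSpec, ...] = tuple(ets_candidates())
    prophet_spec: ProphetSpec = field(default_factory=ProphetSpec)
    max_failure_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "validation_start", pd.Timestamp(self.validation_start))
        object.__setattr__(self, "validation_end", pd.Timestamp(self.validation_end))
        if self.validation_start > self.validation_end:
            raise ValueError("validation_start after validation_end")
        if not 1 <= self.training_years <= 7:
            raise ValueError("training_years must be in 1..7")
        if self.window_policy not in WINDOW_POLICIES:
            raise ValueError(f"window_policy must be one of {WINDOW_POLICIES}")
        if self.horizon != 1:
            raise ValueError("only one-step-ahead validation is supported")
        if self.refit_cadence < 1:
            raise ValueError("refit_cadence must be >= 1")
        unknown = set(self.models) - {"arima", "ets", "prophet", "ensemble"}
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        if "ensemble" in self.models and len(set(self.models) - {"ensemble"}) < 2:
            raise ValueError("ensemble requires at least two member models")

    @property
    def training_start(self) -> pd.Timestamp:
        return self.validation_start - pd.DateOffset(years=self.training_years)


@dataclass
class BacktestResult:
    """Per-validation-day table of actuals and per-model forecasts."""

    frame: pd.DataFrame  # columns: date, model, actual, point, lo95, hi95
    config: BacktestConfig
    selected: dict = field(default_factory=dict)
    calibration: dict = field(default_factory=dict)

    def for_model(self, name: str) -> pd.DataFrame:
        sub = self.frame[self.frame["model"] == name]
        if sub.empty:
            raise KeyError(f"no forecasts for model {name!r}")
        return sub.reset_index(drop=True)


class _ArimaRunner:
    name = "arima"

    def __init__(self, spec: ArimaSpec):
        self.spec = spec
        self.fit = None

    def refit(self, window: np.ndarray):
        start = self.fit.se.get("xopt") if self.fit is not None else None
        self.fit = fit_arima(window, self.spec, start_params=start, compute_se=False)

    def forecast(self, date, seed) -> Forecast:
        f = forecast_arima(self.fit, 1, dates=[date])[0]
        return f


class _EtsRunner:
    name = "ets"

    def __init__(self, spec: EtsSpec):
        self.spec = spec
        self.fit = None

    def refit(self, window: np.ndarray):
        start = self.fit.se.get("xopt") if self.fit is not None else None
        self.fit = fit_ets(window, self.spec, start_params=start)

    def forecast(self, date, seed) -> Forecast:
        return forecast_ets(self.fit, 1, dates=[date])[0]


class _ProphetRunner:
    name = "prophet"

    def __init__(self, spec: ProphetSpec):
        self.spec = spec
        self.fit = None

    def refit(self, window: np.ndarray):
        spec = self.spec
        if spec.yearly_order > 0 and len(window) < 2 * 366:
            # short training windows cannot identify yearly terms
            spec = replace(spec, yearly_order=0)
        self.fit = fit_prophet(window, spec)

    def forecast(self, date, seed) -> Forecast:
        return forecast_prophet(self.fit, 1, seed=seed, dates=[date])[0]


def _select_runners(train: DailySeries, config: BacktestConfig) -> list:
    runners = []
    members = [m for m in config.models if m != "ensemble"]
    if "arima" in members:
        spec = select_arima(train, list(config.arima_candidates))
        runners.append(_ArimaRunner(spec))
    if "ets" in members:
        spec = select_ets(train, list(config.ets_candidates))
        runners.append(_EtsRunner(spec))
    if "prophet" in members:
        runners.append(_ProphetRunner(config.prophet_spec))
    return runners


def run_backtest(series: DailySeries, config: BacktestConfig) -> BacktestResult:
    """Execute the rolling-origin one-step-ahead validation.

    Raises if the series does not cover the initial training window plus
    the validation period, or if any model fails to refit on more than
    ``config.max_failure_fraction`` of validation days.
    """
    t0 = config.training_start
    if series.start > t0 or series.end < config.validation_end:
        raise ValueError(
            f"series [{series.start.date()}, {series.end.date()}] does not cover "
            f"training from {t0.date()} and validation to "
            f"{config.validation_end.date()}"
        )
    val_dates = pd.date_range(config.validation_start, config.validation_end, freq="D")
    initial_train = series.window(t0, config.validation_start - pd.Timedelta(days=1))
    init_len = len(initial_train)
    runners = _select_runners(initial_train, config)
    selected = {r.name: str(getattr(r, "spec")) for r in runners}

    y_all = series.values()
    date_to_pos = {d: i for i, d in enumerate(series.dates)}
    rows = []
    failures = {r.name: 0 for r in runners}
    max_fail = config.max_failure_fraction * len(val_dates)

    for i, d in enumerate(val_dates):
        pos = date_to_pos[d]
        if config.window_policy == "sliding-365":
            lo_pos = max(0, pos - 365)
        elif config.window_policy == "sliding":
            lo_pos = max(0, pos - init_len)
        else:  # expanding: fixed start at the initial training origin
            lo_pos = date_to_pos[t0]
        window = y_all[lo_pos:pos]
        member_fcs = []
        day_seed = (config.seed * 100003 + i) % (2**31 - 1)
        for r in runners:
            if i % config.refit_cadence == 0 or r.fit is None:
                try:
                    r.refit(window)
                except Exception as exc:  # fall back to previous parameters
                    failures[r.name] += 1
                    if r.fit is None or failures[r.name] > max_fail:
                        raise RuntimeError(
                            f"{r.name} failed to refit on {d.date()} "
                            f"({failures[r.name]} failures): {exc}"
                        ) from exc
                    warnings.warn(
                        f"{r.name} refit failed on {d.date()}; reusing previous "
                        f"parameters ({exc})",
                        RuntimeWarning,
                    )
            fc = r.forecast(d, day_seed)
            member_fcs.append(fc)
            rows.append((d, r.name, y_all[pos], fc.point, fc.lo95, fc.hi95))
        if "ensemble" in config.models:
            ens = ensemble_forecast(member_fcs)
            rows.append((d, "ensemble", y_all[pos], ens.point, ens.lo95, ens.hi95))

    frame = pd.DataFrame(
        rows, columns=["date", "model", "actual", "point", "lo95", "hi95"]
    )
    return BacktestResult(frame=frame, config=config, selected=selected)


def evaluate_backtest(
    result: BacktestResult,
    history: DailySeries,
    percentile: float = 0.95,
    zero_policy: str = "exclude",
) -> pd.DataFrame:
    """One metrics row per model: MAPE, Cover %, PPV, NPV, Sens, Spec,
    AUC with 95% CI.

    The observed high-risk threshold comes from ``history`` (training-era
    counts); each model's calibrated prediction threshold is the 95th
    percentile of its own validation-period predictions.
    """
    obs_thr = observed_threshold(history, percentile)
    rows = []
    for name in result.config.models:
        sub = result.for_model(name)
        cal_thr = None
        if len(sub) >= 20:
            cal_thr = prediction_threshold(sub["point"], percentile)
        rep = evaluate_forecasts(
            sub["actual"], sub["point"], sub["lo95"], sub["hi95"],
            observed_thr=obs_thr, calibrated_thr=cal_thr, zero_policy=zero_policy,
        )
        rows.append(
            {
                "model": name,
                "mape": rep.mape,
                "coverage": rep.coverage,
                "ppv": rep.ppv,
                "npv": rep.npv,
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
                "auc": rep.auc,
                "auc_lo": rep.auc_lo,
                "auc_hi": rep.auc_hi,
                "n_days": rep.n_days,
                "zero_days_excluded": rep.zero_days_excluded,
            }
        )
    return pd.DataFrame(rows)


def sweep_training_windows(
    series: DailySeries,
    years_list: list[int],
    validation_start,
    validation_end,
    models: tuple[str, ...] = ("arima", "ets", "prophet", "ensemble"),
    seed: int = 0,
    **config_kwargs,
) -> pd.DataFrame:
    """Metrics table over initial-training-window lengths.

    One row per (training window length, model) with the full metric
    column set; per-cell failures are recorded as NaN rows so other cells
    survive.
    """
    tables = []
    for years in years_list:
        config = BacktestConfig(
            validation_start=validation_start,
            validation_end=validation_end,
            training_years=years,
            models=models,
            seed=seed,
            **config_kwargs,
        )
        try:
            result = run_backtest(series, config)
            history = series.window(
                config.training_start,
                config.validation_start - pd.Timedelta(days=1),
            )
            tab = evaluate_backtest(result, history)
        except (RuntimeError, ValueError) as exc:
            warnings.warn(
                f"backtest failed for {years}-year window: {exc}", RuntimeWarning
            )
            tab = pd.DataFrame({"model": list(models)})
        tab.insert(0, "training_years", years)
        tables.append(tab)
    return pd.concat(tables, ignore_index=True)


def covid_splits(series: DailySeries, seed: int = 0) -> dict[str, BacktestConfig]:
    """The pre-pandemic, pandemic-era, and two-year-validation configs.

    Pre-pandemic: train 2016-2018, validate 2019.  Pandemic era: train
    2020-2022, validate 2023.  Two-year validation: train 2016-2021,
    validate 2022-2023.  Years refer to the series' own calendar span,
    which must cover 2016-2023 (the synthetic analogue qualifies).
    """
    need_start, need_end = pd.Timestamp("2016-01-01"), pd.Timestamp("2023-12-31")
    if series.start > need_start or series.end < need_end:
        raise ValueError("series must span 2016-01-01 .. 2023-12-31")
    return {
        "pre_pandemic": BacktestConfig(
            validation_start="2019-01-01", validation_end="2019-12-31",
            training_years=3, seed=seed,
        ),
        "pandemic": BacktestConfig(
            validation_start="2023-01-01", validation_end="2023-12-31",
            training_years=3, seed=seed,
        ),
        "two_year_validation": BacktestConfig(
            validation_start="2022-01-01", validation_end="2023-12-31",
            training_years=6, seed=seed,
        ),
    }
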