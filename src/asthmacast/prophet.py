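"""Prophet-style decomposable forecaster: y(t) = g(t) + s(t) + eps_t.

g(t) is a continuous piecewise-linear trend with S changepoints placed
equally over the first 80% of the history; each changepoint's rate change
delta_j carries a Laplace(0, tau) prior, so the MAP estimate is least
squares with an L1 penalty (lambda = 1/tau) on the deltas.  s(t) is an
unpenalized Fourier series with weekly (period 7) and yearly (period
365.25) terms.  There is no holiday term: hospitals operate through
holidays, so h(t) = 0.

Forecast uncertainty is generated by Monte-Carlo simulation of future
trend changes: future changepoints arrive at the historical frequency
S/T per day, with slope changes drawn from a Laplace whose scale is the
mean absolute fitted delta, plus Gaussian observation noise; interval
limits are the 2.5%/97.5% sample quantiles.  This simulation scheme is
this package's own reimplementation choice for interval construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso

from .forecast import Forecast
from .series import DailySeries

__all__ = ["ProphetSpec", "ProphetFit", "fit_prophet", "forecast_prophet"]


@dataclass(frozen=True)
class ProphetSpec:
    n_changepoints: int = 25
    changepoint_scale: float = 0.05
    weekly_order: int = 3
    yearly_order: int = 10
    interval_level: float = 0.95
    uncertainty_samples: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_changepoints < 0:
            raise ValueError("n_changepoints must be >= 0")
        if self.changepoint_scale <= 0:
            raise ValueError("changepoint_scale tau must be > 0")
        if self.weekly_order < 0 or self.yearly_order < 0:
            raise ValueError("Fourier orders must be >= 0")


@dataclass
class ProphetFit:
    spec: ProphetSpec
    base_rate: float  # k: slope of the first segment (per scaled-time unit)
    offset: float  # m: intercept at t=0
    deltas: np.ndarray
    changepoints: np.ndarray  # scaled-time locations in (0, 1)
    changepoint_dates: pd.DatetimeIndex | None
    fourier_coefs: np.ndarray
    sigma2: float
    t_scale: float  # number of days mapped onto scaled time [0, 1]
    start_date: pd.Timestamp | None
    fitted: np.ndarray = field(default=None, repr=False)
    residuals: np.ndarray = field(default=None, repr=False)
    n: int = 0
    model_name: str = "prophet"


def _fourier_matrix(day_index: np.ndarray, weekly_order: int, yearly_order: int):
    cols = []
    for period, order in ((7.0, weekly_order), (365.25, yearly_order)):
        for k in range(1, order + 1):
            ang = 2.0 * np.pi * k * day_index / period
            cols.append(np.sin(ang))
            cols.append(np.cos(ang))
    if not cols:
        return np.zeros((len(day_index), 0))
    return np.column_stack(cols)


def _design(t: np.ndarray, cps: np.ndarray, X_seas: np.ndarray):
    """Columns: [1, t, relu(t - cp_j)..., seasonal...]."""
    hinges = np.maximum(0.0, t[:, None] - cps[None, :]) if len(cps) else np.zeros(
        (len(t), 0)
    )
    return np.column_stack([np.ones(len(t)), t, hinges, X_seas])


def fit_prophet(
    series: DailySeries | np.ndarray, spec: ProphetSpec
) -> ProphetFit:
    """MAP fit of the trend + seasonality decomposition.

    The L1-penalised least squares (penalty only on the changepoint rate
    adjustments) is solved exactly: the unpenalised columns (intercept,
    base slope, Fourier terms) are projected out, and a Lasso is solved on
    the residualised changepoint basis.
    """
    if isinstance(series, DailySeries):
        y = series.values()
        start_date = series.start
        dates = series.dates
    else:
        y = np.asarray(series, dtype=float)
        start_date = None
        dates = None
    n = len(y)
    if spec.yearly_order > 0 and n < 2 * 366:
        raise ValueError(
            "need at least two full years of history for yearly seasonality"
        )
    day_index = np.arange(n, dtype=float)
    t_scale = max(n - 1, 1)
    t = day_index / t_scale
    S = spec.n_changepoints
    cps = (
        np.linspace(0, 0.8, S + 2)[1:-1] if S > 0 else np.zeros(0)
    )  # equally spaced over first 80% of history, endpoints excluded
    X_seas = _fourier_matrix(day_index, spec.weekly_order, spec.yearly_order)
    U = np.column_stack([np.ones(n), t, X_seas])  # unpenalised
    H = np.maximum(0.0, t[:, None] - cps[None, :]) if S else np.zeros((n, 0))

    if S == 0:
        beta_u, *_ = np.linalg.lstsq(U, y, rcond=None)
        deltas = np.zeros(0)
    else:
        # project penalised columns and y onto the orthogonal complement of U
        Q, _ = np.linalg.qr(U)
        H_r = H - Q @ (Q.T @ H)
        y_r = y - Q @ (Q.T @ y)
        lam = 1.0 / spec.changepoint_scale
        # sklearn Lasso minimizes (1/2n)||y - Xw||^2 + a||w||_1
        lasso = Lasso(
            alpha=lam / n, fit_intercept=False, max_iter=50000, tol=1e-10
        )
        lasso.fit(H_r, y_r)
        deltas = np.asarray(lasso.coef_, dtype=float)
        beta_u, *_ = np.linalg.lstsq(U, y - H @ deltas, rcond=None)

    fitted = U @ beta_u + (H @ deltas if S else 0.0)
    resid = y - fitted
    sigma2 = float(np.dot(resid, resid) / max(n - (U.shape[1] + S), 1))
    cp_dates = (
        start_date + pd.to_timedelta(np.round(cps * t_scale), unit="D")
        if start_date is not None and S
        else None
    )
    return ProphetFit(
        spec=spec,
        base_rate=float(beta_u[1]),
        offset=float(beta_u[0]),
        deltas=deltas,
        changepoints=cps,
        changepoint_dates=cp_dates,
        fourier_coefs=np.asarray(beta_u[2:], dtype=float),
        sigma2=sigma2,
        t_scale=float(t_scale),
        start_date=start_date,
        fitted=np.asarray(fitted),
        residuals=np.asarray(resid),
        n=n,
    )


def _predict_mean(fit: ProphetFit, day_index: np.ndarray) -> np.ndarray:
    t = day_index / fit.t_scale
    X_seas = _fourier_matrix(day_index, fit.spec.weekly_order, fit.spec.yearly_order)
    H = (
        np.maximum(0.0, t[:, None] - fit.changepoints[None, :])
        if len(fit.changepoints)
        else np.zeros((len(t), 0))
    )
    return (
        fit.offset
        + fit.base_rate * t
        + (H @ fit.deltas if len(fit.deltas) else 0.0)
        + (X_seas @ fit.fourier_coefs if X_seas.shape[1] else 0.0)
    )


def forecast_prophet(
    fit: ProphetFit, h: int, seed: int | None = None, dates=None
) -> list[Forecast]:
    """Extrapolate g + s with future rate changes zero in the mean path;
    Monte-Carlo 95% intervals from simulated future changepoints."""
    if h < 1:
        raise ValueError("forecast horizon must be >= 1")
    spec = fit.spec
    n = fit.n
    future_idx = np.arange(n, n + h, dtype=float)
    mean_path = _predict_mean(fit, future_idx)

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    nsamp = spec.uncertainty_samples
    S, T = len(fit.deltas), n
    cp_prob = min(S / T, 1.0) if S else 0.0
    delta_scale = float(np.mean(np.abs(fit.deltas))) if S else 0.0
    sigma = np.sqrt(fit.sigma2)

    sims = np.tile(mean_path, (nsamp, 1))
    if cp_prob > 0 and delta_scale > 0:
        occur = rng.random((nsamp, h)) < cp_prob
        slopes = rng.laplace(0.0, delta_scale, size=(nsamp, h)) * occur
        # each future changepoint at step j adds slope*(i-j)/t_scale for i >= j
        steps = np.arange(1, h + 1, dtype=float)
        ramp = np.maximum(0.0, steps[None, :] - steps[:, None])  # [j, i]
        sims = sims + (slopes @ ramp) / fit.t_scale
    if sigma > 0:
        sims = sims + rng.normal(0.0, sigma, size=(nsamp, h))
    lo = np.quantile(sims, 0.5 * (1 - spec.interval_level), axis=0)
    hi = np.quantile(sims, 1 - 0.5 * (1 - spec.interval_level), axis=0)
    lo = np.minimum(lo, mean_path)
    hi = np.maximum(hi, mean_path)
    if dates is None:
        dates = [None] * h
    return [
        Forecast(
            date=dates[j],
            point=float(mean_path[j]),
            lo95=float(lo[j]),
            hi95=float(hi[j]),
            model_name=fit.model_name,
        )
        for j in range(h)
    ]


def prophet_one_step_path(fit: ProphetFit, length: int | None = None):
    """In-sample mean path (decomposition fitted values) with residual
    variance; the Prophet-style model is a regression, so its 'one-step'
    path is the fitted mean."""
    if length is None:
        return fit.fitted.copy(), np.full(fit.n, fit.sigma2)
    idx = np.arange(length, dtype=float)
    return _predict_mean(fit, idx), np.full(length, fit.sigma2)
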