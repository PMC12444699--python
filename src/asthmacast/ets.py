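"""Additive-class exponential smoothing (ETS) state-space models.

Supported forms: additive errors with trend in {none, additive, damped}
and seasonality in {none, additive} at an integer period m (weekly m=7 by
default for daily admissions).  Estimation maximizes the Gaussian
innovations likelihood over smoothing parameters and initial states;
model selection is by AIC.  h-step interval variances use the additive
class closed form sigma^2 * (1 + sum_{j<h} c_j^2) where c_j collects the
level, (damped-)trend and seasonal error weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from ._filters import ets_filter
from .forecast import Forecast
from .series import DailySeries

__all__ = ["EtsSpec", "EtsFit", "fit_ets", "select_ets", "forecast_ets", "ets_candidates"]

Z95 = 1.96
_TREND_CODES = {"none": 0, "additive": 1, "additive-damped": 2}


@dataclass(frozen=True)
class EtsSpec:
    error: str = "additive"
    trend: str = "none"
    seasonal: str = "none"
    period: int = 7

    def __post_init__(self) -> None:
        if self.error != "additive":
            raise ValueError("only additive errors are supported")
        if self.trend not in _TREND_CODES:
            raise ValueError(f"trend must be one of {sorted(_TREND_CODES)}")
        if self.seasonal not in ("none", "additive"):
            raise ValueError("seasonal must be 'none' or 'additive'")
        if self.period < 1:
            raise ValueError("period must be >= 1")

    @property
    def has_trend(self) -> bool:
        return self.trend != "none"

    @property
    def has_seasonal(self) -> bool:
        return self.seasonal == "additive"

    @property
    def n_params(self) -> int:
        """alpha (+beta, +phi, +gamma), initial states, sigma2."""
        k = 1 + 1  # alpha + initial level + ... start: alpha, l0
        if self.has_trend:
            k += 2  # beta, b0
            if self.trend == "additive-damped":
                k += 1  # phi
        if self.has_seasonal:
            k += 1 + (self.period - 1)  # gamma + m-1 free initial seasonals
        return k + 1  # sigma2

    def __str__(self) -> str:
        t = {"none": "N", "additive": "A", "additive-damped": "Ad"}[self.trend]
        s = "A" if self.has_seasonal else "N"
        return f"ETS(A,{t},{s})"


@dataclass
class EtsFit:
    spec: EtsSpec
    alpha: float
    beta: float
    gamma: float
    phi_damp: float
    initial_level: float
    initial_trend: float
    initial_seasonals: np.ndarray
    level: float
    trend: float
    seasonals: np.ndarray
    sigma2: float
    loglik: float
    aic: float
    residuals: np.ndarray
    fitted: np.ndarray
    se: dict = field(default_factory=dict)
    converged: bool = True
    n: int = 0
    model_name: str = "ets"


def _heuristic_init(y: np.ndarray, spec: EtsSpec):
    m = spec.period
    if spec.has_seasonal and len(y) >= 2 * m:
        nseas = min(len(y) // m, 8)
        folds = y[: nseas * m].reshape(nseas, m)
        seas = folds.mean(axis=0) - folds.mean()
        deseason = y[: nseas * m] - np.tile(seas, nseas)
        l0 = float(deseason[: min(len(deseason), 2 * m)].mean())
        s0 = seas - seas.mean()
    else:
        l0 = float(y[: max(2, min(10, len(y)))].mean())
        s0 = np.zeros(m)
    if spec.has_trend and len(y) >= 20:
        b0 = float((y[10:20].mean() - y[:10].mean()) / 10.0)
    else:
        b0 = 0.0
    return l0, b0, s0


def _run_filter(y, spec: EtsSpec, alpha, beta, gamma, phi, l0, b0, s0):
    return ets_filter(
        y,
        float(alpha),
        float(beta),
        float(gamma),
        float(phi),
        float(l0),
        float(b0),
        np.asarray(s0, dtype=float),
        _TREND_CODES[spec.trend],
        1 if spec.has_seasonal else 0,
        spec.period,
    )


def fit_ets(
    series: DailySeries | np.ndarray,
    spec: EtsSpec,
    start_params: np.ndarray | None = None,
) -> EtsFit:
    """Maximize the Gaussian innovations likelihood.

    Parameters are alpha (and beta, phi, gamma as applicable) plus the
    initial level/trend/seasonal states; sigma^2 is concentrated out as
    SSE/n, giving loglik = -n/2 * (log(2 pi SSE/n) + 1).
    """
    if isinstance(series, DailySeries):
        y = series.values()
    else:
        y = np.asarray(series, dtype=float)
    n = len(y)
    m = spec.period
    if spec.has_seasonal and n < 3 * m:
        raise ValueError(f"need at least 3 full periods ({3 * m}) for {spec}")
    if n < 10:
        raise ValueError("series too short for ETS estimation")

    l0h, b0h, s0h = _heuristic_init(y, spec)

    # free parameter vector layout:
    # [alpha, (beta), (phi), (gamma), l0, (b0), (s0 first m-1)]
    names = ["alpha"]
    lo, hi, x0 = [1e-4], [0.9999], [0.2]
    if spec.has_trend:
        names.append("beta")
        lo.append(1e-4); hi.append(0.9999); x0.append(0.05)
        if spec.trend == "additive-damped":
            names.append("phi")
            lo.append(0.8); hi.append(0.98); x0.append(0.95)
    if spec.has_seasonal:
        names.append("gamma")
        lo.append(1e-4); hi.append(0.9999); x0.append(0.05)
    span = max(float(np.std(y)) * 10.0, 1.0)
    names.append("l0"); lo.append(l0h - span); hi.append(l0h + span); x0.append(l0h)
    if spec.has_trend:
        names.append("b0"); lo.append(-span); hi.append(span); x0.append(b0h)
    if spec.has_seasonal:
        for j in range(m - 1):
            names.append(f"s{j}")
            lo.append(-span); hi.append(span); x0.append(s0h[j])

    def unpack(x):
        i = 0
        alpha = x[i]; i += 1
        beta = gamma = 0.0
        phi = 1.0
        if spec.has_trend:
            beta = x[i]; i += 1
            if spec.trend == "additive-damped":
                phi = x[i]; i += 1
        if spec.has_seasonal:
            gamma = x[i]; i += 1
        l0 = x[i]; i += 1
        b0 = 0.0
        if spec.has_trend:
            b0 = x[i]; i += 1
        s0 = np.zeros(m)
        if spec.has_seasonal:
            s0[: m - 1] = x[i:]
            s0[m - 1] = -s0[: m - 1].sum()  # seasonals sum to zero
        return alpha, beta, gamma, phi, l0, b0, s0

    def negll(x):
        alpha, beta, gamma, phi, l0, b0, s0 = unpack(x)
        if spec.has_seasonal and not (gamma < 1.0 - alpha):
            return 1e12
        if spec.has_trend and not (beta < alpha):
            return 1e12
        _, e, _, _, _ = _run_filter(y, spec, alpha, beta, gamma, phi, l0, b0, s0)
        sse = float(np.dot(e, e))
        if not np.isfinite(sse) or sse <= 0:
            return 1e12
        return 0.5 * n * (np.log(2 * np.pi * sse / n) + 1.0)

    bounds = list(zip(lo, hi))
    starts = [np.array(x0)]
    if start_params is not None and len(start_params) == len(x0):
        starts.insert(0, np.clip(np.asarray(start_params, float), lo, hi))
    else:
        rng = np.random.default_rng(0)
        alt = np.array(x0)
        alt[0] = 0.6
        starts.append(alt)
        jit = np.array(x0) + rng.normal(0, 0.05, len(x0))
        starts.append(np.clip(jit, lo, hi))
    best = None
    for x_init in starts:
        res = optimize.minimize(negll, x_init, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
        if start_params is not None and res.success:
            break
    xopt = best.x
    converged = bool(best.success and np.isfinite(best.fun))
    if not converged:
        warnings.warn(f"{spec}: optimizer did not report convergence", RuntimeWarning)

    alpha, beta, gamma, phi, l0, b0, s0 = unpack(xopt)
    fitted, e, l_fin, b_fin, s_fin = _run_filter(
        y, spec, alpha, beta, gamma, phi, l0, b0, s0
    )
    sse = float(np.dot(e, e))
    sigma2 = sse / n
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    aic = -2.0 * ll + 2.0 * spec.n_params
    return EtsFit(
        spec=spec,
        alpha=float(alpha),
        beta=float(beta),
        gamma=float(gamma),
        phi_damp=float(phi),
        initial_level=float(l0),
        initial_trend=float(b0),
        initial_seasonals=s0,
        level=float(l_fin),
        trend=float(b_fin),
        seasonals=np.asarray(s_fin),
        sigma2=sigma2,
        loglik=float(ll),
        aic=float(aic),
        residuals=np.asarray(e),
        fitted=np.asarray(fitted),
        se={"xopt": xopt},
        converged=converged,
        n=n,
    )


def forecast_ets(fit: EtsFit, h: int, dates=None) -> list[Forecast]:
    """h-step forecasts with the additive-class analytic variance."""
    if h < 1:
        raise ValueError("forecast horizon must be >= 1")
    spec = fit.spec
    m = spec.period
    points = np.empty(h)
    for j in range(1, h + 1):
        if spec.trend == "none":
            mu = fit.level
        elif spec.trend == "additive":
            mu = fit.level + j * fit.trend
        else:
            phi = fit.phi_damp
            mu = fit.level + fit.trend * phi * (1 - phi**j) / (1 - phi)
        if spec.has_seasonal:
            mu += fit.seasonals[(j - 1) % m]
        points[j - 1] = mu
    # error weights c_j: var_h = sigma2 * (1 + sum_{j=1}^{h-1} c_j^2)
    var = np.empty(h)
    csum = 0.0
    var[0] = fit.sigma2
    for j in range(1, h):
        if spec.trend == "none":
            c = fit.alpha
        elif spec.trend == "additive":
            c = fit.alpha + fit.beta * j
        else:
            phi = fit.phi_damp
            c = fit.alpha + fit.beta * phi * (1 - phi**j) / (1 - phi)
        if spec.has_seasonal and j % m == 0:
            c += fit.gamma
        csum += c * c
        var[j] = fit.sigma2 * (1.0 + csum)
    sd = np.sqrt(var)
    if dates is None:
        dates = [None] * h
    return [
        Forecast(
            date=dates[j],
            point=float(points[j]),
            lo95=float(points[j] - Z95 * sd[j]),
            hi95=float(points[j] + Z95 * sd[j]),
            model_name=fit.model_name,
        )
        for j in range(h)
    ]


def ets_one_step_path(fit: EtsFit, y: np.ndarray):
    """One-step-ahead forecasts along y using fit's parameters and initial
    states; returns (points, variances)."""
    fitted, e, _, _, _ = _run_filter(
        np.asarray(y, dtype=float),
        fit.spec,
        fit.alpha,
        fit.beta,
        fit.gamma,
        fit.phi_damp,
        fit.initial_level,
        fit.initial_trend,
        fit.initial_seasonals,
    )
    return np.asarray(fitted), np.full(len(y), fit.sigma2)


def ets_candidates(period: int = 7) -> list[EtsSpec]:
    """The candidate set compared by AIC: simple exponential smoothing,
    Holt linear, damped Holt, and their additive-seasonal counterparts."""
    specs = []
    for trend in ("none", "additive", "additive-damped"):
        for seasonal in ("none", "additive"):
            specs.append(EtsSpec(trend=trend, seasonal=seasonal, period=period))
    return specs


def select_ets(
    series: DailySeries | np.ndarray, candidates: list[EtsSpec] | None = None
) -> EtsSpec:
    """Return the minimal-AIC spec among the candidates."""
    if candidates is None:
        candidates = ets_candidates()
    if not candidates:
        raise ValueError("candidate list is empty")
    best = None
    for spec in candidates:
        try:
            fit = fit_ets(series, spec)
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"{spec} failed to fit: {exc}", RuntimeWarning)
            continue
        if best is None or fit.aic < best[1]:
            best = (spec, fit.aic)
    if best is None:
        raise RuntimeError("no ETS candidate could be fitted")
    return best[0]
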