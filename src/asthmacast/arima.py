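"""ARIMA(p,d,q) with constant: exact Gaussian MLE via a state-space filter.

The d-times differenced series z_t is modelled as a stationary, invertible
ARMA(p,q) process around a mean mu (for d=1 the constant acts as drift, so
long-range forecasts of the original series grow by the constant per step
and the level forecast reverts toward the series mean trend, which is the
reason the constant is included).  The likelihood is the exact Gaussian
likelihood computed with the Kalman filter in the Harvey companion form,
with sigma^2 concentrated out.  Stationarity/invertibility are enforced by
optimizing over partial-autocorrelation-transformed parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from ._filters import kalman_filter_arma, kalman_state_arma
from .diagnostics import difference, ljung_box
from .forecast import Forecast
from .series import DailySeries

__all__ = ["ArimaSpec", "ArimaFit", "fit_arima", "select_arima", "forecast_arima"]

Z95 = 1.96


class ConvergenceError(RuntimeError):
    """Raised when an optimizer fails to produce a usable fit."""


@dataclass(frozen=True)
class ArimaSpec:
    p: int
    d: int
    q: int
    include_constant: bool = True

    def __post_init__(self) -> None:
        if self.p < 0 or self.q < 0:
            raise ValueError("p and q must be >= 0")
        if self.d not in (0, 1):
            raise ValueError("d must be 0 or 1")
        if self.p + self.q == 0 and not self.include_constant:
            raise ValueError("need p+q >= 1 or a constant term")

    @property
    def n_params(self) -> int:
        """Estimated parameters counted for AIC/BIC: ARMA + constant + sigma2."""
        return self.p + self.q + int(self.include_constant) + 1

    def __str__(self) -> str:
        c = "+c" if self.include_constant else ""
        return f"ARIMA({self.p},{self.d},{self.q}){c}"


@dataclass
class ArimaFit:
    spec: ArimaSpec
    phi: np.ndarray
    theta: np.ndarray
    mu: float
    sigma2: float
    loglik: float
    aic: float
    bic: float
    residuals: np.ndarray
    se: dict = field(default_factory=dict)
    converged: bool = True
    n: int = 0
    last_y: float = 0.0
    final_state: np.ndarray | None = None
    final_cov: np.ndarray | None = None
    model_name: str = "arima"

    @property
    def constant(self) -> float:
        """Constant c of the ARMA equation, c = mu * (1 - sum(phi))."""
        return self.mu * (1.0 - float(np.sum(self.phi)))


def _pacf_to_coef(x: np.ndarray) -> np.ndarray:
    """Map unconstrained reals to stationary AR (or invertible MA) coefs."""
    r = x / np.sqrt(1.0 + x**2)
    k = len(r)
    phi = r.copy()
    for j in range(1, k):
        phi[:j] = phi[:j] - r[j] * phi[j - 1 :: -1]
    return phi


def _state_matrices(phi: np.ndarray, theta: np.ndarray):
    p, q = len(phi), len(theta)
    m = max(p, q + 1)
    T = np.zeros((m, m))
    T[:p, 0] = phi
    T[:-1, 1:] = np.eye(m - 1)
    R = np.zeros(m)
    R[0] = 1.0
    R[1 : q + 1] = theta
    RRt = np.outer(R, R)
    # stationary covariance: vec(P) = (I - T kron T)^{-1} vec(RRt)
    m2 = m * m
    A = np.eye(m2) - np.kron(T, T)
    P0 = np.linalg.solve(A, RRt.reshape(m2)).reshape(m, m)
    return T, RRt, P0, R


def _concentrated_negloglik(v: np.ndarray, F: np.ndarray):
    n = len(v)
    if np.any(F <= 0) or not np.all(np.isfinite(F)):
        return np.inf, np.nan
    sigma2 = float(np.mean(v**2 / F))
    if sigma2 <= 0 or not np.isfinite(sigma2):
        return np.inf, np.nan
    ll = -0.5 * n * (np.log(2 * np.pi) + 1.0 + np.log(sigma2)) - 0.5 * float(
        np.sum(np.log(F))
    )
    return -ll, sigma2


def _loglik_natural(z: np.ndarray, phi: np.ndarray, theta: np.ndarray, mu: float):
    T, RRt, P0, _ = _state_matrices(phi, theta)
    v, F = kalman_filter_arma(z - mu, T, RRt, P0)
    nll, sigma2 = _concentrated_negloglik(v, F)
    return -nll, sigma2, v, F


def fit_arima(
    series: DailySeries | np.ndarray,
    spec: ArimaSpec,
    start_params: np.ndarray | None = None,
    compute_se: bool = True,
) -> ArimaFit:
    """Fit by exact Gaussian maximum likelihood.

    ``start_params`` (unconstrained optimizer coordinates, as stored in a
    previous fit's ``se['xopt']``) warm-starts the optimizer, which is what
    makes daily re-estimation in the backtest cheap.
    """
    if isinstance(series, DailySeries):
        y = series.values()
    else:
        y = np.asarray(series, dtype=float)
    if np.allclose(y, y[0]):
        raise ValueError("constant series: ARIMA likelihood is degenerate")
    if len(y) < 10 * (spec.p + spec.q + 1):
        raise ValueError(
            f"series length {len(y)} too short for {spec} "
            f"(need >= {10 * (spec.p + spec.q + 1)})"
        )
    z = difference(y, spec.d)
    n = len(z)
    p, q = spec.p, spec.q

    def unpack(x):
        phi = _pacf_to_coef(x[:p]) if p else np.zeros(0)
        theta = _pacf_to_coef(x[p : p + q]) if q else np.zeros(0)
        mu = x[p + q] if spec.include_constant else 0.0
        return phi, theta, mu

    def nll(x):
        phi, theta, mu = unpack(x)
        try:
            ll, _, _, _ = _loglik_natural(z, phi, theta, mu)
        except np.linalg.LinAlgError:
            return np.inf
        return -ll if np.isfinite(ll) else np.inf

    k_free = p + q + int(spec.include_constant)
    if p + q == 0:
        # degenerate case: ML constant is the sample mean, in closed form
        xopt = np.array([z.mean()])
        converged = True
    else:
        starts = []
        x0 = np.zeros(k_free)
        if spec.include_constant:
            x0[-1] = z.mean()
        starts.append(x0)
        if start_params is not None and len(start_params) == k_free:
            starts.insert(0, np.asarray(start_params, dtype=float))
        else:
            rng = np.random.default_rng(0)
            for _ in range(2):
                xr = x0 + rng.normal(0, 0.4, size=k_free)
                starts.append(xr)
        best = None
        for x0_ in starts:
            res = optimize.minimize(nll, x0_, method="L-BFGS-B")
            if best is None or res.fun < best.fun:
                best = res
            if start_params is not None and res.success:
                break  # warm start converged; skip restarts
        xopt = best.x
        converged = bool(best.success and np.isfinite(best.fun))
    phi, theta, mu = unpack(xopt)
    ll, sigma2, v, F = _loglik_natural(z, phi, theta, mu)
    if not np.isfinite(ll):
        raise ConvergenceError(f"{spec}: likelihood not finite at optimum")

    k = spec.n_params
    aic = -2.0 * ll + 2.0 * k
    bic = -2.0 * ll + k * np.log(n)
    T, RRt, P0, _ = _state_matrices(phi, theta)
    a_fin, P_fin = kalman_state_arma(z - mu, T, RRt, P0)

    se: dict = {"xopt": xopt}
    if compute_se and k_free > 0:
        se.update(_natural_se(z, phi, theta, mu, spec))
    fit = ArimaFit(
        spec=spec,
        phi=phi,
        theta=theta,
        mu=float(mu),
        sigma2=sigma2,
        loglik=float(ll),
        aic=float(aic),
        bic=float(bic),
        residuals=v,
        se=se,
        converged=converged,
        n=n,
        last_y=float(y[-1]),
        final_state=a_fin,
        final_cov=P_fin,
    )
    if not converged:
        warnings.warn(f"{spec}: optimizer did not report convergence", RuntimeWarning)
    return fit


def _natural_se(z, phi, theta, mu, spec):
    """Standard errors from the numerical Hessian in natural coordinates."""
    p, q = spec.p, spec.q
    x0 = np.concatenate([phi, theta, [mu] if spec.include_constant else []])

    def nll_nat(x):
        ph = x[:p]
        th = x[p : p + q]
        m = x[p + q] if spec.include_constant else 0.0
        try:
            ll, _, _, _ = _loglik_natural(z, ph, th, m)
        except np.linalg.LinAlgError:
            return np.inf
        return -ll if np.isfinite(ll) else np.inf

    k = len(x0)
    h = 1e-4 * np.maximum(1.0, np.abs(x0))
    H = np.zeros((k, k))
    f0 = nll_nat(x0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (nll_nat(x0 + ei) - 2 * f0 + nll_nat(x0 - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    nll_nat(x0 + ei + ej)
                    - nll_nat(x0 + ei - ej)
                    - nll_nat(x0 - ei + ej)
                    + nll_nat(x0 - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        ses = np.full(k, np.nan)
    out = {}
    out["phi"] = ses[:p]
    out["theta"] = ses[p : p + q]
    if spec.include_constant:
        out["mu"] = float(ses[p + q])
    return out


def forecast_arima(fit: ArimaFit, h: int, dates=None) -> list[Forecast]:
    """h-step-ahead forecasts with Gaussian 95% intervals.

    Point forecasts are the conditional expectations from the filtered
    state; for d=1 the differenced-scale forecasts are cumulated onto the
    last observation, and the interval variance sums the full covariance
    of the multi-step difference forecasts.
    """
    if h < 1:
        raise ValueError("forecast horizon must be >= 1")
    T, RRt, P0, R = _state_matrices(fit.phi, fit.theta)
    m = T.shape[0]
    a, P = fit.final_state, fit.final_cov
    # W[j] = e1' T^j ; u[j] = e1' T^j R
    W = np.empty((h, m))
    u = np.empty(h)
    row = np.zeros(m)
    row[0] = 1.0
    for j in range(h):
        W[j] = row
        u[j] = float(row @ R)
        row = row @ T
    zhat = fit.mu + W @ a
    cov = W @ P @ W.T
    for i in range(1, h + 1):
        for j in range(1, h + 1):
            for k in range(1, min(i, j)):
                cov[i - 1, j - 1] += u[i - 1 - k] * u[j - 1 - k]
    cov *= fit.sigma2

    if fit.spec.d == 0:
        points = zhat
        var = np.diag(cov).copy()
    else:
        points = fit.last_y + np.cumsum(zhat)
        var = np.array([cov[: j + 1, : j + 1].sum() for j in range(h)])
    sd = np.sqrt(np.maximum(var, 0.0))
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


def arima_one_step_path(fit: ArimaFit, y: np.ndarray):
    """In-sample one-step-ahead forecasts along a series, using fit's params.

    Returns (points, variances) aligned with y[d:]: the forecast of each
    observation given only its predecessors.  Used for rolling risk
    calibration and coverage checks without refitting.
    """
    z = difference(np.asarray(y, dtype=float), fit.spec.d)
    T, RRt, P0, _ = _state_matrices(fit.phi, fit.theta)
    v, F = kalman_filter_arma(z - fit.mu, T, RRt, P0)
    zpred = z - v  # one-step predictions of z (mean added back implicitly)
    if fit.spec.d == 0:
        points = zpred
    else:
        points = y[:-1] + zpred
    var = F * fit.sigma2
    return points, var


def select_arima(
    series: DailySeries | np.ndarray,
    candidates: list[ArimaSpec],
    lb_lags: int = 10,
    lb_level: float = 0.05,
) -> ArimaSpec:
    """Choose a spec by BIC among candidates with white-noise residuals.

    Candidates whose Ljung-Box residual p-value (lags=10, fitdf = number
    of ARMA coefficients) exceeds ``lb_level`` compete on BIC; if none
    pass, the overall minimal-BIC spec is returned with a warning.  Ties
    break toward fewer parameters, then lexicographic (p, q).
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    rows = []
    for spec in candidates:
        try:
            fit = fit_arima(series, spec, compute_se=False)
        except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"{spec} failed to fit: {exc}", RuntimeWarning)
            continue
        fitdf = spec.p + spec.q
        lags = max(lb_lags, fitdf + 1)
        lb = ljung_box(fit.residuals, lags=lags, fitdf=fitdf)
        rows.append((spec, fit.bic, lb.p_value))
    if not rows:
        raise ConvergenceError("no ARIMA candidate could be fitted")
    passing = [r for r in rows if r[2] > lb_level]
    pool = passing if passing else rows
    if not passing:
        warnings.warn(
            "no candidate passed the Ljung-Box residual check; "
            "returning minimal-BIC spec anyway",
            RuntimeWarning,
        )
    pool = sorted(pool, key=lambda r: (r[1], r[0].n_params, r[0].p, r[0].q))
    return pool[0][0]
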