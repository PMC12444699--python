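"""Stationarity and residual diagnostics for ARIMA specification.

KPSS level/trend-stationarity test, differencing, sample ACF/PACF, and the
Ljung-Box portmanteau test.  These are the tools used to decide the
differencing order and to verify that fitted-model residuals are white
noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "CorrelogramResult",
    "difference",
    "kpss_test",
    "acf",
    "pacf",
    "ljung_box",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``p_value`` is the numeric value used in comparisons; ``p_value_bound``
    carries an interval-bound rendering (e.g. ">0.1") when the statistic
    falls outside the tabulated critical range, as is conventional for
    table-interpolated tests such as KPSS.
    """

    statistic: float
    p_value: float
    lags_used: int
    null_description: str
    p_value_bound: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


@dataclass(frozen=True)
class CorrelogramResult:
    """Sample (partial) autocorrelations at lags 1..L with a white-noise band."""

    lags: np.ndarray
    values: np.ndarray
    conf_band: float


def difference(series, d: int = 1) -> np.ndarray:
    """Apply d-fold first differencing; d=0 returns the input unchanged."""
    x = np.asarray(series, dtype=float)
    if d < 0:
        raise ValueError("differencing order must be >= 0")
    if len(x) <= d:
        raise ValueError(f"series of length {len(x)} too short for d={d}")
    for _ in range(d):
        x = np.diff(x)
    return x


# Tabulated KPSS critical values (statistic at upper-tail probability).
_KPSS_TABLE = {
    "level": ([0.347, 0.463, 0.574, 0.739], [0.10, 0.05, 0.025, 0.01]),
    "trend": ([0.119, 0.146, 0.176, 0.216], [0.10, 0.05, 0.025, 0.01]),
}


def kpss_test(series, lags: int | str = "auto", regression: str = "level") -> TestResult:
    """KPSS test with null hypothesis of (level- or trend-) stationarity.

    The statistic is (1/n^2) * sum_t S_t^2 / s2_lrv, where S_t are partial
    sums of the residuals from regressing on a constant (level) or a
    constant plus linear trend (trend), and s2_lrv is the Bartlett-kernel
    long-run variance with truncation ``lags`` (default
    floor(4*(n/100)^0.25)).  The p-value is linearly interpolated from the
    published critical-value table and reported as a bound (">0.1" or
    "<0.01") outside the tabulated range.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("series too short for KPSS (need n >= 10)")
    if regression not in _KPSS_TABLE:
        raise ValueError("regression must be 'level' or 'trend'")
    if regression == "level":
        resid = x - x.mean()
    else:
        t = np.arange(n, dtype=float)
        X = np.column_stack([np.ones(n), t])
        beta, *_ = np.linalg.lstsq(X, x, rcond=None)
        resid = x - X @ beta
    if np.allclose(resid, 0.0):
        raise ValueError("series has zero residual variance")
    if lags == "auto":
        lags = int(np.floor(4.0 * (n / 100.0) ** 0.25))
    lags = int(lags)
    s = np.cumsum(resid)
    eta = float(np.sum(s**2)) / n**2
    lrv = float(np.dot(resid, resid)) / n
    for k in range(1, lags + 1):
        w = 1.0 - k / (lags + 1.0)
        lrv += 2.0 * w * float(np.dot(resid[k:], resid[:-k])) / n
    stat = eta / lrv

    crit, pvals = _KPSS_TABLE[regression]
    bound = None
    if stat < crit[0]:
        p, bound = 0.10, ">0.1"
    elif stat > crit[-1]:
        p, bound = 0.01, "<0.01"
    else:
        p = float(np.interp(stat, crit, pvals))
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        lags_used=lags,
        null_description=f"{regression}-stationarity",
        p_value_bound=bound,
    )


def _autocovariances(x: np.ndarray, max_lag: int) -> np.ndarray:
    n = len(x)
    xc = x - x.mean()
    denom = n  # biased estimator, standard for sample ACF
    return np.array(
        [np.dot(xc[k:], xc[: n - k]) / denom for k in range(max_lag + 1)]
    )


def acf(series, max_lag: int = 20) -> CorrelogramResult:
    """Sample autocorrelation function at lags 1..max_lag.

    Lag 0 (identically 1) is excluded from the output.  The white-noise
    band is z_{0.975}/sqrt(n).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if max_lag >= n:
        raise ValueError("max_lag must be < series length")
    gamma = _autocovariances(x, max_lag)
    if gamma[0] <= 0:
        raise ValueError("constant series: autocorrelation undefined")
    r = gamma[1:] / gamma[0]
    band = sps.norm.ppf(0.975) / np.sqrt(n)
    return CorrelogramResult(np.arange(1, max_lag + 1), r, float(band))


def pacf(series, max_lag: int = 20) -> CorrelogramResult:
    """Sample partial autocorrelations via Durbin-Levinson recursions."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    if max_lag >= n:
        raise ValueError("max_lag must be < series length")
    gamma = _autocovariances(x, max_lag)
    if gamma[0] <= 0:
        raise ValueError("constant series: autocorrelation undefined")
    rho = gamma[1:] / gamma[0]
    pac = np.zeros(max_lag)
    phi_prev = np.zeros(max_lag)
    for k in range(1, max_lag + 1):
        if k == 1:
            a = rho[0]
            phi_prev[0] = a
        else:
            num = rho[k - 1] - np.dot(phi_prev[: k - 1], rho[k - 2 :: -1])
            den = 1.0 - np.dot(phi_prev[: k - 1], rho[: k - 1])
            a = num / den
            phi_new = phi_prev.copy()
            phi_new[: k - 1] = phi_prev[: k - 1] - a * phi_prev[k - 2 :: -1]
            phi_new[k - 1] = a
            phi_prev = phi_new
        pac[k - 1] = a
    band = sps.norm.ppf(0.975) / np.sqrt(n)
    return CorrelogramResult(np.arange(1, max_lag + 1), pac, float(band))


def ljung_box(residuals, lags: int = 10, fitdf: int = 0) -> TestResult:
    """Ljung-Box portmanteau test that residual autocorrelations are zero.

    Q = n(n+2) * sum_{k=1..h} r_k^2/(n-k), referred to chi-square with
    (lags - fitdf) degrees of freedom, where fitdf is the number of
    estimated ARMA coefficients.
    """
    x = np.asarray(residuals, dtype=float)
    n = len(x)
    if lags >= n:
        raise ValueError("lags must be < number of residuals")
    if fitdf < 0 or lags <= fitdf:
        raise ValueError("need lags > fitdf >= 0 (positive degrees of freedom)")
    r = acf(x, max_lag=lags).values
    k = np.arange(1, lags + 1)
    q = n * (n + 2.0) * float(np.sum(r**2 / (n - k)))
    df = lags - fitdf
    p = float(sps.chi2.sf(q, df))
    return TestResult(
        statistic=float(q),
        p_value=p,
        lags_used=lags,
        null_description="residuals are white noise",
    )
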