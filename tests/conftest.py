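import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from asthmacast import generate_series, reference_config
from asthmacast.series import DailySeries
import pandas as pd


@pytest.fixture(scope="session")
def reference_series():
    """One full 2016-2023 realisation of the reference generator."""
    return generate_series(reference_config(seed=101), "2016-01-01", "2023-12-31")


@pytest.fixture(scope="session")
def reference_series_seeds():
    """Five independent 2016-2023 realisations (marginal-calibration checks)."""
    return [
        generate_series(reference_config(seed=s), "2016-01-01", "2023-12-31")
        for s in (101, 102, 103, 104, 105)
    ]


def simulate_arima_012(n, theta=(0.4, 0.2), const=0.01, sigma=1.0, seed=0, y0=5.0):
    """Independent oracle simulation of an ARIMA(0,1,2) with drift."""
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sigma, n + 2)
    z = const + eps[2:] + theta[0] * eps[1:-1] + theta[1] * eps[:-2]
    return np.cumsum(z) + y0


def simulate_ets_ana(n, alpha=0.3, gamma=0.1, sigma=1.0, level=10.0, seed=0, m=7):
    """Hand-rolled ETS(A,N,A) simulation, period m."""
    rng = np.random.default_rng(seed)
    s = np.array([2.0, 1.0, 0.0, -1.0, -2.0, 1.0, -1.0])[:m]
    s = s - s.mean()
    l = level
    y = np.empty(n)
    for t in range(n):
        e = rng.normal(0.0, sigma)
        y[t] = l + s[0] + e
        l = l + alpha * e
        snew = s[0] + gamma * e
        s = np.roll(s, -1)
        s[-1] = snew
    return y


def daily(counts, start="2020-01-01"):
    counts = np.asarray(counts)
    return DailySeries(pd.date_range(start, periods=len(counts), freq="D"), counts)
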