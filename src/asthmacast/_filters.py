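"""Compiled inner loops for likelihood evaluation.

These kernels are called thousands of times inside optimizer iterations
and daily-refit backtests, so they are JIT-compiled with numba.  They
contain no model logic beyond the standard recursions: the Kalman filter
for a stationary ARMA state-space model, and the additive
exponential-smoothing state updates.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["kalman_filter_arma", "ets_filter"]


@njit(cache=True)
def kalman_filter_arma(x, T, RRt, P0):
    """Innovations of a zero-mean stationary ARMA model, unit sigma2.

    State form: alpha_{t+1} = T alpha_t + R eta_t, x_t = alpha_t[0].
    Returns (v, F): one-step prediction errors and their variances
    (in units of sigma2).
    """
    n = x.shape[0]
    m = T.shape[0]
    a = np.zeros(m)
    P = P0.copy()
    v = np.empty(n)
    F = np.empty(n)
    for t in range(n):
        vt = x[t] - a[0]
        Ft = P[0, 0]
        v[t] = vt
        F[t] = Ft
        # K = T @ P[:, 0] / Ft
        K = np.zeros(m)
        for i in range(m):
            s = 0.0
            for j in range(m):
                s += T[i, j] * P[j, 0]
            K[i] = s / Ft
        # a = T @ a + K * vt
        anew = np.zeros(m)
        for i in range(m):
            s = 0.0
            for j in range(m):
                s += T[i, j] * a[j]
            anew[i] = s + K[i] * vt
        a = anew
        # P = T P T' + RRt - K K' Ft
        TP = np.zeros((m, m))
        for i in range(m):
            for j in range(m):
                s = 0.0
                for k in range(m):
                    s += T[i, k] * P[k, j]
                TP[i, j] = s
        Pnew = np.zeros((m, m))
        for i in range(m):
            for j in range(m):
                s = 0.0
                for k in range(m):
                    s += TP[i, k] * T[j, k]
                Pnew[i, j] = s + RRt[i, j] - K[i] * K[j] * Ft
        P = Pnew
    return v, F


@njit(cache=True)
def kalman_state_arma(x, T, RRt, P0):
    """Final predicted state and covariance after filtering x (unit sigma2)."""
    n = x.shape[0]
    m = T.shape[0]
    a = np.zeros(m)
    P = P0.copy()
    for t in range(n):
        vt = x[t] - a[0]
        Ft = P[0, 0]
        K = np.zeros(m)
        for i in range(m):
            s = 0.0
            for j in range(m):
                s += T[i, j] * P[j, 0]
            K[i] = s / Ft
        anew = np.zeros(m)
        for i in range(m):
            s = 0.0
            for j in range(m):
                s += T[i, j] * a[j]
            anew[i] = s + K[i] * vt
        a = anew
        TP = np.zeros((m, m))
        for i in range(m):
            for j in range(m):
                s = 0.0
                for k in range(m):
                    s += T[i, k] * P[k, j]
                TP[i, j] = s
        Pnew = np.zeros((m, m))
        for i in range(m):
            for j in range(m):
                s = 0.0
                for k in range(m):
                    s += TP[i, k] * T[j, k]
                Pnew[i, j] = s + RRt[i, j] - K[i] * K[j] * Ft
        P = Pnew
    return a, P


@njit(cache=True)
def ets_filter(y, alpha, beta, gamma, phi, l0, b0, s0, trend, seasonal, m):
    """Additive-class exponential smoothing recursion.

    trend: 0 = none, 1 = additive, 2 = additive damped (phi).
    seasonal: 0 = none, 1 = additive with period m.
    Returns (fitted, e, l, b, s) with one-step fitted values, residuals,
    and final states; s is the seasonal buffer ordered so s[0] applies to
    the next (first out-of-sample) time point.
    """
    n = y.shape[0]
    fitted = np.empty(n)
    e = np.empty(n)
    l = l0
    b = b0
    s = s0.copy()
    for t in range(n):
        if trend == 0:
            mu = l
        elif trend == 1:
            mu = l + b
        else:
            mu = l + phi * b
        if seasonal == 1:
            mu += s[0]
        fitted[t] = mu
        et = y[t] - mu
        e[t] = et
        if trend == 0:
            l = l + alpha * et
        elif trend == 1:
            lnew = l + b + alpha * et
            b = b + beta * et
            l = lnew
        else:
            lnew = l + phi * b + alpha * et
            b = phi * b + beta * et
            l = lnew
        if seasonal == 1:
            snew = s[0] + gamma * et
            for j in range(m - 1):
                s[j] = s[j + 1]
            s[m - 1] = snew
    return fitted, e, l, b, s
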