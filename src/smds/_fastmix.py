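"""Numba-accelerated kernels for the brightness-mixture likelihood.

The bootstrap confidence intervals refit the full mixture (shape + weights)
on every resample, so the likelihood kernel has to be fast; these jitted
loops evaluate the constrained-mixture negative log-likelihood (optionally
with its analytic gradient in (xi, log omega, alpha), including the chain
rule through the tied oligomer centers and widths) and run weight-EM sweeps
without allocating (k, n) temporaries per iteration.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_SQRT1_2 = 1.0 / math.sqrt(2.0)
_SQRT_2_PI = math.sqrt(2.0 / math.pi)


@njit(cache=True)
def _log_ndtr(z: float) -> float:
    if z > -20.0:
        return math.log(0.5 * math.erfc(-z * _SQRT1_2))
    # asymptotic tail: log Phi(z) ~ -z^2/2 - log(-z) - log(sqrt(2 pi))
    return -0.5 * z * z - math.log(-z) - _LOG_SQRT_2PI


@njit(cache=True)
def _mills(z: float) -> float:
    """phi(z) / Phi(z), stable for very negative z."""
    if z > -20.0:
        phi = math.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)
        return phi / (0.5 * math.erfc(-z * _SQRT1_2))
    return -z + 1.0 / (-z)  # asymptotic inverse Mills ratio


@njit(cache=True)
def _moments(xi: float, omega: float, alpha: float):
    delta = alpha / math.sqrt(1.0 + alpha * alpha)
    mean = xi + omega * delta * _SQRT_2_PI
    sd = omega * math.sqrt(1.0 - 2.0 * delta * delta / math.pi)
    return mean, sd


@njit(cache=True, fastmath=True)
def mixture_nll(x: np.ndarray, xi: float, omega: float, alpha: float,
                logw: np.ndarray) -> float:
    """Negative log-likelihood of the tied skew-normal + Gaussian comb."""
    k = logw.size
    if omega <= 0.0:
        return 1e300
    mu, sd = _moments(xi, omega, alpha)
    if mu <= 0.0 or sd <= 0.0:
        return 1e300
    log_om = math.log(omega)
    log_sd = math.log(sd)
    nll = 0.0
    for i in range(x.size):
        t = (x[i] - xi) / omega
        m = math.log(2.0) - log_om - 0.5 * t * t - _LOG_SQRT_2PI \
            + _log_ndtr(alpha * t) + logw[0]
        acc = 1.0
        for s in range(1, k):
            u = (x[i] - (s + 1) * mu) / sd
            lp = -0.5 * u * u - log_sd - _LOG_SQRT_2PI + logw[s]
            if lp > m:
                acc = acc * math.exp(m - lp) + 1.0
                m = lp
            else:
                acc += math.exp(lp - m)
        nll -= m + math.log(acc)
    if not math.isfinite(nll):
        return 1e300
    return nll


@njit(cache=True, fastmath=True)
def mixture_nll_grad(x: np.ndarray, xi: float, omega: float, alpha: float,
                     logw: np.ndarray):
    """(nll, grad) with grad over (xi, log omega, alpha)."""
    k = logw.size
    grad = np.zeros(3)
    if omega <= 0.0:
        return 1e300, grad
    one_a2 = 1.0 + alpha * alpha
    delta = alpha / math.sqrt(one_a2)
    ddelta = one_a2 ** (-1.5)
    root = math.sqrt(1.0 - 2.0 * delta * delta / math.pi)
    mu = xi + omega * delta * _SQRT_2_PI
    sd = omega * root
    if mu <= 0.0 or sd <= 0.0:
        return 1e300, grad
    # derivatives of mu and sd wrt (xi, omega, alpha)
    dmu = (1.0, delta * _SQRT_2_PI, omega * _SQRT_2_PI * ddelta)
    dsd = (0.0, root, -omega * 2.0 * delta * ddelta / (math.pi * root))
    log_om = math.log(omega)
    log_sd = math.log(sd)
    nll = 0.0
    g0 = 0.0
    g1 = 0.0
    g2 = 0.0
    lp = np.empty(k)
    df = np.empty((k, 3))
    for i in range(x.size):
        t = (x[i] - xi) / omega
        z = alpha * t
        lp[0] = math.log(2.0) - log_om - 0.5 * t * t - _LOG_SQRT_2PI \
            + _log_ndtr(z) + logw[0]
        r = _mills(z)
        # d logpdf / d xi, omega, alpha for the skew-normal
        df[0, 0] = t / omega - (alpha / omega) * r
        df[0, 1] = -1.0 / omega + t * t / omega - (alpha * t / omega) * r
        df[0, 2] = t * r
        for s in range(1, k):
            c = (s + 1) * mu
            u = (x[i] - c) / sd
            lp[s] = -0.5 * u * u - log_sd - _LOG_SQRT_2PI + logw[s]
            dfdc = u / sd
            dfdsd = (u * u - 1.0) / sd
            for j in range(3):
                df[s, j] = dfdc * (s + 1) * dmu[j] + dfdsd * dsd[j]
        m = lp[0]
        for s in range(1, k):
            if lp[s] > m:
                m = lp[s]
        z_sum = 0.0
        for s in range(k):
            z_sum += math.exp(lp[s] - m)
        nll -= m + math.log(z_sum)
        for s in range(k):
            resp = math.exp(lp[s] - m) / z_sum
            g0 -= resp * df[s, 0]
            g1 -= resp * df[s, 1]
            g2 -= resp * df[s, 2]
    if not math.isfinite(nll):
        return 1e300, grad
    grad[0] = g0
    grad[1] = g1 * omega  # chain rule to log omega
    grad[2] = g2
    return nll, grad


@njit(cache=True, fastmath=True)
def em_weights(x: np.ndarray, xi: float, omega: float, alpha: float,
               w0: np.ndarray, max_iter: int, tol: float) -> np.ndarray:
    """EM updates of the mixture weights at fixed component shapes.

    Component densities are computed once (normalized per point, linear
    space), so each EM sweep is pure arithmetic.
    """
    k = w0.size
    n = x.size
    mu, sd = _moments(xi, omega, alpha)
    log_om = math.log(omega)
    log_sd = math.log(sd)
    comp = np.empty((n, k))
    for i in range(n):
        t = (x[i] - xi) / omega
        comp[i, 0] = math.log(2.0) - log_om - 0.5 * t * t - _LOG_SQRT_2PI \
            + _log_ndtr(alpha * t)
        m = comp[i, 0]
        for s in range(1, k):
            u = (x[i] - (s + 1) * mu) / sd
            comp[i, s] = -0.5 * u * u - log_sd - _LOG_SQRT_2PI
            if comp[i, s] > m:
                m = comp[i, s]
        for s in range(k):
            comp[i, s] = math.exp(comp[i, s] - m)
    w = w0.copy()
    w_new = np.empty(k)
    for _ in range(max_iter):
        for s in range(k):
            w_new[s] = 0.0
        for i in range(n):
            z = 0.0
            for s in range(k):
                z += w[s] * comp[i, s]
            if z <= 0.0:
                continue
            for s in range(k):
                w_new[s] += w[s] * comp[i, s] / z
        delta = 0.0
        for s in range(k):
            w_new[s] /= n
            d = abs(w_new[s] - w[s])
            if d > delta:
                delta = d
            w[s] = w_new[s]
        if delta < tol:
            break
    return w
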