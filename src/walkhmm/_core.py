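"""Numerical kernels for the forward recursion.

The forward recursion is inherently sequential; a numba-compiled kernel
makes the multi-start maximization practical.  A pure-numpy implementation
with identical semantics is used when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(fastmath=False)
def _forward_scaled_numba(p, tpm, delta):  # pragma: no cover - numba path
    T, n = p.shape
    alpha = np.empty(n)
    for i in range(n):
        alpha[i] = delta[i] * p[0, i]
    c = 0.0
    for i in range(n):
        c += alpha[i]
    if c <= 0.0 or not np.isfinite(c):
        return -np.inf
    total = np.log(c)
    for i in range(n):
        alpha[i] /= c
    nxt = np.empty(n)
    for t in range(1, T):
        for j in range(n):
            acc = 0.0
            for i in range(n):
                acc += alpha[i] * tpm[i, j]
            nxt[j] = acc * p[t, j]
        c = 0.0
        for j in range(n):
            c += nxt[j]
        if c <= 0.0 or not np.isfinite(c):
            return -np.inf
        total += np.log(c)
        for j in range(n):
            alpha[j] = nxt[j] / c
    return total


def _forward_scaled_numpy(p, tpm, delta):
    T = p.shape[0]
    alpha = delta * p[0]
    c = alpha.sum()
    if c <= 0.0 or not np.isfinite(c):
        return -np.inf
    total = np.log(c)
    alpha = alpha / c
    for t in range(1, T):
        alpha = (alpha @ tpm) * p[t]
        c = alpha.sum()
        if c <= 0.0 or not np.isfinite(c):
            return -np.inf
        total += np.log(c)
        alpha = alpha / c
    return float(total)


@njit(fastmath=False)
def _forward_backward_numba(logp, tpm, delta):  # pragma: no cover - numba path
    T, n = logp.shape
    p = np.empty((T, n))
    row_max_total = 0.0
    for t in range(T):
        m = logp[t, 0]
        for i in range(1, n):
            if logp[t, i] > m:
                m = logp[t, i]
        if not np.isfinite(m):
            return np.nan, p, p[:1]
        row_max_total += m
        for i in range(n):
            p[t, i] = np.exp(logp[t, i] - m)
    alpha = np.empty((T, n))
    c = np.empty(T)
    acc = 0.0
    for i in range(n):
        alpha[0, i] = delta[i] * p[0, i]
        acc += alpha[0, i]
    if acc <= 0.0 or not np.isfinite(acc):
        return np.nan, alpha, alpha[:1]
    c[0] = acc
    for i in range(n):
        alpha[0, i] /= acc
    for t in range(1, T):
        acc = 0.0
        for j in range(n):
            s = 0.0
            for i in range(n):
                s += alpha[t - 1, i] * tpm[i, j]
            alpha[t, j] = s * p[t, j]
            acc += alpha[t, j]
        if acc <= 0.0 or not np.isfinite(acc):
            return np.nan, alpha, alpha[:1]
        c[t] = acc
        for j in range(n):
            alpha[t, j] /= acc
    ll = row_max_total
    for t in range(T):
        ll += np.log(c[t])
    # backward pass: state posteriors gamma and summed transition posteriors
    gamma = np.empty((T, n))
    xi = np.zeros((n, n))
    beta = np.ones(n)
    for i in range(n):
        gamma[T - 1, i] = alpha[T - 1, i]
    newbeta = np.empty(n)
    for t in range(T - 2, -1, -1):
        for i in range(n):
            s = 0.0
            for j in range(n):
                w = tpm[i, j] * p[t + 1, j] * beta[j]
                xi[i, j] += alpha[t, i] * w / c[t + 1]
                s += w
            newbeta[i] = s / c[t + 1]
        for i in range(n):
            beta[i] = newbeta[i]
            gamma[t, i] = alpha[t, i] * beta[i]
    return ll, gamma, xi


def _forward_backward_numpy(logp, tpm, delta):
    T, n = logp.shape
    row_max = logp.max(axis=1)
    if not np.all(np.isfinite(row_max)):
        return np.nan, None, None
    p = np.exp(logp - row_max[:, None])
    alpha = np.empty((T, n))
    c = np.empty(T)
    a = delta * p[0]
    c[0] = a.sum()
    if c[0] <= 0.0 or not np.isfinite(c[0]):
        return np.nan, None, None
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ tpm) * p[t]
        c[t] = a.sum()
        if c[t] <= 0.0 or not np.isfinite(c[t]):
            return np.nan, None, None
        alpha[t] = a / c[t]
    ll = float(row_max.sum() + np.log(c).sum())
    gamma = np.empty((T, n))
    xi = np.zeros((n, n))
    beta = np.ones(n)
    gamma[T - 1] = alpha[T - 1]
    for t in range(T - 2, -1, -1):
        w = tpm * (p[t + 1] * beta)[None, :]
        xi += alpha[t][:, None] * w / c[t + 1]
        beta = w.sum(axis=1) / c[t + 1]
        gamma[t] = alpha[t] * beta
    return ll, gamma, xi


def forward_backward(logp, tpm, delta):
    """Log likelihood, state posteriors and summed transition posteriors.

    Returns ``(loglik, gamma, xi)`` where ``gamma[t, i] = P(state_t = i |
    obs)`` and ``xi[i, j] = sum_t P(state_t = i, state_{t+1} = j | obs)``.
    ``loglik`` is NaN (with undefined posteriors) when the likelihood is
    not finite.
    """
    if _HAVE_NUMBA:
        ll, gamma, xi = _forward_backward_numba(
            np.ascontiguousarray(logp), np.ascontiguousarray(tpm),
            np.ascontiguousarray(delta))
        return float(ll), gamma, xi
    return _forward_backward_numpy(logp, tpm, delta)


def forward_scaled(p: np.ndarray, tpm: np.ndarray, delta: np.ndarray) -> float:
    """Sum of per-step log scaling constants of the forward recursion.

    ``p`` holds per-step emission probabilities already scaled by their
    row maximum; the caller adds back the row maxima.
    """
    if _HAVE_NUMBA:
        return float(_forward_scaled_numba(p, tpm, delta))
    return _forward_scaled_numpy(p, tpm, delta)
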