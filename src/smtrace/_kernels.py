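"""Jit-compiled numerical kernels for the forward-backward recursions.

Traces routinely reach 3e4 time steps and population studies fit hundreds of
them, so the per-time-step recursions are compiled with numba.  Scaling uses
per-step normalization constants with a per-step shift of the log emission
row by its maximum, so likelihoods stay finite for arbitrarily long traces.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["forward_loglik", "forward_backward", "reversible_mstep"]


@njit(cache=True)
def forward_loglik(A, pi0, logB):
    """Scaled forward recursion; returns log p(data | params).

    Parameters: A (K,K) row-stochastic, pi0 (K,), logB (T,K) per-step log
    emission probabilities (channels already summed).
    """
    T, K = logB.shape
    alpha = np.empty(K)
    nxt = np.empty(K)
    m = logB[0, 0]
    for k in range(1, K):
        if logB[0, k] > m:
            m = logB[0, k]
    s = 0.0
    for k in range(K):
        alpha[k] = pi0[k] * math.exp(logB[0, k] - m)
        s += alpha[k]
    if s <= 0.0:
        return -np.inf
    ll = math.log(s) + m
    for k in range(K):
        alpha[k] /= s
    for t in range(1, T):
        m = logB[t, 0]
        for k in range(1, K):
            if logB[t, k] > m:
                m = logB[t, k]
        s = 0.0
        for j in range(K):
            a = 0.0
            for i in range(K):
                a += alpha[i] * A[i, j]
            a *= math.exp(logB[t, j] - m)
            nxt[j] = a
            s += a
        if s <= 0.0:
            return -np.inf
        ll += math.log(s) + m
        for j in range(K):
            alpha[j] = nxt[j] / s
    return ll


@njit(cache=True)
def forward_backward(A, pi0, logB):
    """Scaled forward-backward smoothing.

    Returns ``(loglik, gamma, xi_sum)`` where ``gamma`` is the (T,K) matrix of
    posterior state probabilities and ``xi_sum`` the (K,K) matrix of expected
    transition counts summed over time.
    """
    T, K = logB.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    mshift = np.empty(T)

    # forward
    m = logB[0, 0]
    for k in range(1, K):
        if logB[0, k] > m:
            m = logB[0, k]
    mshift[0] = m
    s = 0.0
    for k in range(K):
        alpha[0, k] = pi0[k] * math.exp(logB[0, k] - m)
        s += alpha[0, k]
    c[0] = s
    ll = math.log(s) + m
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        m = logB[t, 0]
        for k in range(1, K):
            if logB[t, k] > m:
                m = logB[t, k]
        mshift[t] = m
        s = 0.0
        for j in range(K):
            a = 0.0
            for i in range(K):
                a += alpha[t - 1, i] * A[i, j]
            a *= math.exp(logB[t, j] - m)
            alpha[t, j] = a
            s += a
        c[t] = s
        ll += math.log(s) + m
        for j in range(K):
            alpha[t, j] /= s

    # backward, gamma, xi
    gamma = np.empty((T, K))
    xi = np.zeros((K, K))
    beta = np.ones(K)
    bh = np.empty(K)
    prev = np.empty(K)
    for k in range(K):
        gamma[T - 1, k] = alpha[T - 1, k]
    for t in range(T - 2, -1, -1):
        for j in range(K):
            bh[j] = math.exp(logB[t + 1, j] - mshift[t + 1]) * beta[j]
        for i in range(K):
            b = 0.0
            for j in range(K):
                term = A[i, j] * bh[j]
                xi[i, j] += alpha[t, i] * term / c[t + 1]
                b += term
            prev[i] = b / c[t + 1]
        g = 0.0
        for i in range(K):
            gamma[t, i] = alpha[t, i] * prev[i]
            g += gamma[t, i]
        # numerical guard: renormalize
        for i in range(K):
            gamma[t, i] /= g
        for i in range(K):
            beta[i] = prev[i]
    # xi rows were accumulated with gamma normalization implicit in alpha/c
    return ll, gamma, xi


@njit(cache=True)
def reversible_mstep(xi, allowed, max_iter=2000, tol=1e-13):
    """M-step for a detailed-balance-constrained transition matrix.

    Parameterizes A_ij = w_ij / sum_k w_ik with symmetric non-negative weights
    w (including a free diagonal), which satisfies detailed balance with
    pi_i proportional to the row sums of w.  Maximizes the expected
    complete-data log-likelihood sum_ij xi_ij log A_ij by the standard
    self-consistent fixed-point iteration.
    """
    K = xi.shape[0]
    C = np.empty(K)
    for i in range(K):
        tot = 0.0
        for j in range(K):
            tot += xi[i, j]
        C[i] = tot
    w = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            if allowed[i, j] or allowed[j, i]:
                w[i, j] = 0.5 * (xi[i, j] + xi[j, i]) + 1e-12
        w[i, i] = xi[i, i] + 1e-12
    S = np.empty(K)
    for _ in range(max_iter):
        for i in range(K):
            tot = 0.0
            for j in range(K):
                tot += w[i, j]
            S[i] = tot
        delta = 0.0
        for i in range(K):
            for j in range(i + 1, K):
                if w[i, j] > 0.0:
                    denom = 0.0
                    if S[i] > 0.0 and C[i] > 0.0:
                        denom += C[i] / S[i]
                    if S[j] > 0.0 and C[j] > 0.0:
                        denom += C[j] / S[j]
                    if denom > 0.0:
                        new = (xi[i, j] + xi[j, i]) / denom
                        d = abs(new - w[i, j])
                        if d > delta:
                            delta = d
                        w[i, j] = new
                        w[j, i] = new
        for i in range(K):
            if C[i] > 0.0 and S[i] > 0.0:
                new = xi[i, i] * S[i] / C[i]
                d = abs(new - w[i, i])
                if d > delta:
                    delta = d
                w[i, i] = new
        if delta < tol:
            break
    A = np.empty((K, K))
    for i in range(K):
        tot = 0.0
        for j in range(K):
            tot += w[i, j]
        if tot <= 0.0:
            for j in range(K):
                A[i, j] = 1.0 if i == j else 0.0
        else:
            for j in range(K):
                A[i, j] = w[i, j] / tot
    return A
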