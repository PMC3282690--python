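"""Independent brute-force oracles used by the test suite.

These enumerate all K^T hidden paths explicitly and never share code with the
recursions they check.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

from smtrace.hmm import HmmParams, log_emission_matrix
from smtrace.traces import Trace


def brute_force_loglik(trace: Trace, params: HmmParams) -> float:
    """log p(data) as an explicit sum over all K^T hidden paths."""
    K, T = params.K, trace.T
    logB = log_emission_matrix(trace, params.emissions)
    total = -np.inf
    for path in product(range(K), repeat=T):
        lp = math.log(params.pi0[path[0]]) if params.pi0[path[0]] > 0 else -np.inf
        for t in range(1, T):
            a = params.A[path[t - 1], path[t]]
            lp += math.log(a) if a > 0 else -np.inf
        for t in range(T):
            lp += logB[t, path[t]]
        total = np.logaddexp(total, lp)
    return float(total)


def brute_force_posteriors(trace: Trace, params: HmmParams) -> np.ndarray:
    """Exact (T, K) posterior state marginals by path enumeration."""
    K, T = params.K, trace.T
    logB = log_emission_matrix(trace, params.emissions)
    logpost = np.full((T, K), -np.inf)
    for path in product(range(K), repeat=T):
        lp = math.log(params.pi0[path[0]]) if params.pi0[path[0]] > 0 else -np.inf
        for t in range(1, T):
            a = params.A[path[t - 1], path[t]]
            lp += math.log(a) if a > 0 else -np.inf
        for t in range(T):
            lp += logB[t, path[t]]
        for t in range(T):
            logpost[t, path[t]] = np.logaddexp(logpost[t, path[t]], lp)
    post = np.exp(logpost - logpost.max(axis=1, keepdims=True))
    return post / post.sum(axis=1, keepdims=True)


def random_instance(rng: np.random.Generator, K: int, T: int, family: str = "poisson"):
    """A random trace + valid random parameters for oracle comparisons."""
    A = rng.dirichlet(np.ones(K) * 2.0, size=K)
    pi0 = rng.dirichlet(np.ones(K))
    mu = np.sort(rng.uniform(2.0, 30.0, size=K))[:, None]
    if family == "poisson":
        from smtrace.hmm import EmissionParams

        em = EmissionParams(("poisson",), mu)
        x = rng.poisson(10.0, size=(T, 1)).astype(float)
    else:
        from smtrace.hmm import EmissionParams

        sigma = rng.uniform(0.5, 3.0, size=(K, 1))
        em = EmissionParams(("gaussian",), mu, sigma)
        x = rng.normal(10.0, 4.0, size=(T, 1))
    trace = Trace(f"rand-{K}-{T}", 1.0, x)
    return trace, HmmParams(A, em, pi0)
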