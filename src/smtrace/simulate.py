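"""Synthetic single-molecule trace generation.

Traces are drawn from a hidden Markov chain started at its stationary
distribution, with per-state Poisson or Gaussian emissions conditionally
independent given the hidden state.  Photobleaching is emulated by coupling
trace length to excitation intensity: T * SNR = c, so higher signal-to-noise
(higher laser power) gives shorter traces.

The two-state SNR statistic for a Poisson channel with state means mu1, mu2 is
|mu2 - mu1| / sqrt((mu1 + mu2) / 2): the level separation over the pooled shot
noise.  Means 100 and 110 give an SNR of about 1.  Independent channels add in
quadrature, so two channels at SNR 1 combine to sqrt(2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .hmm import EmissionParams, HmmParams
from .markov import stationary_distribution
from .traces import Trace, TraceSet

__all__ = [
    "SimulationConfig",
    "stationary_distribution",
    "snr_two_state",
    "combined_snr",
    "means_for_snr",
    "simulate_trace",
    "simulate_population",
    "two_state_params",
    "linear_chain_params",
]


def snr_two_state(
    mu1: float,
    mu2: float,
    family: str = "poisson",
    sigma1: float | None = None,
    sigma2: float | None = None,
) -> float:
    """Two-state signal-to-noise ratio for one channel.

    Poisson: |mu2 - mu1| / sqrt((mu1 + mu2)/2) (shot-noise variance equals the
    mean).  Gaussian: |mu2 - mu1| / sqrt((sigma1^2 + sigma2^2)/2).
    """
    if family == "poisson":
        if mu1 <= 0 or mu2 <= 0:
            raise ValueError("Poisson means must be positive")
        return abs(mu2 - mu1) / math.sqrt((mu1 + mu2) / 2.0)
    if family == "gaussian":
        if sigma1 is None or sigma2 is None or sigma1 <= 0 or sigma2 <= 0:
            raise ValueError("Gaussian SNR requires positive sigma1 and sigma2")
        return abs(mu2 - mu1) / math.sqrt((sigma1**2 + sigma2**2) / 2.0)
    raise ValueError(f"unknown family {family!r}")


def combined_snr(per_channel_snrs: Sequence[float]) -> float:
    """Overall SNR of independent channels: root sum of squares."""
    if len(per_channel_snrs) == 0:
        raise ValueError("need at least one channel SNR")
    if any(s < 0 for s in per_channel_snrs):
        raise ValueError("channel SNRs must be non-negative")
    return math.sqrt(sum(s * s for s in per_channel_snrs))


def means_for_snr(
    snr: float, mu1: float, family: str = "poisson", sigma: float | None = None
) -> float:
    """Second state mean achieving a target two-state SNR above base mean mu1."""
    if snr < 0:
        raise ValueError("snr must be >= 0")
    if family == "poisson":
        if mu1 <= 0:
            raise ValueError("mu1 must be positive")
        # solve d^2 - (snr^2/2) d - snr^2 mu1 = 0 for d = mu2 - mu1
        s2 = snr * snr
        d = (s2 / 2.0 + math.sqrt(s2 * s2 / 4.0 + 4.0 * s2 * mu1)) / 2.0
        return mu1 + d
    if family == "gaussian":
        if sigma is None or sigma <= 0:
            raise ValueError("Gaussian mode requires positive sigma")
        return mu1 + snr * sigma
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# Concrete parameter helpers

def two_state_params(
    k12: float,
    k21: float,
    snr: float,
    mu1: float = 100.0,
    n_channels: int = 1,
    anti_correlated: bool = True,
) -> HmmParams:
    """Two-state Poisson parameters at a target overall SNR.

    With ``n_channels > 1`` the per-channel SNR is ``snr / sqrt(n_channels)``
    (independent channels add in quadrature) and channel means alternate
    direction, emulating donor/acceptor anti-correlation.
    """
    A = np.array([[1.0 - k12, k12], [k21, 1.0 - k21]])
    per_channel = snr / math.sqrt(n_channels)
    mu2 = means_for_snr(per_channel, mu1)
    mu = np.empty((2, n_channels))
    for c in range(n_channels):
        if anti_correlated and c % 2 == 1:
            mu[:, c] = [mu2, mu1]
        else:
            mu[:, c] = [mu1, mu2]
    em = EmissionParams(families=tuple(["poisson"] * n_channels), mu=mu)
    return HmmParams(A=A, emissions=em, pi0=stationary_distribution(A))


def linear_chain_params(
    rates: float | Sequence[float],
    snr_outer: float,
    K: int = 3,
    mu1: float = 100.0,
) -> HmmParams:
    """K-state linear-chain Poisson parameters with evenly spaced means.

    The outer states sit at the two-state SNR ``snr_outer``; intermediate
    states are spaced evenly between them (for K=3 the middle state is halfway,
    giving an effective SNR of about half between adjacent states).
    ``rates`` is the shared (or per-edge, ordered (0,1),(1,0),(1,2),(2,1),...)
    transition probability per step along the chain.
    """
    mu_top = means_for_snr(snr_outer, mu1)
    mus = np.linspace(mu1, mu_top, K)
    n_edges = 2 * (K - 1)
    if np.isscalar(rates):
        rvec = [float(rates)] * n_edges
    else:
        rvec = [float(r) for r in rates]
        if len(rvec) != n_edges:
            raise ValueError(f"need {n_edges} rates for a {K}-state chain")
    A = np.eye(K)
    idx = 0
    for i in range(K - 1):
        for (a, b) in ((i, i + 1), (i + 1, i)):
            A[a, b] = rvec[idx]
            idx += 1
    np.fill_diagonal(A, 0.0)
    np.fill_diagonal(A, 1.0 - A.sum(axis=1))
    if np.any(np.diag(A) < 0):
        raise ValueError("rates too large: negative self-transition probability")
    em = EmissionParams(families=("poisson",), mu=mus[:, None].copy())
    return HmmParams(A=A, emissions=em, pi0=stationary_distribution(A))


# ---------------------------------------------------------------------------
# Simulation

@dataclass
class SimulationConfig:
    """Study conditions for a simulated population.

    ``length_mode='photobleach'`` couples trace length to SNR as
    ``T = round(c / snr)``; ``'fixed'`` uses ``T`` directly.
    """

    params: HmmParams
    snr: float | None = None
    c: float = 10_000.0
    n_traces: int = 1
    seed: int = 0
    length_mode: Literal["photobleach", "fixed"] = "photobleach"
    T: int | None = None
    dt: float = 1.0
    metadata: dict[str, str] = field(default_factory=dict)

    def trace_length(self) -> int:
        if self.length_mode == "fixed":
            if self.T is None or self.T < 2:
                raise ValueError("fixed length mode requires T >= 2")
            return int(self.T)
        if self.snr is None or self.snr <= 0:
            raise ValueError("photobleach mode requires snr > 0")
        if self.c <= 0:
            raise ValueError("c must be positive")
        T = int(round(self.c / self.snr))
        if T < 2:
            raise ValueError(
                f"T = round(c/snr) = {T} < 2; increase the photobleaching constant c"
            )
        return T


def simulate_trace(
    config: SimulationConfig, trace_index: int = 0
) -> tuple[Trace, np.ndarray]:
    """Simulate one trace; returns ``(trace, hidden_states)``.

    The hidden path starts from the stationary distribution of the transition
    matrix and the emissions are conditionally independent given the state.
    Deterministic given ``(config.seed, trace_index)`` regardless of the order
    in which traces of a population are generated.
    """
    params = config.params
    A = params.A
    K = A.shape[0]
    T = config.trace_length()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) % 2**31, trace_index]))

    pi = stationary_distribution(A) if K > 1 else np.array([1.0])
    states = np.empty(T, dtype=np.int64)
    cum = np.cumsum(A, axis=1)
    u = rng.random(T)
    states[0] = np.searchsorted(np.cumsum(pi), u[0], side="right")
    for t in range(1, T):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t], side="right")

    C = params.emissions.n_channels
    channels = np.empty((T, C))
    for c in range(C):
        fam = params.emissions.families[c]
        mu = params.emissions.mu[states, c]
        if fam == "poisson":
            channels[:, c] = rng.poisson(mu)
        elif fam == "gaussian":
            channels[:, c] = rng.normal(mu, params.emissions.sigma[states, c])
        else:
            raise ValueError(f"unknown family {fam!r}")

    meta = dict(config.metadata)
    meta.setdefault("families", ",".join(params.emissions.families))
    if config.snr is not None:
        meta.setdefault("snr", repr(float(config.snr)))
    trace = Trace(
        id=f"sim-{config.seed}-{trace_index:04d}",
        dt=config.dt,
        channels=channels,
        metadata=meta,
    )
    return trace, states


def simulate_population(
    config: SimulationConfig,
) -> tuple[TraceSet, dict[str, np.ndarray]]:
    """Simulate ``config.n_traces`` traces; returns the set and hidden paths."""
    traces: list[Trace] = []
    paths: dict[str, np.ndarray] = {}
    for i in range(config.n_traces):
        tr, states = simulate_trace(config, i)
        traces.append(tr)
        paths[tr.id] = states
    return TraceSet(traces, provenance=f"simulated (seed={config.seed})"), paths
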