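"""Hidden Markov model likelihood evaluation and Baum-Welch fitting.

The data likelihood of a trace under a K-state HMM is the sum over all hidden
paths of path probability times emission probability; it is evaluated by the
scaled forward recursion, with multi-channel emissions multiplying under
conditional independence.  Maximum-likelihood parameters are found by
Baum-Welch (EM), supporting restricted topologies (forbidden transitions stay
zero), tied emissions (states sharing a pooled emission update), and a
detailed-balance (thermodynamic closure) constraint on the transition matrix.

The initial state distribution defaults to the stationary distribution of the
transition matrix — consistent with molecules observed at steady state — and
then contributes no free parameters; it can instead be estimated freely.

After fitting, states are relabeled in ascending order of the first channel's
emission mean, so ``k12`` always denotes the low-to-high intensity transition.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.special import gammaln

from . import _kernels
from .markov import stationary_distribution
from .models import ModelSpec, validate_model
from .traces import Trace

__all__ = [
    "EmissionParams",
    "HmmParams",
    "FitResult",
    "log_likelihood",
    "posterior_state_probs",
    "fit_hmm",
    "parse_param",
    "get_param",
    "set_param",
]


@dataclass
class EmissionParams:
    """Concrete per-(state, channel) emission parameters.

    ``mu`` has shape (K, C); ``sigma`` likewise for Gaussian channels (ignored,
    may be NaN, for Poisson channels).
    """

    families: tuple[str, ...]
    mu: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        if self.sigma is not None:
            self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        if self.sigma is None and "gaussian" in self.families:
            raise ValueError("gaussian channels require sigma")
        for c, fam in enumerate(self.families):
            if fam == "poisson" and np.any(self.mu[:, c] <= 0):
                raise ValueError(f"channel {c + 1}: Poisson means must be positive")
            if fam == "gaussian" and np.any(self.sigma[:, c] <= 0):
                raise ValueError(f"channel {c + 1}: Gaussian sd must be positive")

    @property
    def K(self) -> int:
        return self.mu.shape[0]

    @property
    def n_channels(self) -> int:
        return len(self.families)

    def copy(self) -> "EmissionParams":
        return EmissionParams(
            self.families,
            self.mu.copy(),
            None if self.sigma is None else self.sigma.copy(),
        )


@dataclass
class HmmParams:
    """Transition matrix, emission parameters and initial distribution."""

    A: np.ndarray
    emissions: EmissionParams
    pi0: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.pi0 = np.asarray(self.pi0, dtype=float)
        K = self.A.shape[0]
        if self.A.shape != (K, K):
            raise ValueError("A must be square")
        if np.max(np.abs(self.A.sum(axis=1) - 1.0)) > 1e-8:
            raise ValueError("rows of A must sum to 1")
        if np.any(self.A < -1e-12) or np.any(self.A > 1 + 1e-12):
            raise ValueError("entries of A must lie in [0, 1]")
        if self.pi0.shape != (K,) or abs(self.pi0.sum() - 1.0) > 1e-8:
            raise ValueError("pi0 must be a length-K probability vector")
        if self.emissions.K != K:
            raise ValueError("emission parameters must cover K states")

    @property
    def K(self) -> int:
        return self.A.shape[0]

    def copy(self) -> "HmmParams":
        return HmmParams(self.A.copy(), self.emissions.copy(), self.pi0.copy())


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model to one trace."""

    trace_id: str
    spec: ModelSpec
    params: HmmParams
    loglik: float
    n_iter: int
    converged: bool
    posteriors: np.ndarray
    restarts_used: int = 1
    degenerate: bool = False
    loglik_path: list[float] = field(default_factory=list)
    cis: dict = field(default_factory=dict)

    def param_dict(self) -> dict[str, float]:
        """Flat mapping of named parameters (1-based state labels).

        Includes ``A[i][j]`` entries for allowed edges with ``kij`` aliases,
        emission ``mu[s][c]`` (and ``sigma[s][c]``), and ``loglik``.
        """
        out: dict[str, float] = {}
        K = self.params.K
        for i, j in sorted(self.spec.topology.edges):
            v = float(self.params.A[i, j])
            out[f"A[{i + 1}][{j + 1}]"] = v
            out[f"k{i + 1}{j + 1}"] = v
        em = self.params.emissions
        for s in range(K):
            for c in range(em.n_channels):
                out[f"mu[{s + 1}][{c + 1}]"] = float(em.mu[s, c])
                if em.families[c] == "gaussian":
                    out[f"sigma[{s + 1}][{c + 1}]"] = float(em.sigma[s, c])
        out["loglik"] = float(self.loglik)
        return out


# ---------------------------------------------------------------------------
# Parameter naming: "A[1][2]" / "k12" / "mu[2][1]" / "sigma[2][1]" (1-based)

_PARAM_RE = re.compile(r"^(A|mu|sigma)\[(\d+)\]\[(\d+)\]$")
_RATE_RE = re.compile(r"^k(\d)(\d)$")


def parse_param(name: str) -> tuple[str, int, int]:
    """Parse a parameter name into ``(kind, first_index, second_index)``, 0-based."""
    m = _PARAM_RE.match(name)
    if m:
        return m.group(1), int(m.group(2)) - 1, int(m.group(3)) - 1
    m = _RATE_RE.match(name)
    if m:
        return "A", int(m.group(1)) - 1, int(m.group(2)) - 1
    raise ValueError(f"cannot parse parameter name {name!r}")


def get_param(params: HmmParams, name: str) -> float:
    kind, a, b = parse_param(name)
    if kind == "A":
        return float(params.A[a, b])
    if kind == "mu":
        return float(params.emissions.mu[a, b])
    return float(params.emissions.sigma[a, b])


def set_param(params: HmmParams, name: str, value: float) -> HmmParams:
    """Return a copy of ``params`` with one named parameter replaced.

    Setting a transition probability adjusts the same row's diagonal so the
    row still sums to one; a value that would drive the diagonal negative
    raises ``ValueError``.  The initial distribution is refreshed to the
    stationary distribution of the new transition matrix when possible.
    """
    kind, a, b = parse_param(name)
    out = params.copy()
    if kind == "A":
        if a == b:
            raise ValueError("set off-diagonal entries; the diagonal is residual")
        off_sum = out.A[a].sum() - out.A[a, a] - out.A[a, b]
        if value < 0 or off_sum + value > 1 + 1e-12:
            raise ValueError(f"A[{a + 1}][{b + 1}] = {value} leaves no valid diagonal")
        out.A[a, b] = value
        out.A[a, a] = 1.0 - off_sum - value
        try:
            out.pi0 = stationary_distribution(out.A)
        except ValueError:
            pass
    elif kind == "mu":
        if params.emissions.families[b] == "poisson" and value <= 0:
            raise ValueError("Poisson mean must be positive")
        out.emissions.mu[a, b] = value
    else:
        if value <= 0:
            raise ValueError("sigma must be positive")
        out.emissions.sigma[a, b] = value
    return out


# ---------------------------------------------------------------------------
# Likelihood evaluation

def log_emission_matrix(trace: Trace, em: EmissionParams) -> np.ndarray:
    """(T, K) matrix of per-step log emission probabilities, channels summed."""
    if trace.n_channels != em.n_channels:
        raise ValueError(
            f"trace has {trace.n_channels} channels, params expect {em.n_channels}"
        )
    T, K = trace.T, em.K
    logB = np.zeros((T, K))
    for c, fam in enumerate(em.families):
        x = trace.channels[:, c]
        if fam == "poisson":
            if np.any(x < 0):
                raise ValueError(f"negative intensity in Poisson channel {c + 1}")
            lg = gammaln(x + 1.0)
            mu = em.mu[:, c]
            logB += x[:, None] * np.log(mu)[None, :] - mu[None, :] - lg[:, None]
        else:
            mu = em.mu[:, c]
            sd = em.sigma[:, c]
            z = (x[:, None] - mu[None, :]) / sd[None, :]
            logB += -0.5 * z**2 - np.log(sd)[None, :] - 0.5 * math.log(2 * math.pi)
    return logB


def log_likelihood(trace: Trace, params: HmmParams) -> float:
    """Natural log of p(data | params) by the scaled forward recursion."""
    logB = log_emission_matrix(trace, params.emissions)
    return float(_kernels.forward_loglik(params.A, params.pi0, logB))


def posterior_state_probs(trace: Trace, params: HmmParams) -> np.ndarray:
    """(T, K) forward-backward smoothing posteriors (rows sum to 1)."""
    logB = log_emission_matrix(trace, params.emissions)
    _, gamma, _ = _kernels.forward_backward(params.A, params.pi0, logB)
    return gamma


# ---------------------------------------------------------------------------
# Baum-Welch fitting

def _initial_params(
    trace: Trace, spec: ModelSpec, rng: np.random.Generator, jitter: bool
) -> HmmParams:
    """Quantile-based, scale-free initialization.

    Emission means start at evenly spaced quantiles of each channel's pooled
    intensity distribution; the transition matrix spreads 0.1 off-diagonal
    mass over the allowed edges of each row.  Restarts jitter means by +-10%.
    """
    K, C = spec.K, spec.n_channels
    mu = np.empty((K, C))
    sigma = np.empty((K, C))
    qs = (np.arange(K) + 1.0) / (K + 1.0)
    for c in range(C):
        x = trace.channels[:, c]
        mu[:, c] = np.quantile(x, qs)
        sigma[:, c] = max(np.std(x) / max(K, 1), 1e-3)
        if spec.emissions.families[c] == "poisson":
            mu[:, c] = np.maximum(mu[:, c], 1e-3)
    if jitter:
        mu = mu * (1.0 + rng.uniform(-0.1, 0.1, size=mu.shape))
        for c in range(C):
            if spec.emissions.families[c] == "poisson":
                mu[:, c] = np.maximum(mu[:, c], 1e-3)
    A = np.eye(K)
    for i in range(K):
        out = spec.topology.out_edges(i)
        if out:
            p = 0.1 / len(out)
            for (_, j) in out:
                A[i, j] = p
            A[i, i] = 1.0 - 0.1
    try:
        pi0 = stationary_distribution(A)
    except ValueError:
        pi0 = np.full(K, 1.0 / K)
    sig = sigma if "gaussian" in spec.emissions.families else None
    em = EmissionParams(tuple(spec.emissions.families), mu, sig)
    return HmmParams(A, em, pi0)


def _mstep_transitions(
    xi: np.ndarray, spec: ModelSpec, A_prev: np.ndarray
) -> np.ndarray:
    mask = spec.topology.mask()
    if spec.detailed_balance:
        return np.asarray(_kernels.reversible_mstep(xi * mask, mask))
    A = np.zeros_like(A_prev)
    xi_m = xi * mask
    rows = xi_m.sum(axis=1)
    for i in range(A.shape[0]):
        if rows[i] > 0:
            A[i] = xi_m[i] / rows[i]
        else:
            A[i] = A_prev[i]
    return A


def _mstep_emissions(
    trace: Trace, gamma: np.ndarray, spec: ModelSpec, em_prev: EmissionParams
) -> EmissionParams:
    K, C = spec.K, spec.n_channels
    mu = em_prev.mu.copy()
    sigma = None if em_prev.sigma is None else em_prev.sigma.copy()
    for c in range(C):
        x = trace.channels[:, c]
        fam = spec.emissions.families[c]
        rng_x = float(np.ptp(x))
        for group in spec.emissions.groups_for(c, K):
            w = gamma[:, list(group)].sum(axis=1)
            wsum = w.sum()
            if wsum <= 1e-300:
                continue
            m = float(w @ x) / wsum
            if fam == "poisson":
                m = max(m, 1e-6)
                for s in group:
                    mu[s, c] = m
            else:
                var = float(w @ (x - m) ** 2) / wsum
                sd = max(math.sqrt(max(var, 0.0)), 1e-6 * max(rng_x, 1e-6))
                for s in group:
                    mu[s, c] = m
                    sigma[s, c] = sd
    return EmissionParams(em_prev.families, mu, sigma)


def _apply_fixed(params: HmmParams, fixed: Mapping[str, float] | None) -> HmmParams:
    if not fixed:
        return params
    for name, value in fixed.items():
        params = set_param(params, name, value)
    return params


def _sort_states(params: HmmParams, spec: ModelSpec) -> tuple[HmmParams, np.ndarray]:
    """Relabel states by ascending first-channel emission mean."""
    order = np.argsort(params.emissions.mu[:, 0], kind="stable")
    if np.array_equal(order, np.arange(params.K)):
        return params, order
    A = params.A[np.ix_(order, order)]
    em = EmissionParams(
        params.emissions.families,
        params.emissions.mu[order],
        None if params.emissions.sigma is None else params.emissions.sigma[order],
    )
    return HmmParams(A, em, params.pi0[order]), order


def _permutation_invariant(spec: ModelSpec) -> bool:
    """Whether relabeling keeps the topology valid (needed to sort states)."""
    mask = spec.topology.mask()
    return bool(np.all(mask == mask[0, 0])) or np.all(mask)


def fit_hmm(
    trace: Trace,
    spec: ModelSpec,
    *,
    max_iter: int = 1000,
    tol: float = 1e-6,
    n_restarts: int = 3,
    seed: int = 0,
    fixed_params: Mapping[str, float] | None = None,
    pi0_mode: str = "stationary",
    init: HmmParams | None = None,
    sort_states: bool = True,
) -> FitResult:
    """Fit ``spec`` to ``trace`` by Baum-Welch maximum likelihood.

    The per-iteration log-likelihood is non-decreasing (up to ~1e-8 numerical
    slack); iteration stops when the increase falls below ``tol`` or after
    ``max_iter`` iterations.  The best of ``n_restarts`` jittered
    initializations is returned (a user-supplied ``init`` replaces the first).
    Tied emission states share a pooled update; forbidden transitions stay
    exactly zero; with ``spec.detailed_balance`` the returned transition matrix
    satisfies pi_i A_ij = pi_j A_ji for its stationary distribution.

    ``fixed_params`` pins named parameters (e.g. ``{"k12": 0.2}``) during the
    fit, which is how profile-likelihood scans re-maximize the remaining
    parameters.
    """
    if trace.T < 2:
        raise ValueError("trace must have at least 2 time steps")
    problems = validate_model(spec)
    if problems:
        raise ValueError("invalid model spec: " + "; ".join(problems))
    if trace.n_channels != spec.n_channels:
        raise ValueError(
            f"trace has {trace.n_channels} channels, model expects {spec.n_channels}"
        )

    rng = np.random.default_rng(np.random.SeedSequence([seed % 2**31, 104729]))
    best: FitResult | None = None
    for restart in range(max(1, n_restarts)):
        if restart == 0 and init is not None:
            params = _apply_fixed(init.copy(), fixed_params)
        else:
            params = _apply_fixed(
                _initial_params(trace, spec, rng, jitter=restart > 0), fixed_params
            )
        ll_path: list[float] = []
        ll_prev = -np.inf
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            logB = log_emission_matrix(trace, params.emissions)
            ll, gamma, xi = _kernels.forward_backward(params.A, params.pi0, logB)
            ll = float(ll)
            if not math.isfinite(ll):
                ll_path.append(ll)
                break
            # with pi0 pinned to the stationary distribution the update is a
            # generalized EM step and can dip slightly near the fixed point;
            # keep the previous (better) parameters in that case
            if ll < ll_prev - 1e-8 * max(1.0, abs(ll_prev)):
                params = prev_params
                converged = True
                break
            ll_path.append(ll)
            if abs(ll - ll_prev) < tol:
                converged = True
                break
            ll_prev = ll
            prev_params = params
            A = _mstep_transitions(xi, spec, params.A)
            em = _mstep_emissions(trace, gamma, spec, params.emissions)
            if pi0_mode == "stationary":
                try:
                    pi0 = stationary_distribution(A)
                except ValueError:
                    pi0 = params.pi0
            elif pi0_mode == "free":
                pi0 = gamma[0] / gamma[0].sum()
            else:
                raise ValueError(f"unknown pi0_mode {pi0_mode!r}")
            params = _apply_fixed(HmmParams(A, em, pi0), fixed_params)
        final_ll = ll_path[-1] if ll_path else -np.inf
        if best is None or final_ll > best.loglik:
            mu = params.emissions.mu
            degenerate = spec.K > 1 and (
                float(np.ptp(trace.channels[:, 0])) == 0.0
                or np.min(np.abs(np.diff(np.sort(mu[:, 0]))))
                < 1e-9 * (abs(float(np.mean(mu[:, 0]))) + 1.0)
            )
            best = FitResult(
                trace_id=trace.id,
                spec=spec,
                params=params,
                loglik=final_ll,
                n_iter=n_iter,
                converged=converged,
                posteriors=np.empty((0, spec.K)),
                restarts_used=restart + 1,
                degenerate=bool(degenerate),
                loglik_path=ll_path,
            )
    assert best is not None
    if sort_states and not fixed_params and _permutation_invariant(spec):
        best.params, _ = _sort_states(best.params, spec)
    best.posteriors = posterior_state_probs(trace, best.params)
    best.loglik = log_likelihood(trace, best.params)
    return best
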