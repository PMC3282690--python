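"""Uncertainty-weighted EM clustering of per-molecule fitted parameters.

Each molecule contributes its MLE parameter vector (up to three parameters)
and a diagonal covariance derived from its own confidence intervals, so
poorly determined molecules pull cluster centers less than well determined
ones.  The mixture likelihood is

    p(theta_i) = sum_c pi_c * Normal(theta_i; m_c, Sigma_i)

— note the covariance is the molecule's *own* measurement covariance, not a
fitted cluster covariance.  The M-step center update is therefore the
precision-weighted mean of the assigned points.  Rates are clustered on a
log10 scale by default because their confidence intervals are multiplicative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .hmm import FitResult, get_param

__all__ = [
    "ClusterInput",
    "ClusterFit",
    "build_cluster_input",
    "fit_clusters",
    "select_cluster_number",
    "partition_accuracy",
]


@dataclass
class ClusterInput:
    """Per-trace parameter estimates with per-trace diagonal variances."""

    theta: np.ndarray  # (n, d)
    var: np.ndarray  # (n, d) diagonal variances
    trace_ids: list[str]
    param_names: list[str]
    transform: str = "log10"
    level: float = 0.90

    def __post_init__(self) -> None:
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        self.var = np.atleast_2d(np.asarray(self.var, dtype=float))
        if self.theta.shape != self.var.shape:
            raise ValueError("theta and var must have the same shape")
        if self.theta.shape[1] > 3:
            raise ValueError("at most three parameters can be clustered jointly")
        if np.any(self.var <= 0) or not np.all(np.isfinite(self.var)):
            raise ValueError("variances must be positive and finite")

    @property
    def n(self) -> int:
        return self.theta.shape[0]

    @property
    def d(self) -> int:
        return self.theta.shape[1]


@dataclass
class ClusterFit:
    """EM mixture fit of a population of molecules."""

    C: int
    centers: np.ndarray  # (C, d)
    weights: np.ndarray  # (C,)
    responsibilities: np.ndarray  # (n, C)
    sizes: np.ndarray  # (C,) sum of responsibilities
    loglik: float
    bic: float
    n_iter: int
    converged: bool
    loglik_path: list[float] = field(default_factory=list)
    empty_clusters: list[int] = field(default_factory=list)

    def assignments(self) -> np.ndarray:
        """Max-responsibility cluster index per trace."""
        return np.argmax(self.responsibilities, axis=1)


def build_cluster_input(
    fits: list[FitResult],
    param_names: list[str],
    transform: str = "log10",
    level: float = 0.90,
) -> ClusterInput:
    """Assemble clustering inputs from fits carrying confidence intervals.

    The per-dimension sd is the (transformed) CI half-width divided by the
    normal quantile z(level) (1.645 at 90%), inverting the Gaussian likelihood
    approximation; asymmetric intervals are symmetrized by averaging the two
    half-widths.  A lower bound clipped at zero is floored at MLE/100 before a
    log transform.
    """
    if transform not in ("log10", "linear"):
        raise ValueError(f"unknown transform {transform!r}")
    if not 1 <= len(param_names) <= 3:
        raise ValueError("cluster on one to three parameters")
    z = norm.ppf(0.5 + level / 2.0)
    n = len(fits)
    theta = np.empty((n, len(param_names)))
    var = np.empty_like(theta)
    ids: list[str] = []
    for i, fit in enumerate(fits):
        ids.append(fit.trace_id)
        for j, name in enumerate(param_names):
            if name not in fit.cis:
                raise KeyError(
                    f"trace {fit.trace_id!r} has no confidence interval for {name!r}"
                )
            ci = fit.cis[name]
            mle = get_param(fit.params, name)
            lo, hi = ci.lo, ci.hi
            if transform == "log10":
                if mle <= 0:
                    raise ValueError(
                        f"trace {fit.trace_id!r}: {name} = {mle} not log-transformable"
                    )
                lo = max(lo, mle / 100.0)
                hi = max(hi, mle)
                t = math.log10(mle)
                half = 0.5 * (math.log10(hi) - math.log10(lo))
            else:
                t = mle
                half = 0.5 * (hi - lo)
            sd = max(half / z, 1e-12)
            theta[i, j] = t
            var[i, j] = sd * sd
    return ClusterInput(theta, var, ids, list(param_names), transform, level)


def _log_resp(
    theta: np.ndarray, var: np.ndarray, centers: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """(n, C) log of pi_c * Normal(theta_i; m_c, Sigma_i), unnormalized."""
    n, d = theta.shape
    C = centers.shape[0]
    out = np.empty((n, C))
    const = -0.5 * d * math.log(2 * math.pi) - 0.5 * np.log(var).sum(axis=1)
    for c in range(C):
        z2 = ((theta - centers[c]) ** 2 / var).sum(axis=1)
        out[:, c] = math.log(max(weights[c], 1e-300)) + const - 0.5 * z2
    return out


def _init_centers(
    theta: np.ndarray, C: int, rng: np.random.Generator
) -> np.ndarray:
    """k-means++-style spread: centers drawn from the observed points."""
    n = theta.shape[0]
    first = rng.integers(n)
    chosen = [first]
    for _ in range(1, C):
        d2 = np.min(
            [((theta - theta[i]) ** 2).sum(axis=1) for i in chosen], axis=0
        )
        total = d2.sum()
        if total <= 0:
            chosen.append(int(rng.integers(n)))
            continue
        chosen.append(int(rng.choice(n, p=d2 / total)))
    return theta[chosen].copy()


def fit_clusters(
    inp: ClusterInput,
    C: int,
    n_init: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> ClusterFit:
    """EM fit of a C-cluster mixture with per-trace measurement covariances.

    Runs ``n_init`` random initializations and returns the best by final
    log-likelihood; the log-likelihood is non-decreasing within each run.
    The mixture BIC uses k = C*(d+1) - 1 free parameters (d per center plus
    C - 1 weights).
    """
    if C < 1:
        raise ValueError("C must be >= 1")
    if C > inp.n:
        raise ValueError(f"cannot fit {C} clusters to {inp.n} traces")
    theta, var = inp.theta, inp.var
    rng = np.random.default_rng(np.random.SeedSequence([seed % 2**31, C]))

    best: ClusterFit | None = None
    for _ in range(max(1, n_init)):
        centers = _init_centers(theta, C, rng)
        weights = np.full(C, 1.0 / C)
        ll_prev = -np.inf
        ll_path: list[float] = []
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            lr = _log_resp(theta, var, centers, weights)
            per_trace = logsumexp(lr, axis=1)
            ll = float(per_trace.sum())
            ll_path.append(ll)
            resp = np.exp(lr - per_trace[:, None])
            if abs(ll - ll_prev) < tol:
                converged = True
                break
            ll_prev = ll
            # M-step: precision-weighted centers, mean responsibilities
            for c in range(C):
                w = resp[:, c][:, None] / var
                denom = w.sum(axis=0)
                if np.all(denom > 0):
                    centers[c] = (w * theta).sum(axis=0) / denom
            weights = resp.mean(axis=0)
            weights = np.maximum(weights, 1e-300)
            weights /= weights.sum()
        sizes = resp.sum(axis=0)
        k_free = C * (inp.d + 1) - 1
        bic_val = -2.0 * ll + k_free * math.log(inp.n)
        fit = ClusterFit(
            C=C,
            centers=centers.copy(),
            weights=weights.copy(),
            responsibilities=resp,
            sizes=sizes,
            loglik=ll,
            bic=float(bic_val),
            n_iter=n_iter,
            converged=converged,
            loglik_path=ll_path,
            empty_clusters=[c for c in range(C) if sizes[c] < 1e-6],
        )
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    return best


def select_cluster_number(
    inp: ClusterInput,
    cmax: int,
    n_init: int = 10,
    seed: int = 0,
    **em_options,
) -> tuple[pd.DataFrame, dict[int, ClusterFit]]:
    """Fit C = 1..cmax clusters and tabulate log-likelihood and BIC.

    Returns the summary table (columns C, loglik, delta_loglik, k, bic, best)
    and the fits themselves.  The minimum-BIC row is flagged; the leveling-off
    of delta_loglik is left to inspection, as is conventional.
    """
    if cmax < 1:
        raise ValueError("cmax must be >= 1")
    fits: dict[int, ClusterFit] = {}
    rows = []
    prev_ll: float | None = None
    for C in range(1, cmax + 1):
        fit = fit_clusters(inp, C, n_init=n_init, seed=seed, **em_options)
        fits[C] = fit
        rows.append(
            {
                "C": C,
                "loglik": fit.loglik,
                "delta_loglik": float("nan") if prev_ll is None else fit.loglik - prev_ll,
                "k": C * (inp.d + 1) - 1,
                "bic": fit.bic,
            }
        )
        prev_ll = fit.loglik
    table = pd.DataFrame(rows)
    table["best"] = table["bic"] == table["bic"].min()
    return table, fits


def partition_accuracy(
    fit: ClusterFit, true_labels: np.ndarray | list[int]
) -> float:
    """Fraction of traces whose max-responsibility cluster matches the
    generating population under the best cluster-to-population mapping."""
    from itertools import permutations

    labels = np.asarray(true_labels)
    assign = fit.assignments()
    pops = np.unique(labels)
    best = 0.0
    for perm in permutations(range(fit.C), len(pops)):
        mapping = dict(zip(perm, pops))
        correct = sum(
            1 for a, t in zip(assign, labels) if mapping.get(a, -1) == t
        )
        best = max(best, correct / len(labels))
    return best
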