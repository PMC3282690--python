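"""Likelihood-ratio confidence intervals for fitted HMM parameters.

A bound at confidence ``level`` is the parameter value at which the data
log-likelihood has dropped by Delta = chi^2_1(level)/2 below its maximum
(1.3529 at 90%), located by root bracketing around the MLE.  In *conditional*
mode all other parameters stay at their MLE values; in *profile* mode they are
re-maximized at each scan point.  A bound is clipped to the edge of the
parameter's valid domain (and flagged) when the likelihood never drops by
Delta on that side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2

from .hmm import FitResult, HmmParams, fit_hmm, get_param, log_likelihood, parse_param, set_param
from .traces import Trace

__all__ = ["CiResult", "confidence_interval", "confidence_intervals"]


@dataclass
class CiResult:
    param: str
    level: float
    lo: float
    hi: float
    mode: str
    mle: float
    clipped_lo: bool = False
    clipped_hi: bool = False

    def half_widths(self) -> tuple[float, float]:
        return self.mle - self.lo, self.hi - self.mle


def _param_domain(fit: FitResult, param: str) -> tuple[float, float | None]:
    """(lower, upper) domain for a conditional scan; upper None = unbounded."""
    kind, a, b = parse_param(param)
    params = fit.params
    if kind == "A":
        off_other = params.A[a].sum() - params.A[a, a] - params.A[a, b]
        return 0.0, 1.0 - off_other
    if kind == "mu":
        if params.emissions.families[b] == "poisson":
            return 1e-9, None
        return -np.inf, None
    return 1e-12, None  # sigma


def confidence_interval(
    trace: Trace,
    fit: FitResult,
    param: str,
    level: float = 0.90,
    mode: str = "conditional",
    rtol: float = 1e-4,
) -> CiResult:
    """Likelihood-ratio confidence interval for one fitted parameter."""
    if not fit.converged:
        raise ValueError("confidence intervals require a converged fit")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    if mode not in ("conditional", "profile"):
        raise ValueError(f"unknown mode {mode!r}")

    mle = get_param(fit.params, param)
    delta = 0.5 * chi2.ppf(level, df=1)
    ll_max = fit.loglik

    def loglik_at(v: float) -> float:
        if mode == "conditional":
            try:
                p = set_param(fit.params, param, v)
            except ValueError:
                return -np.inf
            return log_likelihood(trace, p)
        try:
            refit = fit_hmm(
                trace,
                fit.spec,
                fixed_params={param: v},
                init=fit.params,
                n_restarts=1,
                sort_states=False,
            )
        except ValueError:
            return -np.inf
        return refit.loglik

    def drop(v: float) -> float:
        d = (ll_max - loglik_at(v)) - delta
        # a degenerate scan point (e.g. an absorbing chain at the domain edge)
        # counts as rejected; keep the value finite for the root bracketing
        return 1e12 if not math.isfinite(d) or d > 1e12 else d

    lo_edge, hi_edge = _param_domain(fit, param)
    scale = max(abs(mle), 1e-6)

    def solve(a: float, b: float) -> float:
        return float(brentq(drop, a, b, xtol=rtol * scale * 1e-2, rtol=8.9e-16))

    # upper bound
    clipped_hi = False
    if hi_edge is not None and math.isfinite(hi_edge):
        if drop(hi_edge) <= 0:
            hi, clipped_hi = hi_edge, True
        else:
            hi = solve(mle, hi_edge)
    else:
        step, b = 0.5 * scale, mle
        hi = mle
        found = False
        for _ in range(80):
            b = b + step
            if drop(b) > 0:
                hi = solve(max(mle, b - step), b)
                found = True
                break
            step *= 2.0
        if not found:
            hi, clipped_hi = b, True

    # lower bound
    clipped_lo = False
    if math.isfinite(lo_edge):
        if drop(lo_edge) <= 0:
            lo, clipped_lo = lo_edge, True
        else:
            lo = solve(lo_edge, mle)
    else:
        step, a = 0.5 * scale, mle
        lo = mle
        found = False
        for _ in range(80):
            a = a - step
            if drop(a) > 0:
                lo = solve(a, min(mle, a + step))
                found = True
                break
            step *= 2.0
        if not found:
            lo, clipped_lo = a, True

    return CiResult(
        param=param,
        level=level,
        lo=float(min(lo, mle)),
        hi=float(max(hi, mle)),
        mode=mode,
        mle=float(mle),
        clipped_lo=clipped_lo,
        clipped_hi=clipped_hi,
    )


def confidence_intervals(
    trace: Trace,
    fit: FitResult,
    params: list[str],
    level: float = 0.90,
    mode: str = "conditional",
) -> dict[str, CiResult]:
    """Compute CIs for several parameters and attach them to ``fit.cis``."""
    out: dict[str, CiResult] = {}
    for name in params:
        ci = confidence_interval(trace, fit, name, level=level, mode=mode)
        out[name] = ci
        fit.cis[name] = ci
    return out
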