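"""Model scoring and selection by the Bayesian information criterion.

BIC = -2 log p(data | MLE) + k ln(N), with k the number of free parameters
(transition probabilities, emission means and sds; the initial distribution is
stationary and free of charge) and N the trace length in time steps.  Among
candidate models fitted to the same trace, the smallest BIC wins; ties break
toward fewer parameters, then by name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .hmm import FitResult
from .models import count_free_parameters
from .traces import Trace

__all__ = ["BicResult", "bic", "select_model"]


@dataclass
class BicResult:
    model_name: str
    loglik: float
    k: int
    N: int
    bic: float
    delta_bic: float = 0.0


def bic(fit: FitResult, trace: Trace) -> BicResult:
    """Exact BIC of a converged fit on its trace."""
    if trace.T < 2:
        raise ValueError("BIC requires a trace with N >= 2")
    k = count_free_parameters(fit.spec)
    value = -2.0 * fit.loglik + k * math.log(trace.T)
    return BicResult(fit.spec.name, float(fit.loglik), k, trace.T, float(value))


def select_model(fits: list[FitResult], trace: Trace) -> list[BicResult]:
    """Rank candidate fits of one trace by ascending BIC with Delta-BIC.

    All fits must belong to the same trace; at least one fit is required.
    """
    if not fits:
        raise ValueError("need at least one fit")
    ids = {f.trace_id for f in fits}
    if len(ids) != 1 or fits[0].trace_id != trace.id:
        raise ValueError(f"fits reference mismatched trace ids: {sorted(ids)} vs {trace.id!r}")
    results = [bic(f, trace) for f in fits]
    results.sort(key=lambda r: (r.bic, r.k, r.model_name))
    best = results[0].bic
    for r in results:
        r.delta_bic = r.bic - best
    return results
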