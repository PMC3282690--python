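"""JSON-serializable summaries of per-trace fits (the results-file schema).

One results file is a JSON object keyed by trace id; each entry holds the
model (name and structure), the fitted parameter values, log-likelihood, BIC,
convergence info and any confidence intervals.  Posteriors are not stored —
they are recomputable from the parameters and the trace.
"""

from __future__ import annotations

import numpy as np

from .confidence import CiResult
from .hmm import EmissionParams, FitResult, HmmParams
from .models import model_from_dict, model_to_dict
from .selection import bic
from .traces import Trace

__all__ = ["fit_to_dict", "fit_from_dict"]


def fit_to_dict(fit: FitResult, trace: Trace | None = None) -> dict:
    em = fit.params.emissions
    d = {
        "trace_id": fit.trace_id,
        "model": model_to_dict(fit.spec),
        "A": fit.params.A.tolist(),
        "mu": em.mu.tolist(),
        "sigma": None if em.sigma is None else em.sigma.tolist(),
        "pi0": fit.params.pi0.tolist(),
        "loglik": float(fit.loglik),
        "n_iter": fit.n_iter,
        "converged": bool(fit.converged),
        "degenerate": bool(fit.degenerate),
        "restarts_used": fit.restarts_used,
        "params": fit.param_dict(),
    }
    if trace is not None:
        d["bic"] = bic(fit, trace).bic
        d["N"] = trace.T
    if fit.cis:
        d["ci"] = {
            name: {
                "level": ci.level,
                "lo": ci.lo,
                "hi": ci.hi,
                "mode": ci.mode,
                "mle": ci.mle,
                "clipped_lo": ci.clipped_lo,
                "clipped_hi": ci.clipped_hi,
            }
            for name, ci in fit.cis.items()
        }
    return d


def fit_from_dict(d: dict) -> FitResult:
    spec = model_from_dict(d["model"])
    em = EmissionParams(
        families=tuple(spec.emissions.families),
        mu=np.array(d["mu"]),
        sigma=None if d.get("sigma") is None else np.array(d["sigma"]),
    )
    params = HmmParams(np.array(d["A"]), em, np.array(d["pi0"]))
    fit = FitResult(
        trace_id=d["trace_id"],
        spec=spec,
        params=params,
        loglik=float(d["loglik"]),
        n_iter=int(d.get("n_iter", 0)),
        converged=bool(d.get("converged", True)),
        posteriors=np.empty((0, spec.K)),
        restarts_used=int(d.get("restarts_used", 1)),
        degenerate=bool(d.get("degenerate", False)),
    )
    for name, ci in d.get("ci", {}).items():
        fit.cis[name] = CiResult(
            param=name,
            level=float(ci["level"]),
            lo=float(ci["lo"]),
            hi=float(ci["hi"]),
            mode=str(ci.get("mode", "conditional")),
            mle=float(ci.get("mle", float("nan"))),
            clipped_lo=bool(ci.get("clipped_lo", False)),
            clipped_hi=bool(ci.get("clipped_hi", False)),
        )
    return fit
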