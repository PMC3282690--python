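"""Baseline two-state threshold-crossing analysis.

Each time point is assigned to the low or high state by an intensity cutoff; a
transition is a change of side between consecutive points.  Completed dwell
times (the censored first and last segments are discarded) follow a geometric
law in discrete time, whose MLE is the reciprocal of the mean dwell — the
closed-form equivalent of fitting an exponential to the dwell-time histogram.
Traces with fewer than two transitions carry no usable kinetic information and
are flagged as excluded.

Applied to pure one-state noise with the threshold at the median, each point
falls on either side with probability one half, so the apparent per-step
transition probability converges to 0.5 — a diagnostic of fitting noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .traces import Trace

__all__ = ["ThresholdResult", "threshold_fit", "default_threshold"]


@dataclass
class ThresholdResult:
    threshold: float
    n_transitions: int
    dwells_state1: list[int] = field(default_factory=list)
    dwells_state2: list[int] = field(default_factory=list)
    p12_hat: float | None = None
    p21_hat: float | None = None
    excluded: bool = False
    reason: str | None = None

    def pooled_rate(self) -> float | None:
        """Reciprocal of the mean completed dwell time, both states pooled."""
        dwells = self.dwells_state1 + self.dwells_state2
        if not dwells:
            return None
        return 1.0 / float(np.mean(dwells))


def default_threshold(x: np.ndarray, seed: int = 0) -> float:
    """Midpoint of the two 1-d k-means centroids of the intensity histogram."""
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    km.fit(np.asarray(x, dtype=float).reshape(-1, 1))
    c = np.sort(km.cluster_centers_.ravel())
    return float(0.5 * (c[0] + c[1]))


def threshold_fit(
    trace: Trace, channel: int = 0, threshold: float | None = None
) -> ThresholdResult:
    """Two-state threshold analysis of one channel.

    State 1 is below (or at) the threshold, state 2 above.  Per-step transition
    probability estimates are ``p12 = 1/mean(completed state-1 dwells)`` and
    correspondingly for ``p21``.  Traces with fewer than two transitions are
    returned with ``excluded=True`` and no estimates.
    """
    if trace.T < 2:
        raise ValueError("threshold analysis requires at least 2 time steps")
    x = trace.channels[:, channel]
    if threshold is None:
        threshold = default_threshold(x)
    if not (np.min(x) <= threshold <= np.max(x)):
        raise ValueError(
            f"threshold {threshold} outside the data range [{np.min(x)}, {np.max(x)}]"
        )

    high = x > threshold
    changes = np.flatnonzero(high[1:] != high[:-1])
    n_transitions = int(changes.size)
    if n_transitions < 2:
        return ThresholdResult(
            threshold=float(threshold),
            n_transitions=n_transitions,
            excluded=True,
            reason="fewer than two transitions",
        )

    # segment boundaries: [0, change+1 ..., T]; drop censored first and last
    bounds = np.concatenate(([0], changes + 1, [trace.T]))
    dwells1: list[int] = []
    dwells2: list[int] = []
    for seg in range(1, len(bounds) - 2):
        start, stop = bounds[seg], bounds[seg + 1]
        (dwells2 if high[start] else dwells1).append(int(stop - start))

    p12 = 1.0 / float(np.mean(dwells1)) if dwells1 else None
    p21 = 1.0 / float(np.mean(dwells2)) if dwells2 else None
    return ThresholdResult(
        threshold=float(threshold),
        n_transitions=n_transitions,
        dwells_state1=dwells1,
        dwells_state2=dwells2,
        p12_hat=p12,
        p21_hat=p21,
    )
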