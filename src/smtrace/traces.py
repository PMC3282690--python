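"""Trace containers and the plain-text trace / results formats.

A *trace* is one molecule's multi-channel intensity time series recorded at a
fixed sampling interval until photobleaching.  Traces are stored in a
self-describing TSV: each trace starts with a ``#``-prefixed header block
(``trace_id``, ``dt``, ``channels``, optional ``meta.<key>`` lines) followed by
one tab-separated row of intensities per time step.  Multiple traces are
concatenated in one file.  Fit results live in a separate JSON file keyed by
trace id; the trace file is never mutated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Mapping

import numpy as np

__all__ = [
    "Trace",
    "TraceSet",
    "TraceFormatError",
    "read_traces",
    "write_traces",
    "select_traces",
    "read_results",
    "write_results",
]


class TraceFormatError(ValueError):
    """Raised when a trace file does not conform to the trace TSV format."""


@dataclass
class Trace:
    """One molecule's intensity time series.

    Parameters
    ----------
    id : str
        Unique identifier within a :class:`TraceSet`.
    dt : float
        Sampling interval in seconds per time step (constant within a trace).
    channels : ndarray, shape (T, C)
        Intensity values; rows are time steps, columns are channels
        (e.g. donor/acceptor photon counts).
    metadata : dict
        Free-form experiment annotations (experiment id, date, condition).
        The reserved key ``families`` (comma-separated, one entry per channel)
        declares the noise family of each channel; Poisson channels must be
        non-negative.
    """

    id: str
    dt: float
    channels: np.ndarray
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.channels, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("channels must be a T x C matrix with T >= 1, C >= 1")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"trace {self.id!r}: intensities must be finite")
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise ValueError(f"trace {self.id!r}: dt must be positive")
        self.channels = arr
        fams = self.metadata.get("families")
        if fams:
            families = [f.strip() for f in str(fams).split(",")]
            for c, fam in enumerate(families[: arr.shape[1]]):
                if fam == "poisson" and np.any(arr[:, c] < 0):
                    raise ValueError(
                        f"trace {self.id!r}: negative intensity in Poisson channel {c + 1}"
                    )

    @property
    def T(self) -> int:
        return self.channels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.channels.shape[1]


@dataclass
class TraceSet:
    """Ordered collection of traces with unique ids."""

    traces: list[Trace] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for tr in self.traces:
            if tr.id in seen:
                raise ValueError(f"duplicate trace id {tr.id!r}")
            seen.add(tr.id)

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterator[Trace]:
        return iter(self.traces)

    def __getitem__(self, key: int | str) -> Trace:
        if isinstance(key, str):
            for tr in self.traces:
                if tr.id == key:
                    return tr
            raise KeyError(key)
        return self.traces[key]

    def ids(self) -> list[str]:
        return [tr.id for tr in self.traces]


# ---------------------------------------------------------------------------
# TSV serialization

_ESCAPES = {"\\": "\\\\", "\t": "\\t", "\n": "\\n", "\r": "\\r", "=": "\\="}
_UNESCAPES = {"\\\\": "\\", "\\t": "\t", "\\n": "\n", "\\r": "\r", "\\=": "="}


def _escape(s: str) -> str:
    out = s.replace("\\", "\\\\")
    for raw, esc in _ESCAPES.items():
        if raw != "\\":
            out = out.replace(raw, esc)
    return out


def _unescape(s: str) -> str:
    out: list[str] = []
    i = 0
    while i < len(s):
        if s[i] == "\\" and i + 1 < len(s):
            out.append(_UNESCAPES.get(s[i : i + 2], s[i + 1]))
            i += 2
        else:
            out.append(s[i])
            i += 1
    return "".join(out)


def _split_unescaped(s: str, sep: str = "=") -> tuple[str, str]:
    """Split on the first separator not preceded by a backslash escape."""
    i = 0
    while i < len(s):
        if s[i] == "\\":
            i += 2
            continue
        if s[i] == sep:
            return s[:i], s[i + 1 :]
        i += 1
    raise ValueError(f"no unescaped {sep!r} in {s!r}")


def write_traces(trace_set: TraceSet, path: str | Path) -> None:
    """Write a TraceSet to the self-describing trace TSV format.

    Intensities are written with ``repr`` precision so that reading the file
    back reproduces them bit-exactly.
    """
    path = Path(path)
    with path.open("w") as fh:
        if trace_set.provenance:
            fh.write(f"# provenance={_escape(trace_set.provenance)}\n")
        for tr in trace_set:
            fh.write(f"# trace_id={_escape(tr.id)}\n")
            fh.write(f"# dt={tr.dt!r}\n")
            fh.write(f"# channels={tr.n_channels}\n")
            for key, value in tr.metadata.items():
                fh.write(f"# meta.{_escape(str(key))}={_escape(str(value))}\n")
            for row in tr.channels:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_traces(path: str | Path) -> TraceSet:
    """Read a trace TSV file written by :func:`write_traces`."""
    path = Path(path)
    traces: list[Trace] = []
    provenance = ""

    cur_id: str | None = None
    cur_dt: float | None = None
    cur_channels: int | None = None
    cur_meta: dict[str, str] = {}
    cur_rows: list[list[float]] = []

    def flush(lineno: int) -> None:
        nonlocal cur_id, cur_dt, cur_channels, cur_meta, cur_rows
        if cur_id is None:
            return
        if cur_dt is None or cur_channels is None:
            raise TraceFormatError(
                f"line {lineno}: trace {cur_id!r} header missing dt or channels"
            )
        if not cur_rows:
            raise TraceFormatError(f"line {lineno}: trace {cur_id!r} has no data rows")
        try:
            tr = Trace(cur_id, cur_dt, np.array(cur_rows), dict(cur_meta))
        except ValueError as exc:
            raise TraceFormatError(f"line {lineno}: {exc}") from exc
        traces.append(tr)
        cur_id, cur_dt, cur_channels, cur_meta, cur_rows = None, None, None, {}, []

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                # keep the value verbatim: only the single space after '#'
                # and whitespace around the key are cosmetic
                body = line[1:]
                if body.startswith(" "):
                    body = body[1:]
                try:
                    key, value = _split_unescaped(body)
                except ValueError as exc:
                    raise TraceFormatError(f"line {lineno}: malformed header {line!r}") from exc
                key = key.strip()
                if key == "provenance":
                    provenance = _unescape(value)
                elif key == "trace_id":
                    flush(lineno)
                    cur_id = _unescape(value)
                elif key == "dt":
                    cur_dt = float(value)
                elif key == "channels":
                    cur_channels = int(value)
                elif key.startswith("meta."):
                    cur_meta[_unescape(key[5:])] = _unescape(value)
                else:
                    raise TraceFormatError(f"line {lineno}: unknown header key {key!r}")
            else:
                if cur_id is None:
                    raise TraceFormatError(f"line {lineno}: data row before any trace header")
                values = line.split("\t")
                if cur_channels is not None and len(values) != cur_channels:
                    raise TraceFormatError(
                        f"line {lineno}: expected {cur_channels} columns, got {len(values)}"
                    )
                try:
                    cur_rows.append([float(v) for v in values])
                except ValueError as exc:
                    raise TraceFormatError(f"line {lineno}: non-numeric intensity") from exc
        flush(lineno=-1)

    seen: set[str] = set()
    for tr in traces:
        if tr.id in seen:
            raise TraceFormatError(f"duplicate trace id {tr.id!r}")
        seen.add(tr.id)
    return TraceSet(traces, provenance=provenance)


# ---------------------------------------------------------------------------
# Selection

Criteria = Callable[[Trace, Mapping[str, float] | None], bool] | Mapping[str, object]


def select_traces(
    trace_set: TraceSet,
    criteria: Criteria,
    fits: Mapping[str, Mapping[str, float]] | None = None,
) -> TraceSet:
    """Return the subset of traces satisfying all criteria, preserving order.

    ``criteria`` is either a callable ``(trace, fit_params) -> bool`` or a
    mapping from key to a required value or a closed ``(lo, hi)`` interval.
    Keys are looked up first in trace metadata, then in the per-trace fit
    parameter mapping ``fits[trace.id]`` (e.g. ``{"k12": 0.12}``).  An unknown
    key raises ``KeyError`` naming it.  The input set is not modified.
    """
    fits = fits or {}
    selected: list[Trace] = []
    for tr in trace_set:
        fit = fits.get(tr.id)
        if callable(criteria):
            keep = bool(criteria(tr, fit))
        else:
            keep = True
            for key, want in criteria.items():
                if key in tr.metadata:
                    have: object = tr.metadata[key]
                elif fit is not None and key in fit:
                    have = fit[key]
                else:
                    raise KeyError(
                        f"unknown selection key {key!r} (trace {tr.id!r})"
                    )
                if isinstance(want, tuple) and len(want) == 2:
                    lo, hi = want
                    if not (lo <= float(have) <= hi):
                        keep = False
                        break
                elif isinstance(want, (int, float)) and not isinstance(want, bool):
                    if float(have) != float(want):
                        keep = False
                        break
                else:
                    if str(have) != str(want):
                        keep = False
                        break
        if keep:
            selected.append(tr)
    return TraceSet(list(selected), provenance=trace_set.provenance)


# ---------------------------------------------------------------------------
# Results JSON

def write_results(results: Mapping[str, object], path: str | Path) -> None:
    """Write per-trace fit results (one JSON object keyed by trace id)."""
    Path(path).write_text(json.dumps(results, indent=2, sort_keys=True))


def read_results(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
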