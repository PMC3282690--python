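"""Candidate kinetic + emission model specifications.

A :class:`ModelSpec` describes a hidden Markov model to be fitted: the number
of hidden states, which directed transitions are allowed, the noise family of
each observation channel (Poisson or Gaussian), optional emission ties (states
constrained to share emission parameters), and an optional detailed-balance
(thermodynamic closure) constraint on the transition matrix.

Discrete-time transition probabilities can be converted to continuous-time
rate constants either approximately (division by the sampling interval) or
through the matrix logarithm of the full transition matrix.

State labels are 1-based in files, parameter names and reporting (``k12`` is
the transition probability from state 1 to state 2), 0-based in arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import scipy.linalg
import yaml

__all__ = [
    "EmissionSpec",
    "Topology",
    "ModelSpec",
    "PARAMS_PER_FAMILY",
    "count_free_parameters",
    "prob_to_rate",
    "matrix_prob_to_rate",
    "validate_model",
    "builtin_models",
    "load_model",
    "save_model",
]

PARAMS_PER_FAMILY = {"poisson": 1, "gaussian": 2}


@dataclass(frozen=True)
class Topology:
    """Allowed directed transitions among K hidden states.

    Self-transitions are implicit: the diagonal of the transition matrix
    absorbs whatever probability the allowed off-diagonal edges do not use.
    """

    K: int
    edges: frozenset[tuple[int, int]] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))

    def out_edges(self, i: int) -> list[tuple[int, int]]:
        return sorted(e for e in self.edges if e[0] == i)

    def undirected_edges(self) -> set[frozenset[int]]:
        return {frozenset(e) for e in self.edges}

    def mask(self) -> np.ndarray:
        """Boolean K x K mask of allowed entries (diagonal always allowed)."""
        m = np.eye(self.K, dtype=bool)
        for i, j in self.edges:
            m[i, j] = True
        return m

    def cycle_rank(self) -> int:
        """Number of independent undirected cycles (E - V + components)."""
        parent = list(range(self.K))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        und = self.undirected_edges()
        for e in und:
            a, b = sorted(e)
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
        components = len({find(i) for i in range(self.K)})
        return len(und) - self.K + components


@dataclass(frozen=True)
class EmissionSpec:
    """Per-channel noise families and emission ties.

    ``tie_groups[c]`` is a partition of the state set for channel ``c``; states
    in one group share emission parameters (used when multiple states produce
    identical signals).  ``None`` means every state has its own parameters.
    """

    families: tuple[str, ...]
    tie_groups: tuple[tuple[tuple[int, ...], ...], ...] | None = None

    @property
    def n_channels(self) -> int:
        return len(self.families)

    def groups_for(self, channel: int, K: int) -> tuple[tuple[int, ...], ...]:
        if self.tie_groups is None:
            return tuple((s,) for s in range(K))
        return self.tie_groups[channel]


@dataclass(frozen=True)
class ModelSpec:
    name: str
    topology: Topology
    emissions: EmissionSpec
    detailed_balance: bool = False

    @property
    def K(self) -> int:
        return self.topology.K

    @property
    def n_channels(self) -> int:
        return self.emissions.n_channels


def validate_model(spec: ModelSpec) -> list[str]:
    """Return a list of human-readable invariant violations (empty if valid)."""
    violations: list[str] = []
    K = spec.topology.K
    if K < 1:
        violations.append(f"state count must be >= 1, got {K}")
    for i, j in sorted(spec.topology.edges):
        if i == j:
            violations.append(f"self-edge ({i + 1},{j + 1}) not allowed (implicit)")
        if not (0 <= i < K and 0 <= j < K):
            violations.append(f"edge ({i + 1},{j + 1}) references invalid state")
    if spec.detailed_balance:
        for i, j in sorted(spec.topology.edges):
            if (j, i) not in spec.topology.edges:
                violations.append(
                    f"detailed balance requires reversible edges: ({i + 1},{j + 1}) "
                    f"present but ({j + 1},{i + 1}) missing"
                )
    for c, fam in enumerate(spec.emissions.families):
        if fam not in PARAMS_PER_FAMILY:
            violations.append(f"channel {c + 1}: unknown emission family {fam!r}")
    if spec.emissions.tie_groups is not None:
        if len(spec.emissions.tie_groups) != spec.emissions.n_channels:
            violations.append("tie_groups must have one partition per channel")
        else:
            for c, groups in enumerate(spec.emissions.tie_groups):
                states = sorted(s for g in groups for s in g)
                if states != list(range(K)):
                    violations.append(
                        f"channel {c + 1}: tie groups do not partition the state set"
                    )
    return violations


def count_free_parameters(spec: ModelSpec, n_channels: int | None = None) -> int:
    """Number of free parameters k entering the BIC.

    Kinetic parameters: one per allowed directed edge, minus one per
    independent undirected cycle when detailed balance is imposed (Kolmogorov
    criterion; tree topologies lose nothing).  Emission parameters: one
    (Poisson mean) or two (Gaussian mean and sd) per tie group per channel.
    The initial state distribution is the stationary distribution of the
    transition matrix, not a free parameter.
    """
    if n_channels is None:
        n_channels = spec.n_channels
    k_kinetic = len(spec.topology.edges)
    if spec.detailed_balance:
        k_kinetic -= spec.topology.cycle_rank()
    k_emission = 0
    for c in range(n_channels):
        fam = spec.emissions.families[c]
        groups = spec.emissions.groups_for(c, spec.K)
        k_emission += len(groups) * PARAMS_PER_FAMILY[fam]
    return k_kinetic + k_emission


# ---------------------------------------------------------------------------
# Discrete-time probability -> continuous-time rate conversion

def prob_to_rate(p: float, dt: float) -> float:
    """Approximate rate constant (1/s): transition probability per step / dt."""
    if not (0 <= p < 1):
        raise ValueError(f"transition probability must be in [0, 1), got {p}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    return p / dt


def matrix_prob_to_rate(A: np.ndarray, dt: float, tol: float = 1e-8) -> np.ndarray:
    """Continuous-time generator G = log(A)/dt via the matrix logarithm.

    The result is a valid generator only when the principal matrix logarithm
    has non-negative off-diagonal entries (embeddable chain); otherwise a
    ``ValueError`` is raised.  Agrees with :func:`prob_to_rate` to first order
    for small off-diagonal probabilities.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if dt <= 0:
        raise ValueError("dt must be positive")
    G = scipy.linalg.logm(A)
    if np.max(np.abs(G.imag)) > tol:
        raise ValueError("matrix logarithm is not real: no valid generator")
    G = G.real / dt
    off = G - np.diag(np.diag(G))
    if np.min(off) < -tol:
        raise ValueError("matrix logarithm has negative off-diagonal rates: no valid generator")
    off = np.clip(off, 0.0, None)
    G = off - np.diag(off.sum(axis=1))
    return G


# ---------------------------------------------------------------------------
# Built-in model menu and serialization

def _full_edges(K: int) -> frozenset[tuple[int, int]]:
    return frozenset((i, j) for i in range(K) for j in range(K) if i != j)


def _chain_edges(K: int) -> frozenset[tuple[int, int]]:
    edges: set[tuple[int, int]] = set()
    for i in range(K - 1):
        edges.add((i, i + 1))
        edges.add((i + 1, i))
    return frozenset(edges)


def builtin_models(n_channels: int = 1, family: str = "poisson") -> dict[str, ModelSpec]:
    """The standard candidate menu: 1, 2, 3-linear, 3-cycle, 3-thermo, 4-state.

    3-thermo shares the 3-cycle topology but imposes detailed balance and so
    has exactly one fewer free parameter.  The 4-state candidate is a linear
    chain of distinct emission levels.
    """
    fams = tuple([family] * n_channels)

    def em() -> EmissionSpec:
        return EmissionSpec(families=fams)

    return {
        "1-state": ModelSpec("1-state", Topology(1), em()),
        "2-state": ModelSpec("2-state", Topology(2, _full_edges(2)), em()),
        "3-linear": ModelSpec("3-linear", Topology(3, _chain_edges(3)), em()),
        "3-cycle": ModelSpec("3-cycle", Topology(3, _full_edges(3)), em()),
        "3-thermo": ModelSpec(
            "3-thermo", Topology(3, _full_edges(3)), em(), detailed_balance=True
        ),
        "4-state": ModelSpec("4-state", Topology(4, _chain_edges(4)), em()),
    }


def model_to_dict(spec: ModelSpec) -> dict:
    d: dict = {
        "name": spec.name,
        "K": spec.K,
        "edges": [[i + 1, j + 1] for i, j in sorted(spec.topology.edges)],
        "detailed_balance": spec.detailed_balance,
        "channels": [{"family": f} for f in spec.emissions.families],
    }
    if spec.emissions.tie_groups is not None:
        for c, groups in enumerate(spec.emissions.tie_groups):
            d["channels"][c]["tie_groups"] = [[s + 1 for s in g] for g in groups]
    return d


def model_from_dict(d: dict) -> ModelSpec:
    K = int(d["K"])
    edges = frozenset((int(i) - 1, int(j) - 1) for i, j in d.get("edges", []))
    channels = d.get("channels", [{"family": "poisson"}])
    families = tuple(ch["family"] for ch in channels)
    tie_groups = None
    if any("tie_groups" in ch for ch in channels):
        tie_groups = tuple(
            tuple(
                tuple(s - 1 for s in g)
                for g in ch.get("tie_groups", [[s + 1] for s in range(K)])
            )
            for ch in channels
        )
    return ModelSpec(
        name=str(d.get("name", f"{K}-state")),
        topology=Topology(K, edges),
        emissions=EmissionSpec(families, tie_groups),
        detailed_balance=bool(d.get("detailed_balance", False)),
    )


def save_model(spec: ModelSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(model_to_dict(spec), sort_keys=False))


def load_model(path: str | Path) -> ModelSpec:
    spec = model_from_dict(yaml.safe_load(Path(path).read_text()))
    problems = validate_model(spec)
    if problems:
        raise ValueError("invalid model spec: " + "; ".join(problems))
    return spec
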