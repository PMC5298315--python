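"""Boolean network model: signed conjunction/disjunction rules and
synchronous dynamics.

Each node carries a binary state updated by a single rule

    v_i(t+1) = f_i(v_{i1}(t), ..., v_{ik}(t))

where f_i is either the AND or the OR of its inputs, each input taken
positively or negated (a signed literal), or a constant for input-free
nodes.  All nodes update synchronously from the same previous global
state.  Time is 1-based (t = 1..T): row 1 of a trajectory is the
initial condition and prediction quality is always assessed over rows
2..T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "Gate",
    "BooleanFunction",
    "BooleanNetwork",
    "Trajectory",
    "evaluate_function",
    "step",
    "simulate",
    "predict_one_step",
]


class Gate(str, Enum):
    AND = "AND"
    OR = "OR"
    CONSTANT = "CONST"


@dataclass(frozen=True)
class BooleanFunction:
    """Update rule of one node: signed regulators joined by AND or OR.

    ``regulators`` are node indices (a node may regulate itself);
    ``signs`` align with them, +1 for a plain literal and -1 for a
    negated one.  ``Gate.CONSTANT`` rules have no regulators and output
    ``constant_value`` regardless of the state.
    """

    regulators: tuple[int, ...]
    signs: tuple[int, ...]
    gate: Gate
    constant_value: int = 0

    def __post_init__(self):
        object.__setattr__(self, "regulators", tuple(int(r) for r in self.regulators))
        object.__setattr__(self, "signs", tuple(int(s) for s in self.signs))
        if len(self.signs) != len(self.regulators):
            raise ValueError("signs and regulators must have equal length")
        if len(set(self.regulators)) != len(self.regulators):
            raise ValueError("regulator indices must be unique")
        if any(s not in (-1, 1) for s in self.signs):
            raise ValueError("signs must be +1 or -1")
        if (self.gate is Gate.CONSTANT) != (len(self.regulators) == 0):
            raise ValueError("CONSTANT rules and only CONSTANT rules have no regulators")
        if self.constant_value not in (0, 1):
            raise ValueError("constant_value must be 0 or 1")

    @classmethod
    def constant(cls, value: int) -> "BooleanFunction":
        return cls((), (), Gate.CONSTANT, int(value))


@dataclass
class BooleanNetwork:
    """N nodes, one :class:`BooleanFunction` each."""

    functions: list[BooleanFunction]
    node_names: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.node_names is None:
            self.node_names = [f"G{i + 1}" for i in range(len(self.functions))]
        if len(self.node_names) != len(self.functions):
            raise ValueError("node_names and functions must have equal length")
        n = self.n_nodes
        for i, f in enumerate(self.functions):
            if any(r < 0 or r >= n for r in f.regulators):
                raise ValueError(f"rule for node {i} references a regulator index >= {n}")

    @property
    def n_nodes(self) -> int:
        return len(self.functions)

    @property
    def edges(self) -> set[tuple[int, int, int]]:
        """Signed edge set {(regulator, target, sign)} implied by the rules."""
        out: set[tuple[int, int, int]] = set()
        for target, f in enumerate(self.functions):
            for r, s in zip(f.regulators, f.signs):
                out.add((r, target, s))
        return out

    def in_degree(self, node: int) -> int:
        return len(self.functions[node].regulators)


@dataclass
class Trajectory:
    """T x N binary state matrix; row t holds the global state at time t."""

    states: np.ndarray
    node_names: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.states = np.asarray(self.states)
        if self.states.ndim != 2:
            raise ValueError("states must be a T x N matrix")
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("trajectory entries must be 0 or 1")
        self.states = self.states.astype(np.int8)
        if self.node_names is None:
            self.node_names = [f"G{i + 1}" for i in range(self.states.shape[1])]
        if len(self.node_names) != self.states.shape[1]:
            raise ValueError("node_names must match the number of columns")

    @property
    def T(self) -> int:
        return self.states.shape[0]

    @property
    def n_genes(self) -> int:
        return self.states.shape[1]


def evaluate_function(f: BooleanFunction, state: Sequence[int]) -> int:
    """Evaluate one rule on a global state vector."""
    if f.gate is Gate.CONSTANT:
        return f.constant_value
    state = np.asarray(state)
    if state.ndim != 1 or state.size <= max(f.regulators):
        raise ValueError("state vector too short for this rule's regulators")
    lits = [state[r] if s == 1 else 1 - state[r] for r, s in zip(f.regulators, f.signs)]
    if f.gate is Gate.AND:
        return int(all(lits))
    return int(any(lits))


def step(net: BooleanNetwork, state: Sequence[int]) -> np.ndarray:
    """One synchronous update: every node reads the same input state."""
    state = np.asarray(state)
    if state.shape != (net.n_nodes,):
        raise ValueError(f"state must have length {net.n_nodes}")
    return np.array([evaluate_function(f, state) for f in net.functions], dtype=np.int8)


def simulate(net: BooleanNetwork, initial_state: Sequence[int], T: int) -> Trajectory:
    """Free-running synchronous simulation for T steps (row 1 = initial state)."""
    if T < 1:
        raise ValueError("T must be >= 1")
    states = np.empty((T, net.n_nodes), dtype=np.int8)
    states[0] = np.asarray(initial_state, dtype=np.int8)
    for t in range(1, T):
        states[t] = step(net, states[t - 1])
    return Trajectory(states, list(net.node_names))


def predict_one_step(net: BooleanNetwork, observed: Trajectory) -> Trajectory:
    """Teacher-forced prediction: row t is one step from the OBSERVED row t-1.

    Row 1 copies the observation (there is nothing to predict it from).
    This is the prediction mode under which gene-wise dynamics
    consistency is defined and optimised during inference; free-running
    prediction is available via :func:`simulate` on the observed initial
    state.
    """
    if observed.T < 2:
        raise ValueError("observed trajectory must have T >= 2")
    states = np.empty_like(observed.states)
    states[0] = observed.states[0]
    for t in range(1, observed.T):
        states[t] = step(net, observed.states[t - 1])
    return Trajectory(states, list(observed.node_names))
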