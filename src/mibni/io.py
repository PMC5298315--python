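"""Readers and writers for the package's exchange formats.

Matrices (Boolean trajectories and real-valued expression) travel as
TSV: a header row with a time-column label followed by gene names, then
one row per time point whose first cell is the time index.  Edge lists
are 3-column TSV (regulator, target, sign in {+,-}) with a header.
Rule-bearing networks are JSON, since no common bioinformatics format
encodes signed conjunction/disjunction rules.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .boolnet import BooleanFunction, BooleanNetwork, Gate, Trajectory
from .discretize import ExpressionMatrix

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_expression",
    "write_expression",
    "read_edges",
    "write_edges",
    "network_from_edges",
    "read_network",
    "write_network",
]

_SIGN_TO_STR = {1: "+", -1: "-"}
_STR_TO_SIGN = {"+": 1, "-": -1, "+1": 1, "-1": -1, "1": 1}


def _read_matrix(path) -> tuple[list[str], list[str], list[list[str]]]:
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    rows = [r for r in rows if r and any(c.strip() for c in r)]
    if len(rows) < 2:
        raise ValueError(f"{path}: need a header row and at least one data row")
    header = [c.strip() for c in rows[0]]
    names = header[1:]
    width = len(header)
    time_labels, cells = [], []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ValueError(f"{path}: row {i} has {len(row)} fields, expected {width}")
        time_labels.append(row[0].strip())
        cells.append([c.strip() for c in row[1:]])
    return names, time_labels, cells


def read_trajectory(path) -> Trajectory:
    """Read a Boolean T x N trajectory TSV; rejects non-0/1 cells."""
    names, _, cells = _read_matrix(path)
    data = np.empty((len(cells), len(names)), dtype=np.int8)
    for i, row in enumerate(cells):
        for j, c in enumerate(row):
            if c not in ("0", "1"):
                raise ValueError(
                    f"{path}: non-binary value {c!r} at data row {i + 1}, gene {names[j]!r}"
                )
            data[i, j] = int(c)
    return Trajectory(data, names)


def write_trajectory(traj: Trajectory, path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["t", *traj.node_names])
        for t in range(traj.T):
            w.writerow([t + 1, *traj.states[t].tolist()])


def read_expression(path) -> ExpressionMatrix:
    """Read a real-valued T x N expression TSV."""
    names, time_labels, cells = _read_matrix(path)
    data = np.empty((len(cells), len(names)), dtype=float)
    for i, row in enumerate(cells):
        for j, c in enumerate(row):
            try:
                data[i, j] = float(c)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {c!r} at data row {i + 1}, gene {names[j]!r}"
                ) from None
    return ExpressionMatrix(data, names, time_labels)


def write_expression(x: ExpressionMatrix, path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["t", *x.node_names])
        for t in range(x.values.shape[0]):
            w.writerow([x.time_labels[t], *(repr(float(v)) for v in x.values[t])])


def read_edges(path) -> list[tuple[str, str, int]]:
    """Read a signed edge list TSV; returns (regulator, target, sign) triples."""
    path = Path(path)
    with path.open(newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and any(c.strip() for c in r)]
    if not rows:
        raise ValueError(f"{path}: empty edge file (header expected)")
    edges = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) < 3:
            raise ValueError(f"{path}: row {i} needs 3 fields (regulator, target, sign)")
        reg, tgt, sgn = (c.strip() for c in row[:3])
        if sgn not in _STR_TO_SIGN:
            raise ValueError(f"{path}: row {i}: sign must be one of {sorted(_STR_TO_SIGN)}")
        edges.append((reg, tgt, _STR_TO_SIGN[sgn]))
    return edges


def write_edges(net: BooleanNetwork, path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["regulator", "target", "sign"])
        for r, t, s in sorted(net.edges):
            w.writerow([net.node_names[r], net.node_names[t], _SIGN_TO_STR[s]])


def network_from_edges(
    edges: list[tuple[str, str, int]], node_names: list[str]
) -> BooleanNetwork:
    """Structure-only network from an edge list (for structural evaluation).

    Each target's regulators are joined by an OR gate purely as a
    placeholder; the rules of such a network are not meaningful for
    simulation unless the edge list really came from OR rules.
    """
    index = {n: i for i, n in enumerate(node_names)}
    incoming: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(node_names))}
    for reg, tgt, sign in edges:
        for name in (reg, tgt):
            if name not in index:
                raise ValueError(f"edge references unknown gene {name!r}")
        incoming[index[tgt]].append((index[reg], sign))
    functions = []
    for i in range(len(node_names)):
        regs = sorted(incoming[i])
        if not regs:
            functions.append(BooleanFunction.constant(0))
        else:
            functions.append(
                BooleanFunction(
                    tuple(r for r, _ in regs), tuple(s for _, s in regs), Gate.OR
                )
            )
    return BooleanNetwork(functions, list(node_names))


def write_network(net: BooleanNetwork, path) -> None:
    doc = {
        "nodes": list(net.node_names),
        "rules": [
            {
                "target": net.node_names[i],
                "gate": f.gate.value,
                "inputs": [
                    {"name": net.node_names[r], "sign": _SIGN_TO_STR[s]}
                    for r, s in zip(f.regulators, f.signs)
                ],
                "const": f.constant_value,
            }
            for i, f in enumerate(net.functions)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_network(path) -> BooleanNetwork:
    doc = json.loads(Path(path).read_text())
    names = list(doc["nodes"])
    index = {n: i for i, n in enumerate(names)}
    functions: list[BooleanFunction | None] = [None] * len(names)
    for rule in doc["rules"]:
        tgt = rule["target"]
        if tgt not in index:
            raise ValueError(f"{path}: rule targets unknown gene {tgt!r}")
        gate = Gate(rule["gate"])
        if gate is Gate.CONSTANT:
            f = BooleanFunction.constant(int(rule.get("const", 0)))
        else:
            regs, signs = [], []
            for inp in rule["inputs"]:
                if inp["name"] not in index:
                    raise ValueError(f"{path}: rule input names unknown gene {inp['name']!r}")
                regs.append(index[inp["name"]])
                signs.append(_STR_TO_SIGN[inp["sign"]])
            f = BooleanFunction(tuple(regs), tuple(signs), gate)
        functions[index[tgt]] = f
    for i, f in enumerate(functions):
        if f is None:
            raise ValueError(f"{path}: no rule given for gene {names[i]!r}")
    return BooleanNetwork(functions, names)  # type: ignore[arg-type]
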