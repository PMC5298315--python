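"""Synthetic benchmark generator: scale-free random Boolean networks,
random signed AND/OR rules, random initial states, and the benchmark
driver that ties generation, inference and evaluation together.

The protocol emulated: directed networks of |V| nodes and exactly
2*|V| edges grown by Barabasi-Albert preferential attachment, each node
given an update rule whose gate is drawn uniformly from {AND, OR} and
whose regulator signs are drawn uniformly from {+1, -1}; trajectories
of length T = |V| + 10 started from i.i.d. Bernoulli(0.5) initial
states and advanced by synchronous free-running simulation.  Nodes
with no incoming edge simply hold their (random) initial value, i.e.
they carry a constant rule.

All-positive rules are exposed via ``signs='positive'`` but are not the
default: without negative literals random networks collapse to a fixed
point almost immediately, leaving no dynamical signal to infer from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boolnet import BooleanFunction, BooleanNetwork, Gate, Trajectory, simulate
from .evaluate import evaluate_inference
from .inference import DEFAULT_MAX_K, infer_network

__all__ = [
    "BenchmarkSpec",
    "generate_ba_network",
    "generate_trajectory",
    "run_benchmark",
    "summarize_by_degree",
    "summarize_by_size",
]

_EDGE_FACTOR = 2  # |A| = 2 * |V|
_T_EXTRA = 10  # T = |V| + 10


def _ba_pairs(n: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Exactly 2n distinct node pairs grown by preferential attachment.

    Growth phase: a 3-node star seed, then each new node attaches m = 2
    edges to distinct existing nodes with probability proportional to
    current degree (repeated-nodes sampling).  That yields 2n - 4 pairs;
    four more pairs are then added between existing nodes, both
    endpoints drawn degree-proportionally, rejecting duplicates.
    """
    pairs: list[tuple[int, int]] = [(0, 1), (0, 2)]
    repeated = [0, 1, 0, 2]  # one entry per edge endpoint
    for new in range(3, n):
        targets: set[int] = set()
        while len(targets) < 2:
            targets.add(int(rng.choice(repeated)))
        for t in sorted(targets):
            pairs.append((t, new))
            repeated.extend([t, new])
    return pairs


def generate_ba_network(n: int, seed, signs: str = "random") -> BooleanNetwork:
    """Random scale-free Boolean network with n nodes and exactly 2n edges."""
    if n < 3:
        raise ValueError("need n >= 3")
    if signs not in ("random", "positive"):
        raise ValueError("signs must be 'random' or 'positive'")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    struct_ss, rule_ss = ss.spawn(2)
    rng = np.random.default_rng(struct_ss)

    pairs = _ba_pairs(n, rng)
    # orient growth edges: old -> new, then flip each with probability 1/2
    edges: set[tuple[int, int]] = set()
    for u, v in pairs:
        edges.add((v, u) if rng.random() < 0.5 else (u, v))
    # top up to exactly 2n directed edges, endpoints degree-proportional
    degree = np.zeros(n)
    for u, v in edges:
        degree[u] += 1
        degree[v] += 1
    while len(edges) < _EDGE_FACTOR * n:
        p = degree + 1e-9
        u, v = rng.choice(n, size=2, replace=False, p=p / p.sum())
        e = (int(u), int(v))
        if e not in edges:
            edges.add(e)
            degree[u] += 1
            degree[v] += 1

    rule_rng = np.random.default_rng(rule_ss)
    incoming: list[list[int]] = [[] for _ in range(n)]
    for u, v in sorted(edges):
        incoming[v].append(u)
    functions = []
    for i in range(n):
        regs = sorted(incoming[i])
        if not regs:
            functions.append(BooleanFunction.constant(int(rule_rng.integers(2))))
            continue
        gate = Gate.AND if rule_rng.random() < 0.5 else Gate.OR
        if signs == "random":
            sgn = tuple(int(s) for s in rule_rng.choice([-1, 1], size=len(regs)))
        else:
            sgn = (1,) * len(regs)
        functions.append(BooleanFunction(tuple(regs), sgn, gate))
    return BooleanNetwork(functions)


def generate_trajectory(net: BooleanNetwork, T: int, seed) -> Trajectory:
    """Free-running trajectory from a random Bernoulli(0.5) initial state.

    Input-free (constant-rule) nodes start at their held value so the
    whole trajectory, initial row included, is consistent with the
    generating network.
    """
    if T < 2:
        raise ValueError("need T >= 2")
    rng = np.random.default_rng(seed)
    init = rng.integers(0, 2, size=net.n_nodes).astype(np.int8)
    for i, f in enumerate(net.functions):
        if f.gate is Gate.CONSTANT:
            init[i] = f.constant_value
    return simulate(net, init, T)


@dataclass
class BenchmarkSpec:
    """Conditions for one benchmark sweep."""

    sizes: tuple[int, ...] = (10, 20, 30)
    replicates: int = 30
    t_extra: int = _T_EXTRA  # trajectory length is |V| + t_extra
    seed: int = 0
    signs: str = "random"
    max_k: int = DEFAULT_MAX_K

    def __post_init__(self):
        if any(s < 3 for s in self.sizes) or self.replicates < 1:
            raise ValueError("sizes must be >= 3 and replicates >= 1")


def run_benchmark(spec: BenchmarkSpec) -> pd.DataFrame:
    """Generate, infer and evaluate; one row per gene.

    Per-gene columns record the true in-degree class D and the achieved
    gene-wise consistency; network-level metrics are repeated on each of
    the network's rows for convenient aggregation.
    """
    ss = np.random.SeedSequence(spec.seed)
    rows = []
    for size in spec.sizes:
        for rep in range(spec.replicates):
            net_ss, traj_ss = ss.spawn(2)
            truth = generate_ba_network(size, net_ss, signs=spec.signs)
            traj = generate_trajectory(truth, size + spec.t_extra, traj_ss)
            inferred, results = infer_network(traj, K=spec.max_k)
            with warnings.catch_warnings():
                # an all-constant replicate legitimately infers no edges;
                # the undefined-precision flag is expected there
                warnings.simplefilter("ignore", UserWarning)
                report = evaluate_inference(truth, inferred, traj)
            for i, res in enumerate(results):
                rows.append(
                    {
                        "size": size,
                        "replicate": rep,
                        "gene": traj.node_names[i],
                        "in_degree": truth.in_degree(i),
                        "k_used": res.k_used,
                        "consistency": report.per_gene_consistency[i],
                        "dynamics_accuracy": report.dynamics_accuracy,
                        "structural_accuracy": report.structural_accuracy,
                        "precision": report.precision,
                        "recall": report.recall,
                    }
                )
    return pd.DataFrame(rows)


def summarize_by_degree(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and s.d. of gene-wise consistency per true in-degree class."""
    return (
        records.groupby("in_degree")["consistency"].agg(["mean", "std", "count"]).reset_index()
    )


def summarize_by_size(records: pd.DataFrame) -> pd.DataFrame:
    """Per-size mean and s.d. of the network-level dynamics accuracy."""
    per_net = records.groupby(["size", "replicate"]).agg(
        dynamics_accuracy=("dynamics_accuracy", "first"),
        structural_accuracy=("structural_accuracy", "first"),
    )
    return per_net.groupby("size").agg(["mean", "std"]).reset_index()
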