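"""Built-in small datasets for worked examples and workflow tests.

Both datasets here are SYNTHETIC stand-ins constructed by this package.
They mirror the *shape* of two classic benchmarks — a 10-gene bacterial
regulatory cascade observed over 21 time points, and a 10-node fission
yeast cell-cycle network observed over 10 time points — but they are
generated by code below, not transcribed from any published
supplementary data.  Results obtained on them characterise this
implementation, not the published benchmarks.
"""

from __future__ import annotations

import numpy as np

from .boolnet import BooleanFunction, BooleanNetwork, Gate, Trajectory, simulate

__all__ = ["synthetic_ecoli_like", "synthetic_yeast_cellcycle"]


def synthetic_ecoli_like() -> tuple[Trajectory, BooleanNetwork]:
    """Synthetic 10-gene, 11-edge cascade with a 21-step noisy trajectory.

    A two-gene negative-feedback oscillator drives a signed cascade;
    the free-running Boolean trajectory is then corrupted with 2%
    i.i.d. observation flips (fixed seed), emulating the binarization
    error that real-valued expression data carries after thresholding.
    Returns (observed trajectory, truth network).
    """
    AND, OR = Gate.AND, Gate.OR
    functions = [
        BooleanFunction((1,), (-1,), OR),          # G1 = NOT G2
        BooleanFunction((0,), (1,), OR),           # G2 = G1
        BooleanFunction((1,), (1,), OR),           # G3 = G2
        BooleanFunction((1, 2), (1, -1), AND),     # G4 = G2 AND NOT G3
        BooleanFunction((2,), (1,), OR),           # G5 = G3
        BooleanFunction((3, 4), (1, 1), OR),       # G6 = G4 OR G5
        BooleanFunction((5,), (-1,), OR),          # G7 = NOT G6
        BooleanFunction((6,), (1,), OR),           # G8 = G7
        BooleanFunction((7,), (-1,), OR),          # G9 = NOT G8
        BooleanFunction.constant(1),               # G10 held on (input gene)
    ]
    truth = BooleanNetwork(functions)
    init = np.array([1, 0, 0, 0, 0, 0, 0, 0, 0, 1], dtype=np.int8)
    clean = simulate(truth, init, 21)
    rng = np.random.default_rng(7)
    noisy = clean.states ^ (rng.random(clean.states.shape) < 0.02).astype(np.int8)
    return Trajectory(noisy, list(truth.node_names)), truth


_YEAST_NODES = [
    "Start", "SK", "Cdc2/Cdc13", "Ste9", "Rum1",
    "Slp1", "Cdc2/Cdc13*", "Wee1/Mik1", "Cdc25", "PP",
]

# (regulator, target, sign): a 23-interaction signed wiring in the style
# of threshold Boolean models of the fission yeast cell cycle.
_YEAST_EDGES = [
    ("Start", "SK", 1),
    ("SK", "Ste9", -1),
    ("SK", "Rum1", -1),
    ("Cdc2/Cdc13", "Ste9", -1),
    ("Cdc2/Cdc13", "Rum1", -1),
    ("Cdc2/Cdc13", "Wee1/Mik1", -1),
    ("Cdc2/Cdc13", "Cdc25", 1),
    ("Ste9", "Cdc2/Cdc13", -1),
    ("Rum1", "Cdc2/Cdc13", -1),
    ("Slp1", "Cdc2/Cdc13", -1),
    ("Slp1", "Cdc2/Cdc13*", -1),
    ("Slp1", "PP", 1),
    ("Cdc2/Cdc13*", "Ste9", -1),
    ("Cdc2/Cdc13*", "Rum1", -1),
    ("Cdc2/Cdc13*", "Slp1", 1),
    ("Cdc2/Cdc13*", "Wee1/Mik1", -1),
    ("Cdc2/Cdc13*", "Cdc25", 1),
    ("Wee1/Mik1", "Cdc2/Cdc13*", -1),
    ("Cdc25", "Cdc2/Cdc13*", 1),
    ("PP", "Ste9", 1),
    ("PP", "Rum1", 1),
    ("PP", "Wee1/Mik1", 1),
    ("PP", "Cdc25", -1),
]

# nodes that decay to 0 when their weighted input sum is exactly zero
# (transiently active components); all others hold their state at zero sum
_YEAST_DECAY = {"Start", "SK", "Slp1", "PP"}

# activation thresholds: the basal kinase complex is on unless actively
# inhibited (theta = -0.5) while the starred high-activity form needs net
# positive drive (theta = +0.5); every other node switches around zero
_YEAST_THETA = {"Cdc2/Cdc13": -0.5, "Cdc2/Cdc13*": 0.5}


def _yeast_threshold_step(
    state: np.ndarray, W: np.ndarray, theta: np.ndarray, decay: np.ndarray
) -> np.ndarray:
    s = W.T @ state
    nxt = np.where(s > theta, 1, np.where(s < theta, 0, np.where(decay, 0, state)))
    return nxt.astype(np.int8)


def synthetic_yeast_cellcycle() -> tuple[Trajectory, BooleanNetwork]:
    """Synthetic fission-yeast-style cell-cycle sequence, 10 nodes x 10 steps.

    The truth wiring (23 signed interactions) drives majority-threshold
    dynamics — NOT the AND/OR rule class the inference method assumes —
    simulated from the G1+Start state.  This deliberately misspecified
    generator makes the dataset a hard, realistic workflow test.
    Returns (observed trajectory, truth network).

    The truth network object encodes only the wiring; its OR gates are
    structural placeholders and are not the generating dynamics.
    """
    idx = {n: i for i, n in enumerate(_YEAST_NODES)}
    W = np.zeros((10, 10))
    for reg, tgt, sign in _YEAST_EDGES:
        W[idx[reg], idx[tgt]] = sign
    decay = np.array([n in _YEAST_DECAY for n in _YEAST_NODES])
    theta = np.array([_YEAST_THETA.get(n, 0.0) for n in _YEAST_NODES])
    state = np.zeros(10, dtype=np.int8)
    for n in ("Start", "Ste9", "Rum1", "Wee1/Mik1"):
        state[idx[n]] = 1
    rows = [state]
    for _ in range(9):
        rows.append(_yeast_threshold_step(rows[-1], W, theta, decay))
    traj = Trajectory(np.vstack(rows), list(_YEAST_NODES))

    from .io import network_from_edges  # placed here to avoid an import cycle

    truth = network_from_edges(_YEAST_EDGES, list(_YEAST_NODES))
    return traj, truth
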