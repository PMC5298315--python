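"""Structural and dynamics performance metrics.

Structural metrics compare the inferred edge set against the ground
truth over the space of all N^2 ordered (regulator, target) pairs,
self-pairs included; by default an edge matches on the pair alone,
ignoring the regulation sign (a strict signed mode is available).
Dynamics accuracy is the mean over genes of the per-gene consistency
E(v, v') between observed and predicted trajectories over t = 2..T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .boolnet import BooleanNetwork, Trajectory, predict_one_step
from .inference import gene_wise_consistency

__all__ = [
    "EvaluationReport",
    "confusion_counts",
    "precision",
    "recall",
    "structural_accuracy",
    "dynamics_accuracy",
    "evaluate_inference",
]


@dataclass
class EvaluationReport:
    TP: int
    FP: int
    FN: int
    TN: int
    precision: float
    recall: float
    structural_accuracy: float
    per_gene_consistency: np.ndarray
    dynamics_accuracy: float


def _pair_set(net: BooleanNetwork, signed: bool) -> set:
    if signed:
        return set(net.edges)
    return {(r, t) for r, t, _ in net.edges}


def confusion_counts(
    truth: BooleanNetwork, inferred: BooleanNetwork, signed: bool = False
) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) over the N^2 ordered candidate pairs.

    With ``signed=True`` an edge must also match the regulation sign to
    count as a true positive; in that mode a pair inferred with the
    wrong sign counts as both a false positive and a false negative.
    """
    if truth.n_nodes != inferred.n_nodes or list(truth.node_names) != list(inferred.node_names):
        raise ValueError("truth and inferred networks must share the same node set")
    a = _pair_set(truth, signed)
    b = _pair_set(inferred, signed)
    tp = len(a & b)
    fp = len(b - a)
    fn = len(a - b)
    tn = truth.n_nodes ** 2 - tp - fp - fn
    return tp, fp, fn, tn


def precision(TP: int, FP: int) -> float:
    """TP / (TP + FP); 0 (with a warning) when nothing was predicted."""
    if TP + FP == 0:
        warnings.warn("precision undefined (no predicted edges); returning 0", stacklevel=2)
        return 0.0
    return TP / (TP + FP)


def recall(TP: int, FN: int) -> float:
    """TP / (TP + FN); 0 (with a warning) when the truth has no edges."""
    if TP + FN == 0:
        warnings.warn("recall undefined (no true edges); returning 0", stacklevel=2)
        return 0.0
    return TP / (TP + FN)


def structural_accuracy(TP: int, FP: int, FN: int, TN: int) -> float:
    return (TP + TN) / (TP + FP + FN + TN)


def dynamics_accuracy(observed: Trajectory, predicted: Trajectory) -> tuple[np.ndarray, float]:
    """Per-gene consistencies over t = 2..T and their unweighted mean."""
    if observed.states.shape != predicted.states.shape:
        raise ValueError("observed and predicted trajectories must have equal shape")
    if observed.T < 2:
        raise ValueError("need T >= 2 to evaluate dynamics")
    per_gene = np.array(
        [
            gene_wise_consistency(observed.states[1:, j], predicted.states[1:, j])
            for j in range(observed.n_genes)
        ]
    )
    return per_gene, float(per_gene.mean())


def evaluate_inference(
    truth: BooleanNetwork,
    inferred: BooleanNetwork,
    observed: Trajectory,
    signed: bool = False,
) -> EvaluationReport:
    """Full report: structural metrics plus teacher-forced dynamics accuracy."""
    tp, fp, fn, tn = confusion_counts(truth, inferred, signed=signed)
    predicted = predict_one_step(inferred, observed)
    per_gene, dyn = dynamics_accuracy(observed, predicted)
    return EvaluationReport(
        TP=tp,
        FP=fp,
        FN=fn,
        TN=tn,
        precision=precision(tp, fp),
        recall=recall(tp, fn),
        structural_accuracy=structural_accuracy(tp, fp, fn, tn),
        per_gene_consistency=per_gene,
        dynamics_accuracy=dyn,
    )
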