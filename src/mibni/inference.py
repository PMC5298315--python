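"""Core inference: mutual-information feature selection (MIFS), greedy
SWAP refinement, exhaustive signed-gate rule search, and the outer
k = 1..K loop applied gene by gene.

For each target gene the one-step-lagged problem is formed: the target
series is the gene's states at t = 2..T and every gene's states at
t = 1..T-1 (including the target's own, so self-loops are allowed) are
the candidate regulator series.  MIFS greedily picks k candidates by
relevance minus redundancy,

    S[1] = argmax_w I(v_O; w),
    S[j] = argmax_w I(v_O; w) - sum_{s in S} I(w; s),

then SWAP exchanges selected/unselected candidates whenever the
exchange strictly raises the best gene-wise consistency achievable by
any of the 2^(|S|+1) signed AND/OR rules over S.  k grows until a rule
predicts the target perfectly or k reaches the cap K (default 10).

A gene whose lagged target series is constant carries no dynamical
information about regulators; it gets a constant rule, no regulators,
and consistency 1 (the zero-entropy shortcut).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boolnet import BooleanFunction, BooleanNetwork, Gate, Trajectory
from .infotheory import entropy, mutual_information

__all__ = [
    "LaggedProblem",
    "InferenceResult",
    "make_lagged_problem",
    "gene_wise_consistency",
    "search_update_rule",
    "mifs_select",
    "swap_improve",
    "infer_gene",
    "infer_network",
    "DEFAULT_MAX_K",
]

DEFAULT_MAX_K = 10  # cap on the number of regulators searched per gene


@dataclass
class LaggedProblem:
    """One gene's single-step-lag supervised problem.

    ``target`` has length T-1 (states at t = 2..T); ``candidates`` is an
    (N, T-1) matrix of every gene's states at t = 1..T-1, the target's
    own lagged series included.
    """

    target: np.ndarray
    candidates: np.ndarray
    target_index: int

    def __post_init__(self):
        self.target = np.asarray(self.target, dtype=np.int8)
        self.candidates = np.asarray(self.candidates, dtype=np.int8)
        if self.target.ndim != 1 or self.candidates.ndim != 2:
            raise ValueError("target must be 1-D and candidates 2-D")
        if self.candidates.shape[1] != self.target.size:
            raise ValueError("candidates and target must share length T-1")

    @property
    def n_candidates(self) -> int:
        return self.candidates.shape[0]


@dataclass
class InferenceResult:
    """Outcome of inference for one gene."""

    target_index: int
    selected: tuple[int, ...]
    rule: BooleanFunction
    consistency: float
    k_used: int


def make_lagged_problem(traj: Trajectory, target_index: int) -> LaggedProblem:
    if traj.T < 2:
        raise ValueError("trajectory must have T >= 2")
    target = traj.states[1:, target_index]
    candidates = traj.states[:-1, :].T
    return LaggedProblem(target, candidates, target_index)


def gene_wise_consistency(observed, predicted) -> float:
    """Fraction of positions where the prediction matches the observation.

    This is the per-gene dynamics consistency E(v, v') = sum_t
    I(v(t) = v'(t)) / (T - 1), computed over the lagged series.
    """
    a = np.asarray(observed)
    b = np.asarray(predicted)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("observed and predicted must be equal-length non-empty series")
    return float((a == b).mean())


def _rule_predictions(cand: np.ndarray) -> np.ndarray:
    """Predictions of all 2^(k+1) signed AND/OR rules over the given candidates.

    ``cand`` is (k, L).  Returns (2^(k+1), L) in the canonical
    enumeration order: gate AND first then OR, sign patterns in
    ascending binary order with bit j (LSB = first regulator) flipping
    regulator j's literal to negative.
    """
    k, L = cand.shape
    patterns = np.arange(2 ** k, dtype=np.uint32)
    # flip[p, j] == 1 where pattern p negates regulator j
    flip = ((patterns[:, None] >> np.arange(k)) & 1).astype(np.int8)
    lits = cand[None, :, :] ^ flip[:, :, None]  # (2^k, k, L)
    and_pred = lits.min(axis=1)
    or_pred = lits.max(axis=1)
    return np.concatenate([and_pred, or_pred], axis=0)


def search_update_rule(
    problem: LaggedProblem, S
) -> tuple[BooleanFunction, float]:
    """Best signed AND/OR rule over the regulator set S.

    Enumerates every sign assignment for each gate — 2^(|S|+1) rules —
    and returns the one maximizing gene-wise consistency of its
    one-step predictions against the target.  Ties go to the first rule
    in the canonical enumeration order.
    """
    S = tuple(int(s) for s in S)
    if not S:
        raise ValueError("regulator set S must be non-empty")
    cand = problem.candidates[list(S), :]
    preds = _rule_predictions(cand)
    scores = (preds == problem.target[None, :]).mean(axis=1)
    best = int(np.argmax(scores))  # first max wins: enumeration-order tie-break
    k = len(S)
    gate = Gate.AND if best < 2 ** k else Gate.OR
    pattern = best % (2 ** k)
    signs = tuple(-1 if (pattern >> j) & 1 else 1 for j in range(k))
    return BooleanFunction(S, signs, gate), float(scores[best])


def _mi_with_target(problem: LaggedProblem) -> np.ndarray:
    return np.array(
        [mutual_information(problem.target, problem.candidates[j]) for j in range(problem.n_candidates)]
    )


def mifs_select(problem: LaggedProblem, k: int) -> list[int]:
    """Greedy MIFS selection of k candidate regulators.

    First pick maximizes mutual information with the target; each later
    pick maximizes relevance minus the summed pairwise redundancy with
    the already-selected set.  Ties break to the lowest candidate index.
    """
    n = problem.n_candidates
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    relevance = _mi_with_target(problem)
    selected: list[int] = [int(np.argmax(relevance))]
    remaining = [j for j in range(n) if j != selected[0]]
    while len(selected) < k:
        scores = [
            relevance[w]
            - sum(mutual_information(problem.candidates[w], problem.candidates[s]) for s in selected)
            for w in remaining
        ]
        pick = remaining[int(np.argmax(scores))]
        selected.append(pick)
        remaining.remove(pick)
    return selected


def _order_by_mi(indices, mi: np.ndarray) -> list[int]:
    # descending MI, ties to lowest index
    return sorted(indices, key=lambda j: (-mi[j], j))


def swap_improve(
    problem: LaggedProblem, S, max_accepted_swaps: int | None = None
) -> tuple[list[int], BooleanFunction, float]:
    """Refine a regulator set by single-pair swaps.

    Both the selected set S and the unselected pool are kept ordered by
    descending mutual information with the target.  Each sweep examines
    every pair (s in S, w not in S) in that order and applies the single
    swap giving the largest STRICT increase in the best consistency
    achievable by :func:`search_update_rule` (ties to the
    earliest-scanned pair); sweeps repeat until perfect consistency or
    until no swap improves.  Taking the best swap per sweep rather than
    the first improving one avoids walking away from a reachable
    perfect set via a mediocre early swap.
    """
    S = [int(s) for s in S]
    if not S:
        raise ValueError("S must be non-empty")
    mi = _mi_with_target(problem)
    S = _order_by_mi(S, mi)
    if max_accepted_swaps is None:
        max_accepted_swaps = 10 * problem.n_candidates  # safety valve; never binds in practice
    rule, best = search_update_rule(problem, S)
    accepted = 0
    while best < 1.0 and accepted < max_accepted_swaps:
        unselected = _order_by_mi(set(range(problem.n_candidates)) - set(S), mi)
        sweep_best = None
        for i in range(len(S)):
            for w in unselected:
                trial = _order_by_mi(S[:i] + [w] + S[i + 1:], mi)
                trial_rule, trial_score = search_update_rule(problem, trial)
                if trial_score > best and (
                    sweep_best is None or trial_score > sweep_best[2]
                ):
                    sweep_best = (trial, trial_rule, trial_score)
        if sweep_best is None:
            break
        S, rule, best = sweep_best
        accepted += 1
    return S, rule, best


def infer_gene(traj: Trajectory, target_index: int, K: int = DEFAULT_MAX_K) -> InferenceResult:
    """Infer one gene's regulator set and update rule.

    Applies the zero-entropy shortcut, otherwise grows k from 1 to K,
    running MIFS then SWAP at each k, stopping at the first k reaching
    perfect consistency.  If no k does, the best consistency wins, ties
    to the smallest k (parsimony).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    problem = make_lagged_problem(traj, target_index)
    if entropy(problem.target) == 0.0:
        rule = BooleanFunction.constant(int(problem.target[0]))
        return InferenceResult(target_index, (), rule, 1.0, 0)
    best: InferenceResult | None = None
    for k in range(1, min(K, problem.n_candidates) + 1):
        S0 = mifs_select(problem, k)
        S, rule, c = swap_improve(problem, S0)
        if best is None or c > best.consistency:
            best = InferenceResult(target_index, tuple(S), rule, c, k)
        if c == 1.0:
            break
    assert best is not None
    return best


def infer_network(
    traj: Trajectory, K: int = DEFAULT_MAX_K
) -> tuple[BooleanNetwork, list[InferenceResult]]:
    """Infer every gene independently and assemble the network."""
    results = [infer_gene(traj, i, K) for i in range(traj.n_genes)]
    net = BooleanNetwork([r.rule for r in results], list(traj.node_names))
    return net, results
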