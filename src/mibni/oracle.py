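"""Brute-force exhaustive inference over all small regulator subsets.

A Best-Fit-style global search restricted to the signed AND/OR rule
class: every regulator subset of size 1..max_size is tried with all of
its 2^(|S|+1) rules.  Cost grows as sum_k C(N, k) * 2^(k+1) * T, so it
is only meant for tiny problems — as an independent check on the greedy
search, which can only match or fall below its optimum.
"""

from __future__ import annotations

from itertools import combinations

from .boolnet import BooleanFunction
from .inference import LaggedProblem, search_update_rule

__all__ = ["exhaustive_infer_gene"]


def exhaustive_infer_gene(
    problem: LaggedProblem, max_size: int
) -> tuple[tuple[int, ...], BooleanFunction, float]:
    """Globally optimal (subset, rule, consistency) at the given size cap.

    Subsets are enumerated by increasing size then lexicographically;
    ties keep the first optimum found, matching the greedy search's
    enumeration order for rules.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    n = problem.n_candidates
    best: tuple[tuple[int, ...], BooleanFunction, float] | None = None
    for size in range(1, min(max_size, n) + 1):
        for subset in combinations(range(n), size):
            rule, score = search_update_rule(problem, subset)
            if best is None or score > best[2]:
                best = (subset, rule, score)
                if score == 1.0:
                    return best
    assert best is not None
    return best
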