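"""Plug-in entropy and mutual information for binary time series.

These are the selection scores used by the greedy regulator search:
candidate regulators are ranked by their mutual information with a
target gene's (lagged) Boolean series.  All quantities use empirical
(maximum-likelihood) probabilities with no smoothing and log base 2,
so entropies of a binary series lie in [0, 1] bits.
"""

from __future__ import annotations

import numpy as np

__all__ = ["entropy", "joint_entropy", "mutual_information"]


def _as_binary(x, name: str = "series") -> np.ndarray:
    a = np.asarray(x)
    if a.ndim != 1 or a.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D sequence")
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return a.astype(np.int8, copy=False)


def _plugin_entropy(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n  # 0 * log 0 := 0 by dropping empty cells
    return float(-(p * np.log2(p)).sum())


def entropy(x) -> float:
    """Shannon entropy H(X) in bits of a binary series, H = -sum p log2 p."""
    a = _as_binary(x, "x")
    counts = np.bincount(a, minlength=2)
    return _plugin_entropy(counts, a.size)


def joint_entropy(x, y) -> float:
    """Joint entropy H(X, Y) in bits over the four joint binary outcomes."""
    a = _as_binary(x, "x")
    b = _as_binary(y, "y")
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    counts = np.bincount(2 * a + b, minlength=4)
    return _plugin_entropy(counts, a.size)


def mutual_information(x, y) -> float:
    """Mutual information I(X;Y) = H(X) + H(Y) - H(X,Y), clamped at 0.

    The clamp removes the tiny negative floating-point residue that the
    three-term formula can leave when X and Y are exactly independent.
    """
    mi = entropy(x) + entropy(y) - joint_entropy(x, y)
    return max(mi, 0.0)
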