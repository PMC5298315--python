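"""K-means (k = 2) binarization of real-valued expression series.

Each gene's time course is clustered into two groups; the cluster with
the higher mean becomes the 'on' state (1), the other the 'off' state
(0).  Genes are treated independently.  Centroids are initialised at
the gene's minimum and maximum, which for 1-D two-cluster Lloyd
iteration is deterministic and recovers the optimal interval split at
this scale; a constant gene is mapped to all zeros so that downstream
inference assigns it a constant rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from .boolnet import Trajectory

__all__ = ["ExpressionMatrix", "kmeans_binarize"]


@dataclass
class ExpressionMatrix:
    """T x N real-valued matrix, rows = time points, columns = genes."""

    values: np.ndarray
    node_names: list[str] = field(default=None)  # type: ignore[assignment]
    time_labels: list = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x N matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")
        if self.node_names is None:
            self.node_names = [f"G{i + 1}" for i in range(self.values.shape[1])]
        if self.time_labels is None:
            self.time_labels = list(range(1, self.values.shape[0] + 1))


def _binarize_column(col: np.ndarray) -> np.ndarray:
    lo, hi = col.min(), col.max()
    if lo == hi:
        return np.zeros(col.size, dtype=np.int8)
    with warnings.catch_warnings():
        # near-degenerate columns can collapse to one occupied cluster,
        # which is a valid outcome here, not a convergence problem
        warnings.simplefilter("ignore", ConvergenceWarning)
        km = KMeans(
            n_clusters=2,
            init=np.array([[lo], [hi]]),
            n_init=1,
            max_iter=100,
            tol=1e-9,
        ).fit(col.reshape(-1, 1))
    labels = km.labels_
    means = km.cluster_centers_.ravel()
    on = int(np.argmax(means))
    return (labels == on).astype(np.int8)


def kmeans_binarize(x: ExpressionMatrix) -> Trajectory:
    """Binarize each gene's series by 2-means; higher-mean cluster -> 1."""
    if isinstance(x, np.ndarray):
        x = ExpressionMatrix(x)
    if x.values.shape[0] < 2:
        raise ValueError("need at least 2 time points to binarize")
    cols = [_binarize_column(x.values[:, j]) for j in range(x.values.shape[1])]
    return Trajectory(np.column_stack(cols), list(x.node_names))
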