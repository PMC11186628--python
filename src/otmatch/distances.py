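"""Intra-study distance matrices between feature-intensity vectors.

The alignment rests on the assumption that a metabolite shared by two
studies keeps its intensity-correlation fingerprint: for shared pairs,
d(X_i, X_k) in study 1 approximates d(Y_j, Y_l) in study 2.  Two distances
are supported:

* ``normalized_euclidean``: d(u, v) = ||u - v|| / sqrt(n).  On rows that
  were centered and scaled to unit population variance this equals
  sqrt(2 * cosine distance) of the raw rows.
* ``cosine``: d(u, v) = 1 - corr(u, v), in [0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = ["DistanceMatrix", "pairwise_distance"]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric p x p matrix of distances between a study's feature vectors."""

    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(v < 0) or np.any(np.diag(v) != 0):
            raise ValueError("distances must be nonnegative with zero diagonal")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def pairwise_distance(intensities: np.ndarray, metric: str = "normalized_euclidean") -> DistanceMatrix:
    """Distance matrix between the rows of a (features x samples) intensity matrix."""
    X = np.asarray(intensities, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-d intensity matrix with at least 2 samples")
    n = X.shape[1]
    if metric == "normalized_euclidean":
        d = squareform(pdist(X, metric="euclidean")) / np.sqrt(n)
    elif metric == "cosine":
        if np.any(X.std(axis=1) == 0):
            raise ValueError("cosine distance undefined for constant intensity rows")
        d = 1.0 - np.corrcoef(X)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)  # clamp round-off
    d = 0.5 * (d + d.T)
    return DistanceMatrix(values=d, metric=metric)
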