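"""Local synthetic density against a generator-drawn reference population.

Every quantity here is measured between original objects and the synthetic
set FD (the fake-normals). The k-distance of a query x is the distance to its
k-th nearest synthetic object; the synthetic neighborhood N_k(x) contains
every FD member within that radius (the defining inequality is non-strict,
so ties at the k-distance are all included and |N_k| may exceed k). The
local synthetic density is

    LSD(x) = 1 / (sum_{FD_j in N_k(x)} dist(x, FD_j) + eps)

— large when x sits amid dense synthetic mass, small in sparse regions.
Neighbor search is exact (full pairwise distances); the populations scored
here are a few thousand rows at most.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Neighborhood",
    "euclidean_distance",
    "k_distance",
    "neighborhood",
    "lsd",
    "lsd_all",
    "lsd_synthetic",
    "LSD_EPS",
]

# guard added to the distance sum so coincident points give a large finite
# density instead of a division by zero
LSD_EPS = 1e-12


@dataclass
class Neighborhood:
    """Synthetic neighborhood of one query point.

    neighbor_ids index into FD, sorted by ascending distance; every recorded
    distance is <= k_distance, and ties at the k-distance make the
    neighborhood larger than k.
    """

    neighbor_ids: np.ndarray
    distances: np.ndarray
    k_distance: float


def _as_matrix(fd: np.ndarray) -> np.ndarray:
    fd = np.asarray(fd, dtype=float)
    if fd.ndim != 2:
        raise ValueError("synthetic set must be a 2-D array")
    if not np.isfinite(fd).all():
        raise ValueError("synthetic set contains non-finite entries")
    return fd


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Straight-line distance sqrt(sum_j (a_j - b_j)^2)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(((a - b) ** 2).sum()))


def _dists_to(x: np.ndarray, fd: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size != fd.shape[1]:
        raise ValueError("query dimension does not match synthetic set")
    return cdist(x[None, :], fd)[0]


def k_distance(x: np.ndarray, fd: np.ndarray, k: int) -> float:
    """Distance from x to its k-th nearest synthetic object."""
    fd = _as_matrix(fd)
    if not 1 <= k <= fd.shape[0]:
        raise ValueError(f"k={k} out of range for synthetic set of size {fd.shape[0]}")
    d = _dists_to(x, fd)
    return float(np.partition(d, k - 1)[k - 1])


def neighborhood(x: np.ndarray, fd: np.ndarray, k: int) -> Neighborhood:
    """All synthetic objects within the k-distance of x (ties included)."""
    fd = _as_matrix(fd)
    if not 1 <= k <= fd.shape[0]:
        raise ValueError(f"k={k} out of range for synthetic set of size {fd.shape[0]}")
    d = _dists_to(x, fd)
    kdist = float(np.partition(d, k - 1)[k - 1])
    ids = np.flatnonzero(d <= kdist)
    order = np.argsort(d[ids], kind="stable")
    ids = ids[order]
    return Neighborhood(neighbor_ids=ids, distances=d[ids], k_distance=kdist)


def lsd(x: np.ndarray, fd: np.ndarray, k: int) -> float:
    """Local synthetic density of x: reciprocal summed neighborhood distance."""
    nb = neighborhood(x, fd, k)
    return float(1.0 / (nb.distances.sum() + LSD_EPS))


def lsd_all(X: np.ndarray, fd: np.ndarray, k: int) -> np.ndarray:
    """Vectorized LSD of every row of X against FD; identical to per-row lsd()."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    fd = _as_matrix(fd)
    if not 1 <= k <= fd.shape[0]:
        raise ValueError(f"k={k} out of range for synthetic set of size {fd.shape[0]}")
    D = cdist(X, fd)
    kdist = np.partition(D, k - 1, axis=1)[:, k - 1]
    sums = np.where(D <= kdist[:, None], D, 0.0).sum(axis=1)
    return 1.0 / (sums + LSD_EPS)


def lsd_synthetic(fd: np.ndarray, k: int) -> np.ndarray:
    """Leave-one-out LSD of each synthetic object against the rest of FD.

    Each row's self-distance of zero is excluded so it cannot deflate every
    sum; requires s >= k + 1 so each row still has k genuine neighbors.
    """
    fd = _as_matrix(fd)
    s = fd.shape[0]
    if s < k + 1:
        raise ValueError(f"leave-one-out LSD needs at least k+1={k + 1} rows, got {s}")
    D = cdist(fd, fd)
    np.fill_diagonal(D, np.inf)
    kdist = np.partition(D, k - 1, axis=1)[:, k - 1]
    mask = D <= kdist[:, None]
    sums = np.where(mask, D, 0.0).sum(axis=1)
    return 1.0 / (sums + LSD_EPS)
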