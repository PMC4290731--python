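"""Pairwise fiber distances and affinity-matrix construction.

Two streamline-space distances are provided, both defined over fibers
resampled to the same number of points ``k`` and both treating a fiber and
its reversed copy as identical:

* ``d_smp`` — symmetrized mean-closest-point distance, the average of the
  two directed means of the per-point closest distances
  ``d_m(F_i, F_j) = (1/k) sum_a min_b ||p_a - q_b||``.
* ``d_pp``  — symmetrized point-to-point distance, the mean of the
  index-corresponding point distances, minimized over the flip of the
  second fiber: ``min(d_p(F_i, F_j), d_p(F_i, flip(F_j)))``.

Distances are turned into graph affinities by ``a_ij = exp(-d_ij / sigma)``
with zero diagonal (no self-loops). By default ``sigma`` is the maximum
pairwise distance, which pins the smallest off-diagonal affinity at
``exp(-1)`` regardless of the dataset's scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Union

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "AffinityMatrix",
    "mean_closest_point_directed",
    "d_smp",
    "d_p",
    "d_pp",
    "pairwise_distance_matrix",
    "build_affinity",
]


def _check_same_k(fi: np.ndarray, fj: np.ndarray) -> None:
    if fi.shape != fj.shape:
        raise ValueError(
            f"fibers must share the same sample count, got {fi.shape} vs {fj.shape}"
        )


def mean_closest_point_directed(fi: np.ndarray, fj: np.ndarray) -> float:
    """Directed mean-closest-point distance d_m(F_i, F_j); not symmetric."""
    fi = np.asarray(fi, dtype=float)
    fj = np.asarray(fj, dtype=float)
    _check_same_k(fi, fj)
    return float(cdist(fi, fj).min(axis=1).mean())


def d_smp(fi: np.ndarray, fj: np.ndarray) -> float:
    """Symmetrized mean-closest-point distance (average of both directions)."""
    return 0.5 * (
        mean_closest_point_directed(fi, fj) + mean_closest_point_directed(fj, fi)
    )


def d_p(fi: np.ndarray, fj: np.ndarray) -> float:
    """Mean of index-corresponding point distances (orientation-sensitive)."""
    fi = np.asarray(fi, dtype=float)
    fj = np.asarray(fj, dtype=float)
    _check_same_k(fi, fj)
    return float(np.linalg.norm(fi - fj, axis=1).mean())


def d_pp(fi: np.ndarray, fj: np.ndarray) -> float:
    """Symmetrized point-to-point distance: min over the flip of F_j.

    Flipping F_i instead is equivalent (reversing both orders together
    leaves every corresponding pair intact), so one flip suffices and the
    result is symmetric and flip-invariant.
    """
    fj = np.asarray(fj, dtype=float)
    return min(d_p(fi, fj), d_p(fi, fj[::-1]))


def _stack(fibers: Sequence[np.ndarray]) -> np.ndarray:
    arr = np.asarray(fibers, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("fibers must all be (k, 3) arrays with a common k")
    return arr


def _pairwise_pp(fibers: Sequence[np.ndarray]) -> np.ndarray:
    arr = _stack(fibers)
    n = arr.shape[0]
    flipped = arr[:, ::-1]
    d_fwd = np.linalg.norm(arr[:, None] - arr[None, :], axis=3).mean(axis=2)
    d_rev = np.linalg.norm(arr[:, None] - flipped[None, :], axis=3).mean(axis=2)
    d = np.minimum(d_fwd, d_rev)
    d = 0.5 * (d + d.T)  # symmetric up to fp noise; enforce exactly
    np.fill_diagonal(d, 0.0)
    return d


def _pairwise_smp(fibers: Sequence[np.ndarray], chunk: int = 64) -> np.ndarray:
    arr = _stack(fibers)
    n, k, _ = arr.shape
    flat = arr.reshape(n * k, 3)
    directed = np.empty((n, n))
    # chunked so the (chunk*k, n*k) point-distance block stays small
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        block = cdist(arr[start:stop].reshape(-1, 3), flat)
        block = block.reshape(stop - start, k, n, k)
        directed[start:stop] = block.min(axis=3).mean(axis=1)
    d = 0.5 * (directed + directed.T)
    np.fill_diagonal(d, 0.0)
    return d


def pairwise_distance_matrix(
    fibers: Sequence[np.ndarray], metric: str = "pp"
) -> np.ndarray:
    """Full symmetric distance matrix under ``metric`` ("pp" or "smp")."""
    if len(fibers) < 1:
        raise ValueError("need at least one fiber")
    if metric == "pp":
        return _pairwise_pp(fibers)
    if metric == "smp":
        return _pairwise_smp(fibers)
    raise ValueError(f"unknown streamline metric {metric!r}")


@dataclass
class AffinityMatrix:
    """Symmetric non-negative affinity matrix with zero diagonal."""

    values: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def build_affinity(
    distances: np.ndarray, sigma: Union[float, str] = "max"
) -> AffinityMatrix:
    """Exponential affinity ``a_ij = exp(-d_ij / sigma)``, zero diagonal.

    ``sigma="max"`` resolves the normalization to the maximum pairwise
    distance so that every off-diagonal affinity lands in ``[exp(-1), 1]``.
    A fully degenerate all-zero distance matrix resolves sigma to 1 (all
    off-diagonal affinities become exactly 1).
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.any(d < 0) or not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite and non-negative")
    if isinstance(sigma, str):
        if sigma != "max":
            raise ValueError(f"unknown sigma sentinel {sigma!r}")
        resolved = float(d.max())
        if resolved == 0.0:
            resolved = 1.0
    else:
        resolved = float(sigma)
        if resolved <= 0:
            raise ValueError("sigma must be positive")
    a = np.exp(-d / resolved)
    np.fill_diagonal(a, 0.0)
    return AffinityMatrix(values=a, sigma=resolved)
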