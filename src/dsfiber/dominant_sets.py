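"""Dominant Sets clustering: replicator dynamics on the simplex.

A dominant set (DS) generalizes a maximal clique to edge-weighted graphs: it
is a subset of vertices with high mutual affinity and low affinity to the
rest of the graph. Given a symmetric non-negative affinity matrix ``A`` with
zero diagonal, each DS corresponds to a strict local maximizer of the
quadratic form ``x^T A x`` over the standard simplex; the support
``{i : x_i > 0}`` of the maximizer is the cluster and the objective value
``x^T A x`` is its *cohesiveness* (internal coherence).

Local maximizers are found with replicator dynamics from evolutionary game
theory,

    x_i(t+1) = x_i(t) * (A x(t))_i / (x(t)^T A x(t)),

which preserves the simplex and, for non-negative symmetric ``A``, increases
the objective monotonically. Multiple clusters are extracted with a
peeling-off strategy: extract a DS, delete its members from the graph,
repeat on the remainder.

Because converged iterates are never exactly zero in floating point, the
support is thresholded relative to the largest component:
``{i : x_i > theta * max(x)}`` with a very small ``theta`` (default 1e-5).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np

from .metrics import AffinityMatrix

__all__ = [
    "DSConfig",
    "DominantSet",
    "NoCohesiveStructureError",
    "replicator_dynamics",
    "support",
    "cohesiveness",
    "peel",
]

logger = logging.getLogger(__name__)

#: relative weight of the deterministic symmetry-breaking mix in the default start
_SYMMETRY_BREAK_ETA = 1e-2

#: tolerance on the equilibrium payoff condition (A x)_i / (x^T A x) = 1 that
#: surviving components must meet before the dynamics are declared converged
_EQUILIBRIUM_RTOL = 1e-5


class NoCohesiveStructureError(RuntimeError):
    """The dynamics hit ``x^T A x == 0``: no cohesive structure to extract."""


@dataclass
class DSConfig:
    """Knobs of the dominant-set extraction.

    theta: relative support threshold in [0, 1); very small values keep the
        model stable, larger values over-segment into tighter clusters.
    epsilon: stop when ``||x(t+1) - x(t)||_2 < epsilon``.
    max_iterations: hard cap so non-convergence cannot hang a pipeline.
    regularization: shift ``alpha`` in [0, 1): the dynamics maximize
        ``x^T (A + alpha*I) x`` instead of ``x^T A x``. The default 0 is
        the plain quadratic form, the right setting for generic real-valued
        affinities. Unweighted (0/1) affinity graphs, however, admit
        *spurious* non-strict maximizers of the plain form whose supports
        are not cliques (e.g. the uniform continuum on a 4-cycle); any
        ``0 < alpha < 1`` removes them, making strict local maximizers
        correspond one-to-one with maximal cliques (``alpha = 1/2`` is the
        customary choice). Cohesiveness is always reported on the
        unshifted matrix.
    """

    theta: float = 1e-5
    epsilon: float = 1e-7
    max_iterations: int = 10000
    regularization: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta < 1.0):
            raise ValueError("theta must lie in [0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not (0.0 <= self.regularization < 1.0):
            raise ValueError("regularization must lie in [0, 1)")


@dataclass
class DominantSet:
    """One extracted cluster.

    ``support`` holds member indices in the *original* matrix; ``x`` is the
    converged characteristic vector restricted to those members;
    ``cohesiveness`` is the objective value on the submatrix the cluster was
    extracted from. ``residual`` marks leftover nodes emitted as singletons
    when peeling can no longer find cohesive structure.
    """

    support: np.ndarray
    x: np.ndarray
    cohesiveness: float
    extraction_rank: int
    residual: bool = False

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=int)
        self.x = np.asarray(self.x, dtype=float)

    @property
    def size(self) -> int:
        return int(self.support.size)


def _affinity_values(A: Union[np.ndarray, AffinityMatrix]) -> np.ndarray:
    if isinstance(A, AffinityMatrix):
        A = A.values
    a = np.asarray(A, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("affinity matrix must be square")
    if np.any(a < 0) or not np.all(np.isfinite(a)):
        raise ValueError("affinity matrix must be finite and non-negative")
    return a


def _default_start(n: int) -> np.ndarray:
    """Barycenter of the simplex with a tiny deterministic asymmetric mix.

    The exact barycenter is a fixed point of the dynamics on any affinity
    matrix whose row sums are all equal (e.g. regular unweighted graphs),
    where it is typically a saddle rather than a maximizer. Mixing in a
    small size-seeded random simplex point breaks such symmetries while
    keeping the start deterministic, so repeated runs are identical.
    """
    rng = np.random.default_rng(n)
    v = rng.random(n)
    v /= v.sum()
    x0 = (1.0 - _SYMMETRY_BREAK_ETA) / n + _SYMMETRY_BREAK_ETA * v
    return x0 / x0.sum()


def replicator_dynamics(
    A: Union[np.ndarray, AffinityMatrix],
    x0: Optional[np.ndarray] = None,
    cfg: Optional[DSConfig] = None,
    full_output: bool = False,
):
    """Iterate the replicator equation to a stable characteristic vector.

    The dynamics stop once the step norm drops below ``cfg.epsilon`` *and*
    every component still above the support threshold satisfies the
    equilibrium payoff condition ``(A x)_i = x^T A x`` (to a small relative
    tolerance). The second condition matters because a component that is
    slowly going extinct can make per-step changes smaller than epsilon
    while still carrying weight above the support threshold; its payoff is
    visibly below average, so the dynamics are kept running until it either
    equilibrates or falls out of the support. Without this guard such
    stragglers leak into extracted supports.

    Returns the converged characteristic vector; with ``full_output=True``
    returns ``(x, info)`` where ``info`` carries ``converged``,
    ``n_iterations``, the objective trajectory, and every iterate.

    Raises :class:`NoCohesiveStructureError` if the objective is zero at any
    iterate (the current support touches no positive affinity).
    """
    a = _affinity_values(A)
    cfg = cfg or DSConfig()
    n = a.shape[0]
    if cfg.regularization > 0.0:
        a = a + cfg.regularization * np.eye(n)
    if x0 is None:
        x = _default_start(n)
    else:
        x = np.asarray(x0, dtype=float).copy()
        if x.shape != (n,):
            raise ValueError("x0 has wrong length")
        if np.any(x < 0) or abs(x.sum() - 1.0) > 1e-9:
            raise ValueError("x0 must lie on the simplex")

    objective_path: List[float] = []
    iterates: List[np.ndarray] = [x.copy()] if full_output else []
    converged = False
    it = 0
    for it in range(1, cfg.max_iterations + 1):
        ax = a @ x
        obj = float(x @ ax)
        objective_path.append(obj)
        if obj == 0.0:
            raise NoCohesiveStructureError(
                "x^T A x = 0: the weighted support has no internal affinity"
            )
        payoff_ratio = ax / obj
        x_new = x * payoff_ratio
        x_new /= x_new.sum()  # absorb floating-point drift off the simplex
        step = float(np.linalg.norm(x_new - x))
        surviving = x > cfg.theta * x.max()
        equilibrated = bool(
            np.all(np.abs(payoff_ratio[surviving] - 1.0) <= _EQUILIBRIUM_RTOL)
        )
        x = x_new
        if full_output:
            iterates.append(x.copy())
        if step < cfg.epsilon and equilibrated:
            converged = True
            break
    if not converged:
        logger.warning(
            "replicator dynamics did not converge in %d iterations", cfg.max_iterations
        )
    objective_path.append(float(x @ (a @ x)))
    if full_output:
        info = {
            "converged": converged,
            "n_iterations": it,
            "objective_path": np.asarray(objective_path),
            "iterates": np.asarray(iterates),
        }
        return x, info
    return x


def support(x: np.ndarray, theta: float) -> np.ndarray:
    """Thresholded support ``{i : x_i > theta * max(x)}`` (sorted indices)."""
    if not (0.0 <= theta <= 1.0):
        raise ValueError("theta must lie in [0, 1]")
    x = np.asarray(x, dtype=float)
    return np.flatnonzero(x > theta * x.max())


def cohesiveness(x: np.ndarray, A: Union[np.ndarray, AffinityMatrix]) -> float:
    """Internal coherence ``x^T A x`` of a cluster's characteristic vector."""
    a = _affinity_values(A)
    x = np.asarray(x, dtype=float)
    return float(x @ (a @ x))


def peel(
    A: Union[np.ndarray, AffinityMatrix], cfg: Optional[DSConfig] = None
) -> List[DominantSet]:
    """Extract all dominant sets by peeling-off.

    Runs the dynamics on the remaining submatrix (rows/columns of already
    extracted members deleted, affinities untouched), extracts the support,
    removes it, and repeats while at least two nodes remain and cohesive
    structure exists. Leftover nodes are emitted as residual singletons so
    the output clusters always partition the index set.
    """
    a = _affinity_values(A)
    cfg = cfg or DSConfig()
    remaining = np.arange(a.shape[0])
    clusters: List[DominantSet] = []
    rank = 0
    while remaining.size >= 2:
        sub = a[np.ix_(remaining, remaining)]
        try:
            x = replicator_dynamics(sub, cfg=cfg)
        except NoCohesiveStructureError:
            break
        s = support(x, cfg.theta)
        coh = cohesiveness(x, sub)
        clusters.append(
            DominantSet(
                support=remaining[s],
                x=x[s],
                cohesiveness=coh,
                extraction_rank=rank,
            )
        )
        rank += 1
        mask = np.ones(remaining.size, dtype=bool)
        mask[s] = False
        remaining = remaining[mask]
    for idx in remaining:
        clusters.append(
            DominantSet(
                support=np.array([idx]),
                x=np.array([1.0]),
                cohesiveness=0.0,
                extraction_rank=rank,
                residual=True,
            )
        )
        rank += 1
    return clusters
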