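"""Stage 1: per-subject clustering of streamlines into bundles.

Fibers (already resampled to a common k) are clustered with dominant sets on
the symmetrized point-to-point distance, the streamline-space metric that
tracks the landmark-space metric used in stage 2 most closely. Extracted
clusters are then pruned in two passes driven by the cohesiveness curve
(cohesiveness vs. extraction rank):

1. the last 5% of extracted clusters are dropped (late extractions are
   low-cohesion leftovers), along with all residual singletons;
2. a second-order polynomial trend is removed from the survivors'
   cohesiveness curve and clusters whose residual falls in the negative
   tail of a zero-mean Gaussian fitted to the residuals (one-sided,
   p < alpha) are rejected as outliers.

Each kept cluster is finally summarized by its medoid fiber — the member
minimizing the total distance to all other members — which represents the
bundle in the cross-subject stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.stats import norm

from .dominant_sets import DSConfig, DominantSet, peel
from .metrics import build_affinity, pairwise_distance_matrix

__all__ = [
    "SubjectClustering",
    "cluster_subject",
    "normalize_cohesiveness",
    "select_clusters",
    "medoid",
]


@dataclass
class SubjectClustering:
    """Result of stage-1 clustering for one subject."""

    subject_id: str
    clusters: List[DominantSet]
    distance_matrix: np.ndarray
    sigma: float
    kept_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    medoid_indices: Dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kept_mask is None:
            self.kept_mask = np.ones(len(self.clusters), dtype=bool)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)

    @property
    def cohesiveness_curve(self) -> np.ndarray:
        return np.array([c.cohesiveness for c in self.clusters])

    @property
    def kept_clusters(self) -> List[DominantSet]:
        return [c for c, keep in zip(self.clusters, self.kept_mask) if keep]

    def labels(self, only_kept: bool = False) -> np.ndarray:
        """Per-fiber cluster labels; -1 for fibers in dropped clusters."""
        n = self.distance_matrix.shape[0]
        lab = np.full(n, -1, dtype=int)
        for c, keep in zip(self.clusters, self.kept_mask):
            if only_kept and not keep:
                continue
            lab[c.support] = c.extraction_rank
        return lab


def cluster_subject(
    fibers: Sequence[np.ndarray],
    cfg: Optional[DSConfig] = None,
    subject_id: str = "subject",
) -> SubjectClustering:
    """Cluster resampled fibers with dominant sets on the d_pp metric."""
    if len(fibers) < 2:
        raise ValueError("intra-subject clustering needs at least 2 fibers")
    cfg = cfg or DSConfig()
    dist = pairwise_distance_matrix(fibers, metric="pp")
    aff = build_affinity(dist, sigma="max")
    clusters = peel(aff.values, cfg)
    return SubjectClustering(
        subject_id=subject_id,
        clusters=clusters,
        distance_matrix=dist,
        sigma=aff.sigma,
    )


def normalize_cohesiveness(curve: np.ndarray) -> np.ndarray:
    """Residuals of the cohesiveness curve after removing a quadratic trend.

    With fewer than 3 points a degree-2 fit is underdetermined; the values
    are then merely centered.
    """
    c = np.asarray(curve, dtype=float)
    if c.size < 3:
        return c - c.mean() if c.size else c
    ranks = np.arange(c.size, dtype=float)
    coeffs = np.polyfit(ranks, c, deg=2)
    return c - np.polyval(coeffs, ranks)


def select_clusters(
    clustering: SubjectClustering,
    tail_fraction: float = 0.05,
    alpha: float = 0.05,
) -> SubjectClustering:
    """Prune non-significant clusters and compute medoids for the survivors.

    Pass 1 drops residual singletons and the last ``ceil(tail_fraction * M)``
    clusters by extraction rank (M = total cluster count). Pass 2 detrends
    the survivors' cohesiveness curve, estimates the residual spread as a
    zero-mean Gaussian (sigma-hat = RMS of the residuals) and rejects
    clusters in the one-sided negative tail at confidence ``p < alpha``.
    """
    clusters = clustering.clusters
    m = len(clusters)
    keep = np.array([not c.residual for c in clusters])
    if tail_fraction > 0 and m > 0:
        n_tail = math.ceil(tail_fraction * m)
        ranked = sorted(range(m), key=lambda i: clusters[i].extraction_rank)
        for i in ranked[m - n_tail:]:
            keep[i] = False

    survivor_idx = np.flatnonzero(keep)
    if survivor_idx.size >= 1 and alpha > 0:
        curve = np.array([clusters[i].cohesiveness for i in survivor_idx])
        residuals = normalize_cohesiveness(curve)
        sigma_hat = float(np.sqrt(np.mean(residuals**2)))
        if sigma_hat > 0:
            z = norm.ppf(1.0 - alpha)
            keep[survivor_idx[residuals < -z * sigma_hat]] = False

    medoids = {
        clusters[i].extraction_rank: medoid(
            clusters[i].support, clustering.distance_matrix
        )
        for i in np.flatnonzero(keep)
    }
    return SubjectClustering(
        subject_id=clustering.subject_id,
        clusters=clusters,
        distance_matrix=clustering.distance_matrix,
        sigma=clustering.sigma,
        kept_mask=keep,
        medoid_indices=medoids,
    )


def medoid(members: Sequence[int], distances: np.ndarray) -> int:
    """Member minimizing total distance to the other members; ties → lowest index."""
    idx = np.asarray(members, dtype=int)
    if idx.size == 0:
        raise ValueError("medoid of an empty member set is undefined")
    idx = np.sort(idx)
    row_sums = distances[np.ix_(idx, idx)].sum(axis=1)
    return int(idx[int(np.argmin(row_sums))])
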