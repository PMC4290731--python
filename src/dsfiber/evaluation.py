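"""Clustering quality indices and streamline/landmark metric agreement.

Recovered clusterings are scored against ground truth with two standard
external indices: the Hubert–Arabie adjusted Rand index (chance-corrected
pair-counting agreement, 1 iff the partitions are identical up to
relabeling) and completeness (1 - H(K|C)/H(K): the degree to which all
members of one true bundle end up in a single predicted cluster). A
pair-counting completeness variant — the fraction of truly co-bundled pairs
that are also co-clustered — is provided as a cross-check; both satisfy the
same verbal definition and agree on the extremes.

``metric_correlation`` quantifies how faithfully the landmark-space
encodings preserve streamline-space geometry: Pearson correlations between
all pairwise fiber distances under {d_smp, d_pp} x {min-landmark, full
landmark}, with 2-D histograms of each pairing. The pairing with the
highest correlation motivates which metrics the two pipeline stages use.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist, squareform
from sklearn.metrics import adjusted_rand_score, completeness_score

from .landmark_space import LandmarkSet, encode_full, encode_min, pairwise_landmark_distances
from .metrics import pairwise_distance_matrix

__all__ = [
    "EvaluationReport",
    "adjusted_rand_index",
    "completeness",
    "completeness_pair_counting",
    "evaluate_clustering",
    "metric_correlation",
]


def _check_labels(truth: Sequence, pred: Sequence) -> Tuple[np.ndarray, np.ndarray]:
    t = np.asarray(truth)
    p = np.asarray(pred)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    return t, p


def adjusted_rand_index(truth: Sequence, pred: Sequence) -> float:
    """Hubert–Arabie adjusted Rand index between two labelings."""
    t, p = _check_labels(truth, pred)
    if t.size < 2:
        raise ValueError("need at least 2 items")
    return float(adjusted_rand_score(t, p))


def completeness(truth: Sequence, pred: Sequence) -> float:
    """Entropy-based completeness: 1 - H(K|C)/H(K), defined as 1 if H(K)=0."""
    t, p = _check_labels(truth, pred)
    return float(completeness_score(t, p))


def completeness_pair_counting(truth: Sequence, pred: Sequence) -> float:
    """Fraction of truly co-clustered pairs that the prediction co-clusters.

    Defined as 1 when the truth contains no co-clustered pair.
    """
    t, p = _check_labels(truth, pred)
    same_t = t[:, None] == t[None, :]
    same_p = p[:, None] == p[None, :]
    iu = np.triu_indices(t.size, k=1)
    n_true_pairs = int(same_t[iu].sum())
    if n_true_pairs == 0:
        return 1.0
    return float((same_t[iu] & same_p[iu]).sum() / n_true_pairs)


@dataclass
class EvaluationReport:
    ari: float
    completeness: float
    n_items: int
    n_true_clusters: int
    n_pred_clusters: int

    def to_dict(self) -> Dict[str, float]:
        return {
            "ari": self.ari,
            "completeness": self.completeness,
            "n_items": self.n_items,
            "n_true_clusters": self.n_true_clusters,
            "n_pred_clusters": self.n_pred_clusters,
        }


def evaluate_clustering(truth: Sequence, pred: Sequence) -> EvaluationReport:
    """Score a predicted labeling against ground truth."""
    t, p = _check_labels(truth, pred)
    return EvaluationReport(
        ari=adjusted_rand_index(t, p),
        completeness=completeness(t, p),
        n_items=int(t.size),
        n_true_clusters=int(np.unique(t).size),
        n_pred_clusters=int(np.unique(p).size),
    )


def metric_correlation(
    fibers: Sequence[np.ndarray],
    landmarks: LandmarkSet,
    histogram_bins: int = 50,
) -> Dict[str, object]:
    """Pearson agreement of streamline- vs landmark-space fiber distances.

    Computes condensed pairwise distances under d_smp, d_pp, the
    min-landmark encoding distance, and the full landmark distance, and
    returns the 4 streamline-x-landmark Pearson correlations (NaN where a
    distance set has zero variance) plus paired 2-D histograms.
    """
    if len(fibers) < 10:
        raise ValueError("metric correlation needs at least 10 fibers")
    k = np.asarray(fibers[0]).shape[0]
    iu = np.triu_indices(len(fibers), k=1)

    streamline = {
        "smp": pairwise_distance_matrix(fibers, metric="smp")[iu],
        "pp": pairwise_distance_matrix(fibers, metric="pp")[iu],
    }
    min_enc = np.stack([encode_min(f, landmarks) for f in fibers])
    full_enc = np.stack([encode_full(f, landmarks) for f in fibers])
    landmark = {
        # the min-landmark encoding is flip-invariant already (min over points)
        "min_landmark": cdist(min_enc, min_enc)[iu],
        "full_landmark": pairwise_landmark_distances(full_enc, full_enc, k)[iu],
    }

    correlations: Dict[str, float] = {}
    histograms: Dict[str, Dict[str, np.ndarray]] = {}
    for s_name, s_vals in streamline.items():
        for l_name, l_vals in landmark.items():
            key = f"{s_name}_vs_{l_name}"
            if s_vals.std() == 0.0 or l_vals.std() == 0.0:
                correlations[key] = float("nan")
            else:
                correlations[key] = float(np.corrcoef(s_vals, l_vals)[0, 1])
            h, xe, ye = np.histogram2d(s_vals, l_vals, bins=histogram_bins)
            histograms[key] = {"counts": h, "x_edges": xe, "y_edges": ye}
    return {"correlations": correlations, "histograms": histograms}
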