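"""Landmark-based fiber encodings: space-invariant descriptors.

Fibers from different subjects cannot be compared directly because each
subject's tractogram lives in its own scanner space. Instead of registering
the data, each fiber is described by its Euclidean distances to a set of
anatomical landmark points (ROI centers of gravity from a label atlas
already mapped into the subject's space). Point-landmark distances are
invariant under any rigid motion applied jointly to the fiber and the
landmarks, so encodings of corresponding fibers agree across subjects
without any registration step — the property the cross-subject stage
relies on.

Two encodings are provided: the *min-landmark* vector (length n: minimum
distance from the fiber to each landmark) and the *full* vector (length
k*n: every sampled point against every landmark, point-major). Encoded
fibers are compared with the Euclidean norm, minimized over the flipped
point order of the second fiber since streamlines carry no orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from nibabel.affines import apply_affine
from scipy.spatial.distance import cdist

__all__ = [
    "LandmarkSet",
    "landmarks_from_labels",
    "encode_min",
    "encode_full",
    "flip_encoding",
    "landmark_distance",
    "pairwise_landmark_distances",
]


@dataclass
class LandmarkSet:
    """Ordered labeled landmark points (mm) for one subject.

    The label order must be identical across all subjects of a cohort so
    that encoding dimensions align.
    """

    subject_id: str
    points: np.ndarray  # (n, 3) world mm
    labels: List = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("landmarks must be an (n, 3) array")
        if self.points.shape[0] < 1:
            raise ValueError("need at least one landmark")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")
        if not self.labels:
            self.labels = list(range(self.points.shape[0]))
        if len(self.labels) != self.points.shape[0]:
            raise ValueError("labels must align 1:1 with landmark points")

    @property
    def n(self) -> int:
        return self.points.shape[0]


class MissingLabelError(KeyError):
    """A requested ROI label does not occur in the label volume."""


def landmarks_from_labels(
    label_volume: np.ndarray,
    affine: np.ndarray,
    label_ids: Sequence[int],
    subject_id: str = "subject",
) -> LandmarkSet:
    """Centers of gravity of atlas ROIs, in world mm, in ``label_ids`` order.

    For each id, the unweighted mean of the world coordinates of all voxels
    carrying that label (label volumes have no intensities to weight by).
    """
    vol = np.asarray(label_volume)
    if vol.ndim != 3:
        raise ValueError("label volume must be 3-D")
    points = np.empty((len(label_ids), 3))
    for row, lid in enumerate(label_ids):
        idx = np.argwhere(vol == lid)
        if idx.size == 0:
            raise MissingLabelError(f"label id {lid} not present in the volume")
        points[row] = apply_affine(affine, idx.astype(float)).mean(axis=0)
    return LandmarkSet(subject_id=subject_id, points=points, labels=list(label_ids))


def encode_min(fiber: np.ndarray, landmarks: LandmarkSet) -> np.ndarray:
    """Min-landmark encoding: f_s = min over fiber points of ||p - L_s||."""
    pts = np.asarray(fiber, dtype=float)
    return cdist(landmarks.points, pts).min(axis=1)


def encode_full(fiber: np.ndarray, landmarks: LandmarkSet) -> np.ndarray:
    """Full encoding: all k*n point-landmark distances, point-major order."""
    pts = np.asarray(fiber, dtype=float)
    return cdist(pts, landmarks.points).ravel()


def flip_encoding(encoding: np.ndarray, k: int) -> np.ndarray:
    """Encoding of the flipped fiber: the k point-blocks in reverse order."""
    enc = np.asarray(encoding, dtype=float)
    if enc.size % k != 0:
        raise ValueError(f"encoding length {enc.size} is not a multiple of k={k}")
    return enc.reshape(k, -1)[::-1].ravel()


def landmark_distance(
    enc_i: np.ndarray, enc_j: np.ndarray, enc_j_flipped: np.ndarray
) -> float:
    """Landmark-space fiber distance, orientation-free.

    ``min(||e_i - e_j||, ||e_i - e_j'||)`` where ``e_j'`` encodes the
    flipped second fiber.
    """
    enc_i = np.asarray(enc_i, dtype=float)
    enc_j = np.asarray(enc_j, dtype=float)
    enc_j_flipped = np.asarray(enc_j_flipped, dtype=float)
    if enc_i.shape != enc_j.shape or enc_i.shape != enc_j_flipped.shape:
        raise ValueError("encoding lengths must match")
    return float(
        min(np.linalg.norm(enc_i - enc_j), np.linalg.norm(enc_i - enc_j_flipped))
    )


def pairwise_landmark_distances(
    encodings_a: np.ndarray, encodings_b: np.ndarray, k: int
) -> np.ndarray:
    """Flip-minimized landmark distances between two stacks of encodings.

    ``encodings_a``: (m_a, k*n); ``encodings_b``: (m_b, k*n). Returns the
    (m_a, m_b) matrix of flip-minimized Euclidean encoding distances.
    """
    a = np.atleast_2d(np.asarray(encodings_a, dtype=float))
    b = np.atleast_2d(np.asarray(encodings_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("encoding lengths must match")
    b_flip = np.stack([flip_encoding(e, k) for e in b])
    return np.minimum(cdist(a, b), cdist(a, b_flip))
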