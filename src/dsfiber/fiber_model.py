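"""Streamline representation and geometry.

A streamline (fiber) is an ordered polyline of 3D points in world millimetre
coordinates, stored as a float ``(n, 3)`` array. Whole-brain tractograms are
bags of such polylines tagged with a subject identifier and a voxel-to-world
affine (identity when the data is already in mm).

Before any distance computation every fiber is resampled to a fixed number of
points ``k`` (default 12) equally spaced in arc length along a B-spline
interpolant, so that all fibers live in the same ``k x 3`` representation and
point-to-point correspondences are meaningful. Streamlines carry no intrinsic
orientation, so the reversed (flipped) point order is treated as the same
fiber everywhere downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from scipy.interpolate import splev, splprep

__all__ = [
    "DEFAULT_K",
    "InvalidFiberError",
    "Tractogram",
    "as_streamline",
    "arc_length",
    "resample",
    "flip",
    "filter_short",
    "split_by_hemisphere",
]

DEFAULT_K = 12

#: dense samples used to invert the arc-length parameterization of the spline
_DENSE_SAMPLES = 1024


class InvalidFiberError(ValueError):
    """Raised when a polyline cannot be interpreted as a streamline."""


def as_streamline(points: Iterable) -> np.ndarray:
    """Validate and coerce ``points`` into an ``(n, 3)`` float array.

    Requires at least 2 points, finite coordinates, and no two identical
    consecutive points (zero-length segments are forbidden).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidFiberError(f"streamline must be (n, 3), got {pts.shape}")
    if pts.shape[0] < 2:
        raise InvalidFiberError("streamline needs at least 2 points")
    if not np.all(np.isfinite(pts)):
        raise InvalidFiberError("streamline coordinates must be finite")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0.0):
        raise InvalidFiberError("streamline contains zero-length segments")
    return pts


@dataclass
class Tractogram:
    """One subject's set of streamlines in a common world-mm frame."""

    subject_id: str
    fibers: List[np.ndarray] = field(default_factory=list)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    def __len__(self) -> int:
        return len(self.fibers)


def arc_length(fiber: np.ndarray) -> float:
    """Total polyline length in mm (sum of Euclidean segment lengths)."""
    pts = np.asarray(fiber, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise InvalidFiberError("arc_length needs a polyline of >= 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _dedupe_consecutive(pts: np.ndarray) -> np.ndarray:
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 0.0
    return pts[keep]


def resample(fiber: np.ndarray, k: int = DEFAULT_K) -> np.ndarray:
    """Resample a polyline to exactly ``k`` points equispaced in arc length.

    The polyline is interpolated with a B-spline (cubic where the input has
    at least 4 points, dropping to the highest degree the point count
    supports) and sampled at ``k`` parameters chosen so that consecutive
    output points are equidistant along the curve. The first and last output
    points coincide with the input endpoints.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    pts = np.asarray(fiber, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidFiberError(f"streamline must be (n, 3), got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise InvalidFiberError("streamline coordinates must be finite")
    pts = _dedupe_consecutive(pts)
    if pts.shape[0] < 2:
        raise InvalidFiberError("resample needs >= 2 distinct points")

    degree = min(3, pts.shape[0] - 1)
    # s=0: interpolating spline through every input point
    tck, _ = splprep(pts.T, s=0.0, k=degree)
    u_dense = np.linspace(0.0, 1.0, _DENSE_SAMPLES)
    dense = np.asarray(splev(u_dense, tck)).T
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    cum = np.concatenate(([0.0], np.cumsum(seg)))
    targets = np.linspace(0.0, cum[-1], k)
    u_eq = np.interp(targets, cum, u_dense)
    out = np.asarray(splev(u_eq, tck)).T
    # interpolating spline hits the endpoints; pin them exactly
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def flip(fiber: np.ndarray) -> np.ndarray:
    """Reverse the point order of a fiber. Involution: flip(flip(F)) == F."""
    return np.asarray(fiber, dtype=float)[::-1].copy()


def filter_short(tractogram: Tractogram, min_length: float = 3.0) -> Tractogram:
    """Drop fibers with arc length strictly below ``min_length`` mm.

    Fibers exactly at the threshold are kept ("shorter than" removed).
    Order of survivors is preserved.
    """
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    kept = [f for f in tractogram.fibers if arc_length(f) >= min_length]
    return Tractogram(tractogram.subject_id, kept, tractogram.affine.copy())


def split_by_hemisphere(
    tractogram: Tractogram, midplane_x: float = 0.0
) -> Tuple[Tractogram, Tractogram, Tractogram]:
    """Partition fibers into (left, right, inter-hemispheric) tractograms.

    A fiber with every point strictly at ``x < midplane_x`` is left, every
    point strictly at ``x > midplane_x`` is right; fibers crossing or
    touching the sagittal plane are inter-hemispheric. The three outputs
    partition the input.
    """
    if not math.isfinite(midplane_x):
        raise ValueError("midplane_x must be finite")
    groups: dict[str, List[np.ndarray]] = {"left": [], "right": [], "inter": []}
    for f in tractogram.fibers:
        x = np.asarray(f)[:, 0]
        if np.all(x < midplane_x):
            groups["left"].append(f)
        elif np.all(x > midplane_x):
            groups["right"].append(f)
        else:
            groups["inter"].append(f)
    aff = tractogram.affine
    return tuple(  # type: ignore[return-value]
        Tractogram(tractogram.subject_id, groups[g], aff.copy())
        for g in ("left", "right", "inter")
    )


def resample_tractogram(
    tractogram: Tractogram, k: int = DEFAULT_K
) -> List[np.ndarray]:
    """Resample every fiber of a tractogram to ``k`` points."""
    return [resample(f, k) for f in tractogram.fibers]
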