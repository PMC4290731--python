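"""Ground-truthed synthetic tractography cohorts.

Generates multi-subject streamline datasets that exercise every pipeline
stage without real diffusion data. A *canonical* subject is built first:
``n_bundles`` smooth bundles packed inside a sphere of fixed radius, each
bundle a gently curved centerline (quadratic Bezier arc) surrounded by
fibers with a constant perpendicular Gaussian cross-sectional offset plus
optional per-point jitter, with each fiber's point order randomly flipped
(streamlines have no preferred orientation). Landmarks are points scattered
in the same sphere. Every other subject is the canonical subject under its
own random rigid transform, applied to fibers *and* landmarks together, so
the ground-truth cross-subject correspondence is exact by construction and
landmark encodings of corresponding fibers agree across subjects.

Bundle centerlines are packed by rejection sampling with a minimum
center-to-center separation of ``separation_factor * cross_section_sd``, so
that by construction bundles are well separated relative to their spread —
the regime in which clustering recovery is expected.

Randomness layout: the master seed spawns one independent stream for the
canonical subject and landmarks, plus one stream per subject (transform and
jitter), so adding subjects never perturbs earlier subjects' draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .fiber_model import Tractogram
from .landmark_space import LandmarkSet

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "random_rigid_transform",
    "generate_bundle",
    "generate_subject",
    "generate_cohort",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort (lengths in mm, angles in degrees)."""

    n_subjects: int = 4
    n_bundles: int = 10
    fibers_per_bundle: int = 50
    sphere_radius: float = 50.0
    cross_section_sd: float = 0.5
    point_jitter_sd: float = 0.0
    flip_probability: float = 0.5
    rotation_deg: float = 30.0
    translation_mm: float = 20.0
    n_landmarks: int = 50
    centerline_samples: int = 30
    separation_factor: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_bundles < 1 or self.fibers_per_bundle < 1:
            raise ValueError("counts must be >= 1")
        if self.cross_section_sd < 0 or self.point_jitter_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not (0.0 <= self.flip_probability <= 1.0):
            raise ValueError("flip_probability must lie in [0, 1]")
        if self.sphere_radius <= 0 or self.n_landmarks < 1:
            raise ValueError("sphere_radius must be > 0 and n_landmarks >= 1")


@dataclass
class SyntheticCohort:
    """A generated cohort with full ground truth."""

    tractograms: List[Tractogram]
    true_labels: Dict[str, np.ndarray]  # subject_id -> per-fiber bundle id
    landmarks: Dict[str, LandmarkSet]
    transforms: Dict[str, Tuple[np.ndarray, np.ndarray]]  # (R, t) per subject
    config: SyntheticConfig

    @property
    def subject_ids(self) -> List[str]:
        return [t.subject_id for t in self.tractograms]


def random_rigid_transform(
    rng: np.random.Generator, max_rotation_deg: float, max_translation_mm: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Random rotation (uniform axis, angle <= max) and bounded translation."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_rotation_deg))
    kx, ky, kz = axis
    cross = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    rot = np.eye(3) + np.sin(angle) * cross + (1 - np.cos(angle)) * cross @ cross
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    trans = direction * rng.uniform(0.0, max_translation_mm)
    return rot, trans


def _apply_rigid(points: np.ndarray, rot: np.ndarray, trans: np.ndarray) -> np.ndarray:
    return points @ rot.T + trans


def _bezier_centerline(
    start: np.ndarray, control: np.ndarray, end: np.ndarray, n_samples: int
) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n_samples)[:, None]
    return (1 - t) ** 2 * start + 2 * (1 - t) * t * control + t**2 * end


def _sample_centerline(
    rng: np.random.Generator, center: np.ndarray, cfg: SyntheticConfig
) -> np.ndarray:
    """A gently curved arc through ``center`` staying inside the sphere."""
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    half = rng.uniform(0.25, 0.45) * cfg.sphere_radius
    start, end = center - half * direction, center + half * direction
    # bow the arc perpendicular to the chord
    perp = np.cross(direction, rng.normal(size=3))
    perp /= np.linalg.norm(perp)
    control = center + perp * rng.uniform(0.05, 0.2) * half
    pts = _bezier_centerline(start, control, end, cfg.centerline_samples)
    radius = np.linalg.norm(pts, axis=1).max()
    limit = 0.95 * cfg.sphere_radius
    if radius > limit:  # shrink toward the center to stay inside the volume
        pts = center + (pts - center) * (limit / radius)
    return pts


def generate_bundle(
    centerline: np.ndarray,
    m: int,
    spread: float,
    rng: np.random.Generator,
    point_jitter_sd: float = 0.0,
    flip_probability: float = 0.5,
) -> List[np.ndarray]:
    """``m`` fibers around a centerline.

    Each fiber is the centerline shifted by a constant offset drawn in the
    plane perpendicular to the bundle's mean direction (both components
    N(0, spread)), plus optional isotropic per-point jitter; the point order
    is reversed with probability ``flip_probability``.
    """
    cl = np.asarray(centerline, dtype=float)
    direction = cl[-1] - cl[0]
    direction /= np.linalg.norm(direction)
    # orthonormal basis of the cross-sectional plane
    helper = np.array([1.0, 0.0, 0.0])
    if abs(direction @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(direction, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    fibers = []
    for _ in range(m):
        offset = rng.normal(0.0, spread) * e1 + rng.normal(0.0, spread) * e2
        pts = cl + offset
        if point_jitter_sd > 0:
            pts = pts + rng.normal(0.0, point_jitter_sd, size=pts.shape)
        if rng.random() < flip_probability:
            pts = pts[::-1].copy()
        fibers.append(pts)
    return fibers


def _pack_centers(rng: np.random.Generator, cfg: SyntheticConfig) -> np.ndarray:
    """Bundle centers inside the sphere with a minimum mutual separation."""
    min_sep = max(cfg.separation_factor * cfg.cross_section_sd, 1e-6)
    centers: List[np.ndarray] = []
    max_attempts = 2000 * cfg.n_bundles
    for _ in range(max_attempts):
        cand = rng.uniform(-0.6, 0.6, size=3) * cfg.sphere_radius
        if np.linalg.norm(cand) > 0.6 * cfg.sphere_radius:
            continue
        if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
            centers.append(cand)
            if len(centers) == cfg.n_bundles:
                return np.asarray(centers)
    raise ValueError(
        f"could not pack {cfg.n_bundles} bundle centers with separation "
        f"{min_sep:.2f} mm inside a sphere of radius {cfg.sphere_radius:.1f} mm"
    )


def generate_subject(
    cfg: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
    subject_id: str = "canonical",
) -> Tuple[Tractogram, np.ndarray]:
    """One subject: ``n_bundles`` bundles in the sphere plus per-fiber labels."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    centers = _pack_centers(rng, cfg)
    fibers: List[np.ndarray] = []
    labels: List[int] = []
    for bundle_id, center in enumerate(centers):
        cl = _sample_centerline(rng, center, cfg)
        bundle = generate_bundle(
            cl,
            cfg.fibers_per_bundle,
            cfg.cross_section_sd,
            rng,
            point_jitter_sd=0.0,  # jitter is applied per subject in cohorts
            flip_probability=cfg.flip_probability,
        )
        fibers.extend(bundle)
        labels.extend([bundle_id] * len(bundle))
    return Tractogram(subject_id, fibers), np.asarray(labels)


def _sample_landmarks(rng: np.random.Generator, cfg: SyntheticConfig) -> np.ndarray:
    """Landmarks uniform in the sphere (emulating scattered ROI centroids)."""
    pts = np.empty((cfg.n_landmarks, 3))
    filled = 0
    while filled < cfg.n_landmarks:
        cand = rng.uniform(-1.0, 1.0, size=3) * cfg.sphere_radius
        if np.linalg.norm(cand) <= cfg.sphere_radius:
            pts[filled] = cand
            filled += 1
    return pts


def generate_cohort(cfg: SyntheticConfig) -> SyntheticCohort:
    """Multi-subject cohort: rigid copies of one canonical subject.

    Per subject, the canonical fibers and landmarks are moved by a random
    rigid transform; independent per-point jitter (``point_jitter_sd``) is
    then added to the fibers only, so with zero jitter subjects are exact
    rigid copies and corresponding landmark encodings match exactly.
    """
    if cfg.n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    master = np.random.SeedSequence(cfg.seed)
    canonical_ss, *subject_ss = master.spawn(cfg.n_subjects + 1)
    canonical_rng = np.random.default_rng(canonical_ss)
    canonical, labels = generate_subject(cfg, canonical_rng)
    canonical_landmarks = _sample_landmarks(canonical_rng, cfg)

    tractograms: List[Tractogram] = []
    true_labels: Dict[str, np.ndarray] = {}
    landmark_sets: Dict[str, LandmarkSet] = {}
    transforms: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for s in range(cfg.n_subjects):
        sid = f"subject{s:02d}"
        rng = np.random.default_rng(subject_ss[s])
        rot, trans = random_rigid_transform(rng, cfg.rotation_deg, cfg.translation_mm)
        fibers = []
        for f in canonical.fibers:
            pts = _apply_rigid(f, rot, trans)
            if cfg.point_jitter_sd > 0:
                pts = pts + rng.normal(0.0, cfg.point_jitter_sd, size=pts.shape)
            fibers.append(pts)
        tractograms.append(Tractogram(sid, fibers))
        true_labels[sid] = labels.copy()
        landmark_sets[sid] = LandmarkSet(
            subject_id=sid,
            points=_apply_rigid(canonical_landmarks, rot, trans),
            labels=list(range(cfg.n_landmarks)),
        )
        transforms[sid] = (rot, trans)
    return SyntheticCohort(
        tractograms=tractograms,
        true_labels=true_labels,
        landmarks=landmark_sets,
        transforms=transforms,
        config=cfg,
    )
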