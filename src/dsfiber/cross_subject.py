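"""Stage 2: matching bundles across subjects without registration.

Each subject's kept bundles are represented by their medoid fibers, encoded
in the landmark space (full point-landmark encoding). All subjects' medoids
are pooled into one union dataset and a block affinity matrix is built:
entries between medoids of *different* subjects are exponential affinities
of the flip-minimized landmark distance (each subject pair normalized by its
own block maximum distance), while entries between medoids of the *same*
subject — the diagonal blocks — are forced to zero. Zero same-subject
affinity guarantees that no dominant set can ever contain two bundles of one
subject, so each extracted cluster is a cross-subject correspondence with at
most one bundle per subject.

Dominant sets are peeled off this block matrix and clusters spanning every
subject (*complete* clusters) are kept as the group-wise white-matter
bundles. Subjects may contribute different numbers of bundles; incomplete
clusters are simply discarded by the final selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dominant_sets import DSConfig, peel
from .landmark_space import pairwise_landmark_distances

logger = logging.getLogger(__name__)

__all__ = [
    "CrossSubjectAffinity",
    "CrossCluster",
    "build_block_affinity",
    "cross_cluster",
    "select_complete",
]


@dataclass
class CrossSubjectAffinity:
    """Block affinity over the pooled bundle dataset.

    ``subject_of[i]`` maps row i to its subject id and ``local_index[i]`` to
    the bundle's index within that subject's list. Diagonal (same-subject)
    blocks are identically zero.
    """

    values: np.ndarray
    subject_of: List[str]
    local_index: np.ndarray
    block_sigmas: Dict[Tuple[str, str], float]

    @property
    def n_subjects(self) -> int:
        return len(set(self.subject_of))


@dataclass
class CrossCluster:
    """One cross-subject bundle correspondence."""

    members: Dict[str, int]  # subject_id -> local bundle index
    cohesiveness: float
    extraction_rank: int
    complete: bool = False


def build_block_affinity(
    encodings: Dict[str, np.ndarray],
    k: int,
    sigma_scope: str = "per-block",
) -> CrossSubjectAffinity:
    """Build the zero-diagonal-block affinity matrix from medoid encodings.

    ``encodings`` maps subject id to an ``(m_s, k*n)`` stack of full
    landmark encodings. Cross-subject entries are
    ``exp(-d_l(v_i, v_j) / sigma_{k,h})`` with ``d_l`` the flip-minimized
    landmark distance and ``sigma_{k,h}`` the maximum distance inside that
    subject-pair block (``sigma_scope="global"`` uses the maximum over all
    cross-subject pairs instead). Same-subject entries are zero.
    """
    if len(encodings) < 2:
        raise ValueError("cross-subject matching needs at least 2 subjects")
    if sigma_scope not in ("per-block", "global"):
        raise ValueError("sigma_scope must be 'per-block' or 'global'")
    subjects = list(encodings.keys())
    stacks = {}
    width = None
    for sid in subjects:
        arr = np.atleast_2d(np.asarray(encodings[sid], dtype=float))
        if arr.shape[0] < 1:
            raise ValueError(f"subject {sid!r} contributes no bundles")
        if width is None:
            width = arr.shape[1]
        elif arr.shape[1] != width:
            raise ValueError(
                f"encoding length mismatch: subject {sid!r} has {arr.shape[1]}, "
                f"subject {subjects[0]!r} has {width}"
            )
        stacks[sid] = arr

    subject_of: List[str] = []
    local_index: List[int] = []
    offsets = {}
    total = 0
    for sid in subjects:
        offsets[sid] = total
        m = stacks[sid].shape[0]
        subject_of.extend([sid] * m)
        local_index.extend(range(m))
        total += m

    dist = np.zeros((total, total))
    for ai, sa in enumerate(subjects):
        for sb in subjects[ai + 1:]:
            block = pairwise_landmark_distances(stacks[sa], stacks[sb], k)
            ra = slice(offsets[sa], offsets[sa] + stacks[sa].shape[0])
            rb = slice(offsets[sb], offsets[sb] + stacks[sb].shape[0])
            dist[ra, rb] = block
            dist[rb, ra] = block.T

    values = np.zeros((total, total))
    block_sigmas: Dict[Tuple[str, str], float] = {}
    global_sigma = None
    if sigma_scope == "global":
        cross_mask = np.array(subject_of)[:, None] != np.array(subject_of)[None, :]
        global_sigma = float(dist[cross_mask].max()) if cross_mask.any() else 1.0
        if global_sigma == 0.0:
            global_sigma = 1.0
    for ai, sa in enumerate(subjects):
        for sb in subjects[ai + 1:]:
            ra = slice(offsets[sa], offsets[sa] + stacks[sa].shape[0])
            rb = slice(offsets[sb], offsets[sb] + stacks[sb].shape[0])
            block = dist[ra, rb]
            sigma = global_sigma if global_sigma is not None else float(block.max())
            if sigma == 0.0:
                sigma = 1.0  # identical encodings: affinity saturates at 1
            block_sigmas[(sa, sb)] = block_sigmas[(sb, sa)] = sigma
            values[ra, rb] = np.exp(-block / sigma)
            values[rb, ra] = values[ra, rb].T
    np.fill_diagonal(values, 0.0)
    return CrossSubjectAffinity(
        values=values,
        subject_of=subject_of,
        local_index=np.asarray(local_index),
        block_sigmas=block_sigmas,
    )


def cross_cluster(
    affinity: CrossSubjectAffinity, cfg: Optional[DSConfig] = None
) -> List[CrossCluster]:
    """Peel dominant sets off the block matrix into cross-subject clusters.

    An exact dominant set can never hold two bundles of the same subject:
    a zero-affinity pair cannot both carry weight at a strict equilibrium.
    Numerically, a slowly-extinguishing component can still sit just above
    the support threshold when the dynamics stop; if such a straggler
    duplicates a subject already represented with more weight, it is
    removed from the cluster and re-emitted as an incomplete singleton, so
    every bundle still appears in exactly one output cluster.
    """
    cfg = cfg or DSConfig()
    n_subjects = affinity.n_subjects
    out: List[CrossCluster] = []
    displaced: List[int] = []
    for ds in peel(affinity.values, cfg):
        best: Dict[str, Tuple[int, float]] = {}
        for row, weight in zip(ds.support, ds.x):
            sid = affinity.subject_of[row]
            if sid in best and best[sid][1] >= weight:
                displaced.append(int(row))
                continue
            if sid in best:
                displaced.append(best[sid][0])
            best[sid] = (int(row), float(weight))
        if len(best) < ds.support.size:
            logger.debug(
                "dropped %d same-subject straggler(s) from cluster %d",
                ds.support.size - len(best), ds.extraction_rank,
            )
        members = {sid: int(affinity.local_index[row]) for sid, (row, _) in best.items()}
        out.append(
            CrossCluster(
                members=members,
                cohesiveness=ds.cohesiveness,
                extraction_rank=ds.extraction_rank,
                complete=len(members) == n_subjects,
            )
        )
    rank = len(out)
    for row in displaced:
        out.append(
            CrossCluster(
                members={affinity.subject_of[row]: int(affinity.local_index[row])},
                cohesiveness=0.0,
                extraction_rank=rank,
                complete=n_subjects == 1,
            )
        )
        rank += 1
    return out


def select_complete(
    clusters: Sequence[CrossCluster], n_subjects: int, min_subjects: Optional[int] = None
) -> List[CrossCluster]:
    """Keep clusters spanning at least ``min_subjects`` (default: all) subjects.

    The default mirrors the strictest rule — a correspondence must include
    one bundle from every subject; relax with ``min_subjects`` to tolerate
    missing bundles in a few subjects.
    """
    need = n_subjects if min_subjects is None else min_subjects
    return [c for c in clusters if len(c.members) >= need]
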