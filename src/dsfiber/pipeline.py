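"""End-to-end pipeline: filter -> resample -> intra-subject -> cross-subject.

``run_cohort`` is the in-memory engine (tractograms and landmark sets in,
clusterings and the cross-subject manifest out); ``run_pipeline`` wraps it
with file I/O and a structured run log for CLI use.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import io
from .config import PipelineConfig
from .cross_subject import (
    CrossCluster,
    build_block_affinity,
    cross_cluster,
    select_complete,
)
from .fiber_model import Tractogram, filter_short, resample
from .intra_subject import SubjectClustering, cluster_subject, select_clusters
from .landmark_space import LandmarkSet, encode_full

__all__ = ["PipelineResult", "run_cohort", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    clusterings: Dict[str, SubjectClustering]
    medoid_fiber_indices: Dict[str, List[int]]  # per subject, stage-2 row order
    cross_clusters: Optional[List[CrossCluster]]
    complete_clusters: Optional[List[CrossCluster]]
    log: List[str] = field(default_factory=list)

    def manifest(self) -> dict:
        """JSON-ready description of the selected cross-subject bundles."""
        clusters = self.complete_clusters or []
        return {
            "n_subjects": len(self.clusterings),
            "n_complete_clusters": len(clusters),
            "clusters": [
                {
                    "cluster_id": c.extraction_rank,
                    "members": c.members,
                    "cohesiveness": c.cohesiveness,
                    "complete": c.complete,
                }
                for c in clusters
            ],
        }


def run_cohort(
    tractograms: Sequence[Tractogram],
    landmarks: Optional[Dict[str, LandmarkSet]],
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run both clustering stages on in-memory data.

    The cross-subject stage runs only when landmarks are supplied and at
    least two subjects are present; otherwise intra-subject results are
    returned alone (with a notice in the log).
    """
    cfg = config or PipelineConfig()
    ds_cfg = cfg.ds_config()
    log: List[str] = [f"config_hash={cfg.content_hash()}"]

    clusterings: Dict[str, SubjectClustering] = {}
    resampled: Dict[str, List[np.ndarray]] = {}
    for tg in tractograms:
        kept = filter_short(tg, cfg.min_fiber_length_mm)
        log.append(
            f"{tg.subject_id}: {len(tg)} fibers, {len(kept)} after "
            f">={cfg.min_fiber_length_mm} mm length filter"
        )
        if len(kept) < 2:
            raise ValueError(
                f"subject {tg.subject_id!r} has {len(kept)} usable fibers; "
                "need at least 2"
            )
        fibers = [resample(f, cfg.k_samples) for f in kept.fibers]
        resampled[tg.subject_id] = fibers
        clustering = select_clusters(
            cluster_subject(fibers, ds_cfg, subject_id=tg.subject_id),
            tail_fraction=cfg.tail_fraction,
            alpha=cfg.alpha,
        )
        clusterings[tg.subject_id] = clustering
        log.append(
            f"{tg.subject_id}: {len(clustering.clusters)} clusters, "
            f"{int(clustering.kept_mask.sum())} kept"
        )

    medoid_fiber_indices = {
        sid: [
            clustering.medoid_indices[cl.extraction_rank]
            for cl in clustering.kept_clusters
        ]
        for sid, clustering in clusterings.items()
    }

    if landmarks is None or len(tractograms) < 2:
        log.append("cross-subject stage skipped (needs landmarks and >= 2 subjects)")
        logger.info("cross-subject stage skipped")
        return PipelineResult(clusterings, medoid_fiber_indices, None, None, log)

    encodings = {}
    for sid, fibers in resampled.items():
        if sid not in landmarks:
            raise ValueError(f"no landmarks provided for subject {sid!r}")
        medoid_idx = medoid_fiber_indices[sid]
        if not medoid_idx:
            raise ValueError(f"subject {sid!r} kept no clusters; cannot cross-match")
        encodings[sid] = np.stack(
            [encode_full(fibers[i], landmarks[sid]) for i in medoid_idx]
        )
    affinity = build_block_affinity(encodings, cfg.k_samples, cfg.sigma_scope)
    clusters = cross_cluster(affinity, ds_cfg)
    complete = select_complete(clusters, n_subjects=len(encodings))
    log.append(
        f"cross-subject: {len(clusters)} clusters, {len(complete)} complete"
    )
    return PipelineResult(clusterings, medoid_fiber_indices, clusters, complete, log)


def run_pipeline(
    tractogram_paths: Sequence,
    landmark_paths: Optional[Sequence],
    out_dir,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """File-based pipeline entry point; writes all artifacts under out_dir."""
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tractograms = [io.read_tractogram(p) for p in tractogram_paths]
    landmarks = None
    if landmark_paths:
        sets = [
            io.read_landmarks(p, label_ids=cfg.landmark_label_ids)
            for p in landmark_paths
        ]
        if len(sets) != len(tractograms):
            raise ValueError("need exactly one landmark file per tractogram")
        landmarks = {
            tg.subject_id: LandmarkSet(tg.subject_id, ls.points, ls.labels)
            for tg, ls in zip(tractograms, sets)
        }
    result = run_cohort(tractograms, landmarks, cfg)

    for sid, clustering in result.clusterings.items():
        coh = {c.extraction_rank: c.cohesiveness for c in clustering.clusters}
        io.write_assignments(
            out / f"{sid}_assignments.tsv",
            clustering.labels(),
            clustering.kept_mask[clustering.labels()],
            coh,
        )
    manifest = result.manifest()
    manifest["config"] = cfg.to_dict()
    manifest["config_hash"] = cfg.content_hash()
    (out / "cross_manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "run_log.txt").write_text("\n".join(result.log) + "\n")
    return result
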