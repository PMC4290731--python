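"""File I/O: tractograms (TRK/TCK), landmarks (NIfTI/JSON/CSV), tables.

All streamline data is converted to world mm (RAS) coordinates on load via
the file header, so nothing downstream ever sees voxel indices.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .fiber_model import Tractogram
from .landmark_space import LandmarkSet, landmarks_from_labels

__all__ = [
    "read_tractogram",
    "write_tractogram",
    "read_landmarks",
    "write_landmarks",
    "write_assignments",
    "read_labels_tsv",
]

logger = logging.getLogger(__name__)

_FORMATS = {".trk": nib.streamlines.TrkFile, ".tck": nib.streamlines.TckFile}


def _format_for(path: Path, fmt: Optional[str]) -> str:
    suffix = f".{fmt.lower()}" if fmt else path.suffix.lower()
    if suffix not in _FORMATS:
        raise ValueError(f"unknown tractogram format {suffix!r} (use trk or tck)")
    return suffix


def read_tractogram(path, fmt: Optional[str] = None, subject_id: Optional[str] = None) -> Tractogram:
    """Load a TRK/TCK file; streamlines come back in world mm (RAS)."""
    path = Path(path)
    _format_for(path, fmt)
    tf = nib.streamlines.load(str(path))  # lazy=False: we need all coordinates
    fibers = [np.asarray(s, dtype=float) for s in tf.streamlines]
    sid = subject_id or path.stem
    logger.info("loaded %d streamlines (world mm) from %s", len(fibers), path)
    return Tractogram(subject_id=sid, fibers=fibers, affine=np.eye(4))


def write_tractogram(tractogram: Tractogram, path, fmt: Optional[str] = None) -> None:
    """Write streamlines (assumed world mm) to TRK or TCK."""
    path = Path(path)
    suffix = _format_for(path, fmt)
    t = nib.streamlines.Tractogram(
        [np.asarray(f, dtype=float) for f in tractogram.fibers],
        affine_to_rasmm=np.eye(4),
    )
    _FORMATS[suffix](t).save(str(path))


def read_landmarks(
    path,
    subject_id: Optional[str] = None,
    label_ids: Optional[Sequence[int]] = None,
) -> LandmarkSet:
    """Load landmarks from JSON/CSV coordinate tables or a NIfTI label volume.

    Tables need columns ``label_id, x_mm, y_mm, z_mm`` (JSON: a list of such
    objects, optionally wrapped as ``{"subject_id": ..., "landmarks": [...]}``).
    Rows are re-ordered to ``label_ids`` when given, so every subject of a
    cohort ends up with an identical canonical landmark order. For NIfTI,
    ``label_ids`` selects the ROIs whose centers of gravity become landmarks.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        if label_ids is None:
            raise ValueError("label_ids is required to extract landmarks from NIfTI")
        img = nib.load(str(path))
        vol = np.asanyarray(img.dataobj).astype(int)
        return landmarks_from_labels(
            vol, img.affine, label_ids, subject_id=subject_id or path.stem
        )
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        if isinstance(payload, dict):
            subject_id = subject_id or payload.get("subject_id")
            rows = payload["landmarks"]
        else:
            rows = payload
        df = pd.DataFrame(rows)
    elif path.suffix.lower() in (".csv", ".tsv"):
        df = pd.read_csv(path, sep="\t" if path.suffix.lower() == ".tsv" else ",")
    else:
        raise ValueError(f"unknown landmark file format {path.suffix!r}")

    required = {"label_id", "x_mm", "y_mm", "z_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"landmark table is missing columns: {sorted(missing)}")
    if label_ids is not None:
        df = df.set_index("label_id").loc[list(label_ids)].reset_index()
    points = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    return LandmarkSet(
        subject_id=subject_id or path.stem,
        points=points,
        labels=df["label_id"].tolist(),
    )


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    path = Path(path)
    rows = [
        {"label_id": lab, "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]}
        for lab, p in zip(landmarks.labels, landmarks.points)
    ]
    path.write_text(
        json.dumps({"subject_id": landmarks.subject_id, "landmarks": rows}, indent=1)
    )


def write_assignments(path, labels: np.ndarray, kept: np.ndarray, cohesiveness: Dict[int, float]) -> None:
    """Per-fiber cluster assignment table (TSV)."""
    df = pd.DataFrame(
        {
            "fiber_index": np.arange(len(labels)),
            "cluster_id": labels,
            "kept": kept.astype(int),
            "cohesiveness": [cohesiveness.get(int(c), 0.0) for c in labels],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_labels_tsv(path, column: str = "cluster_id") -> np.ndarray:
    """Read a per-fiber label column from a TSV written by this package."""
    df = pd.read_csv(path, sep="\t")
    if column not in df.columns:
        raise ValueError(f"column {column!r} not found in {path}")
    return df[column].to_numpy()
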