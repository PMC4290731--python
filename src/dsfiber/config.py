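"""Pipeline configuration with strict validation.

Defaults are the method's published operating point: 12 sample points per
fiber, support threshold theta = 1e-5, convergence epsilon = 1e-7, 5%
extraction-tail pruning, one-sided Gaussian outlier rejection at p < 0.05,
and a 3 mm minimum fiber length.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import yaml

from .dominant_sets import DSConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    k_samples: int = 12
    theta: float = 1e-5
    epsilon: float = 1e-7
    max_iterations: int = 10000
    tail_fraction: float = 0.05
    alpha: float = 0.05
    min_fiber_length_mm: float = 3.0
    stage1_metric: str = "pp"
    sigma_scope: str = "per-block"  # stage-2 block normalization
    split_hemispheres: bool = False
    midplane_x_mm: float = 0.0
    landmark_label_ids: Optional[List[int]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_samples < 2:
            raise ValueError("k_samples must be >= 2")
        if self.stage1_metric not in ("pp", "smp"):
            raise ValueError("stage1_metric must be 'pp' or 'smp'")
        if self.sigma_scope not in ("per-block", "global"):
            raise ValueError("sigma_scope must be 'per-block' or 'global'")
        if not (0.0 <= self.tail_fraction < 1.0):
            raise ValueError("tail_fraction must lie in [0, 1)")
        if not (0.0 <= self.alpha < 0.5):
            raise ValueError("alpha must lie in [0, 0.5)")
        if self.min_fiber_length_mm < 0:
            raise ValueError("min_fiber_length_mm must be >= 0")
        # delegate theta/epsilon/max_iterations validation
        self.ds_config()

    def ds_config(self) -> DSConfig:
        return DSConfig(
            theta=self.theta,
            epsilon=self.epsilon,
            max_iterations=self.max_iterations,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        """Stable short hash identifying this configuration (provenance)."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    """Load a YAML/JSON config; unknown keys are an error, never ignored."""
    path = Path(path)
    raw = path.read_text()
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; known keys: {sorted(known)}"
        )
    return PipelineConfig(**data)
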