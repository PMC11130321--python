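"""Pipeline configuration: one human-editable YAML file of thresholds,
layer boundaries, seeds and simulator presets. Unknown keys are rejected.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .circuit import (ACTIVATION_THRESHOLD_MV, STRONG_ACTIVATION_THRESHOLD_MV,
                      LayerTable)
from .ephys import RA_LIMIT_MOHM, RA_MAX_REL_CHANGE
from .patchseq import DEG_FC_MIN, DEG_Q_MAX, DEPTH_FLOOR, MARKER_CEILING

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline, with units in field names."""

    seed: int = 0
    output_dir: str = "optomap_out"
    activation_threshold_mv: float = ACTIVATION_THRESHOLD_MV
    strong_activation_threshold_mv: float = STRONG_ACTIVATION_THRESHOLD_MV
    qc_depth_floor_counts: int = DEPTH_FLOOR
    qc_marker_ceiling_log2: float = MARKER_CEILING
    deg_q_max: float = DEG_Q_MAX
    deg_fc_min: float = DEG_FC_MIN
    ra_limit_mohm: float = RA_LIMIT_MOHM
    ra_max_rel_change: float = RA_MAX_REL_CHANGE
    layer_names: tuple[str, ...] = ("L1", "L2/3", "L4", "L5", "L6")
    layer_bounds_um: tuple[float, ...] = (0.0, 100.0, 310.0, 430.0, 600.0, 850.0)
    simulator_presets: dict = field(default_factory=dict)

    def layer_table(self) -> LayerTable:
        return LayerTable(names=tuple(self.layer_names),
                          bounds=tuple(self.layer_bounds_um))


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config, rejecting keys the pipeline does not define."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("layer_names", "layer_bounds_um"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)
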