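"""Run configuration: every tunable of the pipeline in one serializable
record, echoed next to the outputs of every run for provenance."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline tunables with their defaults.

    Thresholds are dimensionless fractions unless a ``_um`` suffix marks a
    physical length in µm.
    """

    # inputs / outputs
    stack_path: str = ""
    seeds_path: str = ""          # JSON: list of per-vessel seed point lists (z,y,x µm)
    rois_path: str = ""           # optional compartment ROI polygons
    output_dir: str = "avleak_out"
    timepoint_tag: str = ""
    voxel_size_um: tuple[float, float, float] | None = None  # override for untagged files

    # smoothing / tracing
    smooth_sigma_px: float = 1.0
    trace_kappa: float = 10.0
    trace_intensity_floor: float = 1e-3
    resample_spacing_um: float = 1.0

    # lumen filling
    fill_threshold_fraction: float = 0.3
    fill_reach_factor: float = 3.0

    # leakage
    background: float = 0.0
    dilation_guard: bool = True
    aggregate: str = "sum"
    perfusion_factor: float = 2.0

    # leak sites / AV axis
    leak_detection_threshold: float | None = None  # None: background + 3 sd from a corner
    min_site_voxels: int = 5
    sample_interval_um: float = 1.0
    tie_tolerance_um: float = 0.58
    max_attribution_um: float = 50.0
    spreading_mode: str = "3d"
    vessel_flags: dict[str, dict[str, str]] = field(default_factory=dict)

    seed: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        payload = json.loads(p.read_text() if p.exists() else str(source))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if payload.get("voxel_size_um") is not None:
            payload["voxel_size_um"] = tuple(payload["voxel_size_um"])
        return cls(**payload)
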