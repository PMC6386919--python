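"""Pipeline configuration: one nested, validated block per stage.

Defaults follow the device's published operating point where one exists
(hue 90-180 deg, saturation >= 90 %, BT.709 luminance weights, six
stable frames, an 11 x 11 dot grid, a 10-60 cm calibration range); the
remaining knobs are the package's own defaults, documented in the
methods note.  Unknown keys are rejected and configs round-trip through
JSON/YAML unchanged.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .detect import MaskCascadeConfig
from .geometry import CameraModel
from .gridindex import GridConfig
from .synth import SceneSpec

__all__ = ["PipelineConfig", "load_config"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CameraBlock(_Block):
    width: int = 720
    height: int = 480
    fov_deg: float = 66.0
    cx_shift_cm: float = 0.0
    cy_shift_cm: float = 0.0
    y_axis_factor: float = 2.0 / 3.0


class CascadeBlock(_Block):
    hue_min_deg: float = 90.0
    hue_max_deg: float = 180.0
    saturation_min_pct: float = 90.0
    similarity_reference_rgb: tuple[float, float, float] = (0.0, 255.0, 0.0)
    similarity_threshold: float = 0.9
    luminance_threshold: float = 0.6
    luminance_floor: float = 1.0
    opening_disk_radius_px: int = 5
    border_erosion_radius_px: int = 8
    min_area_px: int = 3
    min_separation_px: float = 12.0
    refine_reference: bool = False


class GridBlock(_Block):
    rows: int = 11
    cols: int = 11
    accept_frac: float = 0.45
    occupancy_rescan: float = 0.5


class CalibrationBlock(_Block):
    depth_min_cm: float = 10.0
    depth_max_cm: float = 60.0
    depth_step_cm: float = 1.0
    monotone_tol_px: float = 1.0


class ReconstructionBlock(_Block):
    k_frames: int = 6
    merge_radius_cm: float = 0.5
    refine_poses: bool = False
    bottom_percentile: float = 5.0
    pose_source: str = "ground_truth"   # or "gyro"
    impute: bool = True
    correction_factors: dict[str, float] = {}


class SynthBlock(_Block):
    pitch_deg: float = 2.2
    laser_offset_cm: tuple[float, float, float] = (4.0, 0.0, 0.0)
    toe_cross_cm: float = 35.0
    dot_sigma_px: float = 2.5
    dot_green: float = 230.0
    dot_mix: float = 0.97
    center_dot_gain: float = 1.5
    satellite_green_factor: float = 0.913
    gaussian_sigma: float = 2.0
    reflection_count: int = 3
    background_color: tuple[float, float, float] = (75.0, 75.0, 75.0)
    food_color: tuple[float, float, float] = (120.0, 45.0, 40.0)
    orbit_distance_cm: float = 42.0
    elevation_deg: float = 22.0
    orbit_start_deg: float = 0.0
    n_views: int = 6


class PipelineConfig(_Block):
    camera: CameraBlock = CameraBlock()
    cascade: CascadeBlock = CascadeBlock()
    grid: GridBlock = GridBlock()
    calibration: CalibrationBlock = CalibrationBlock()
    reconstruction: ReconstructionBlock = ReconstructionBlock()
    synth: SynthBlock = SynthBlock()

    # -- domain object builders --------------------------------------------

    def to_camera(self) -> CameraModel:
        c = self.camera
        return CameraModel(c.width, c.height, c.fov_deg, c.cx_shift_cm,
                           c.cy_shift_cm, c.y_axis_factor)

    def to_cascade(self) -> MaskCascadeConfig:
        return MaskCascadeConfig(**self.cascade.model_dump())

    def to_grid(self) -> GridConfig:
        return GridConfig(**self.grid.model_dump())

    def scene_spec(self, surface: str = "plane", params: dict | None = None,
                   seed: int = 0, **overrides) -> SceneSpec:
        s = self.synth.model_dump()
        s.pop("n_views")
        s.update(overrides)
        return SceneSpec(surface=surface, params=params or {}, seed=seed,
                         camera=self.to_camera(),
                         dot_rows=self.grid.rows, dot_cols=self.grid.cols, **s)

    def calibration_depths(self):
        c = self.calibration
        n = int(round((c.depth_max_cm - c.depth_min_cm) / c.depth_step_cm)) + 1
        return [c.depth_min_cm + k * c.depth_step_cm for k in range(n)]

    # -- persistence ---------------------------------------------------------

    def to_canonical_json(self) -> str:
        return json.dumps(self.model_dump(), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical_json().encode()).hexdigest()[:16]

    def save(self, path):
        p = Path(path)
        if p.suffix in (".yaml", ".yml"):
            p.write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))
        else:
            p.write_text(json.dumps(self.model_dump(), indent=1))


def load_config(path=None) -> PipelineConfig:
    """Load a YAML/JSON pipeline config; None gives the defaults."""
    if path is None:
        return PipelineConfig()
    p = Path(path)
    text = p.read_text()
    data = yaml.safe_load(text) if p.suffix in (".yaml", ".yml") else json.loads(text)
    return PipelineConfig.model_validate(data or {})
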