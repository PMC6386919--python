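"""Coordinate conventions, triangulation and pixel/world conversion.

Camera-centred world frame: origin at the optical centre, z along the
viewing axis (positive away from the camera), units centimetres.  Pixel
origin is the top-left corner, 0-based, x rightward, y downward.

A structured-light range is recovered by the law of sines from the
camera-projector baseline |OL| and the two triangle angles::

    |PO| = |OL| * sin(PLO) / sin(LPO)

Pixel coordinates convert to world coordinates through the horizontal
field of view theta::

    x_ratio = (x_C - x_d/2) / (x_d/2)
    x_E = tan(theta/2) * z_E * x_ratio + C_x
    y_E = f_y * tan(theta/2) * z_E * y_ratio + C_y

where ``f_y`` defaults to 2/3 (a 3:2 sensor; override for other aspect
ratios) and (C_x, C_y) are device shifts determined during calibration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SlvolError",
    "InvalidGeometryError",
    "CameraModel",
    "TriangulationSetup",
    "WorldPoint",
    "triangulate_range",
    "pixel_ratio",
    "pixel_to_world",
    "world_to_pixel",
]


class SlvolError(Exception):
    """Base class for pipeline errors."""


class InvalidGeometryError(SlvolError):
    """Degenerate or out-of-domain geometric configuration."""


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera described by image size and horizontal field of view.

    ``y_axis_factor`` scales the vertical half-angle tangent relative to
    the horizontal one; the default 2/3 matches a 3:2 sensor.
    """

    image_width_px: int
    image_height_px: int
    fov_horizontal_deg: float
    cx_shift_cm: float = 0.0
    cy_shift_cm: float = 0.0
    y_axis_factor: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise InvalidGeometryError("image dimensions must be positive")
        if not 0.0 < self.fov_horizontal_deg < 180.0:
            raise InvalidGeometryError("fov_horizontal_deg must be in (0, 180)")
        if self.y_axis_factor <= 0:
            raise InvalidGeometryError("y_axis_factor must be positive")

    @property
    def tan_half_fov(self) -> float:
        return math.tan(math.radians(self.fov_horizontal_deg) / 2.0)

    def to_json_dict(self) -> dict:
        return {
            "width": self.image_width_px,
            "height": self.image_height_px,
            "fov_deg": self.fov_horizontal_deg,
            "cx_shift_cm": self.cx_shift_cm,
            "cy_shift_cm": self.cy_shift_cm,
            "y_axis_factor": self.y_axis_factor,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "CameraModel":
        return cls(
            image_width_px=int(d["width"]),
            image_height_px=int(d["height"]),
            fov_horizontal_deg=float(d["fov_deg"]),
            cx_shift_cm=float(d.get("cx_shift_cm", 0.0)),
            cy_shift_cm=float(d.get("cy_shift_cm", 0.0)),
            y_axis_factor=float(d.get("y_axis_factor", 2.0 / 3.0)),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict())

    @classmethod
    def from_json(cls, s: str) -> "CameraModel":
        return cls.from_json_dict(json.loads(s))


@dataclass(frozen=True)
class TriangulationSetup:
    """Law-of-sines triangle: baseline |OL| plus the two angles (degrees)."""

    baseline_cm: float
    angle_at_laser_deg: float   # angle PLO, at the projector
    angle_at_point_deg: float   # angle LPO, at the surface point

    def __post_init__(self) -> None:
        if self.baseline_cm <= 0:
            raise InvalidGeometryError("baseline_cm must be positive")
        for a in (self.angle_at_laser_deg, self.angle_at_point_deg):
            if not 0.0 < a < 180.0:
                raise InvalidGeometryError("angles must lie in (0, 180) degrees")


@dataclass(frozen=True)
class WorldPoint:
    """Point in the camera-centred frame, centimetres."""

    x_cm: float
    y_cm: float
    z_cm: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x_cm, self.y_cm, self.z_cm], dtype=float)


def triangulate_range(setup: TriangulationSetup) -> float:
    """Range |PO| from the triangulation triangle, in centimetres."""
    s_point = math.sin(math.radians(setup.angle_at_point_deg))
    if abs(s_point) < 1e-300:
        raise InvalidGeometryError("sin(angle_at_point) vanishes")
    return setup.baseline_cm * math.sin(math.radians(setup.angle_at_laser_deg)) / s_point


def pixel_ratio(coord_px, extent_px):
    """Map a pixel coordinate to the symmetric ratio in [-1, 1].

    The image centre maps to 0, the left/top edge to -1.
    """
    extent = float(extent_px)
    if extent <= 0:
        raise InvalidGeometryError("image extent must be positive")
    half = extent / 2.0
    return (np.asarray(coord_px, dtype=float) - half) / half


def pixel_to_world(x_px, y_px, depth_cm, cam: CameraModel):
    """Convert sub-pixel image positions at known depth to world coordinates.

    Returns an array of shape (..., 3) in centimetres.  Scalar inputs give
    shape (3,).
    """
    depth = np.asarray(depth_cm, dtype=float)
    if np.any(depth <= 0):
        raise InvalidGeometryError("depth_cm must be positive")
    xr = pixel_ratio(x_px, cam.image_width_px)
    yr = pixel_ratio(y_px, cam.image_height_px)
    t = cam.tan_half_fov
    x = t * depth * xr + cam.cx_shift_cm
    y = cam.y_axis_factor * t * depth * yr + cam.cy_shift_cm
    z = np.broadcast_to(depth, x.shape).astype(float)
    return np.stack([x, y, np.array(z, copy=True)], axis=-1)


def world_to_pixel(points_cm, cam: CameraModel):
    """Project camera-frame points (..., 3) to sub-pixel image coordinates.

    Exact inverse of :func:`pixel_to_world`; used by the synthetic renderer.
    Returns (x_px, y_px) arrays; points must have positive z.
    """
    p = np.asarray(points_cm, dtype=float)
    x, y, z = p[..., 0], p[..., 1], p[..., 2]
    if np.any(z <= 0):
        raise InvalidGeometryError("points must lie in front of the camera")
    t = cam.tan_half_fov
    xr = (x - cam.cx_shift_cm) / (t * z)
    yr = (y - cam.cy_shift_cm) / (cam.y_axis_factor * t * z)
    x_px = (xr + 1.0) * cam.image_width_px / 2.0
    y_px = (yr + 1.0) * cam.image_height_px / 2.0
    return x_px, y_px
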