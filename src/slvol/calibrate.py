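"""Structured-light calibration from planar image stacks at known depths.

For every grid index (i, j) the pixel position of its dot is collected
across the stack, giving a trajectory (depth, x_px, y_px) that is close
to a straight pixel-space segment whose parameterisation in depth is the
depth cue.  Scan-time lookup projects a dot's pixel position onto the
stored polyline and interpolates depth linearly between the bracketing
calibration samples, which tolerates the mild 1/z nonlinearity of the
true trajectory.  A straight-line least-squares fit and its residuals
are stored per index as a quality diagnostic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .detect import MaskCascadeConfig, detect_dots
from .geometry import CameraModel, SlvolError
from .gridindex import GridConfig, index_dots

__all__ = [
    "CalibrationFailedError",
    "UncalibratedDotError",
    "Trajectory",
    "CalibrationModel",
    "build_calibration",
    "depth_lookup",
    "validate_calibration",
]

logger = logging.getLogger("slvol.calibrate")


class CalibrationFailedError(SlvolError):
    pass


class UncalibratedDotError(SlvolError):
    pass


@dataclass
class Trajectory:
    """Per-index dot trajectory: samples sorted by depth + line fit."""

    depths: np.ndarray    # (n,), strictly increasing
    xy: np.ndarray        # (n, 2) pixel positions
    line_point: np.ndarray = field(default=None)
    line_dir: np.ndarray = field(default=None)
    max_residual_px: float = 0.0

    def fit_line(self):
        c = self.xy.mean(axis=0)
        d = self.xy - c
        if len(self.xy) == 2:
            v = d[1] - d[0]
        else:
            _, _, vt = np.linalg.svd(d, full_matrices=False)
            v = vt[0]
        n = np.linalg.norm(v)
        v = v / n if n > 0 else np.array([1.0, 0.0])
        self.line_point = c
        self.line_dir = v
        perp = d - np.outer(d @ v, v)
        self.max_residual_px = float(np.linalg.norm(perp, axis=1).max())


@dataclass
class CalibrationModel:
    trajectories: dict                 # (i, j) -> Trajectory
    depth_range_cm: tuple
    camera: CameraModel
    warnings: list = field(default_factory=list)

    # -- persistence --------------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "depth_range_cm": list(self.depth_range_cm),
            "camera": self.camera.to_json_dict(),
            "warnings": self.warnings,
            "trajectories": [
                {
                    "i": int(i), "j": int(j),
                    "depths": t.depths.tolist(),
                    "x": t.xy[:, 0].tolist(),
                    "y": t.xy[:, 1].tolist(),
                    "max_residual_px": t.max_residual_px,
                }
                for (i, j), t in sorted(self.trajectories.items())
            ],
        }

    def save(self, path):
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1))

    @classmethod
    def from_json_dict(cls, d: dict) -> "CalibrationModel":
        trajectories = {}
        for rec in d["trajectories"]:
            t = Trajectory(
                depths=np.asarray(rec["depths"], float),
                xy=np.stack([rec["x"], rec["y"]], axis=-1).astype(float),
            )
            t.fit_line()
            trajectories[(rec["i"], rec["j"])] = t
        return cls(
            trajectories=trajectories,
            depth_range_cm=tuple(d["depth_range_cm"]),
            camera=CameraModel.from_json_dict(d["camera"]),
            warnings=list(d.get("warnings", [])),
        )

    @classmethod
    def load(cls, path) -> "CalibrationModel":
        return cls.from_json_dict(json.loads(Path(path).read_text()))


def build_calibration(stack, cfg: MaskCascadeConfig | None = None,
                      grid_cfg: GridConfig | None = None,
                      camera: CameraModel | None = None,
                      monotone_tol_px: float = 1.0) -> CalibrationModel:
    """Build per-index trajectories from a list of (image, depth_cm) pairs.

    Images whose grid cannot be detected/indexed are skipped with a
    warning; indices whose pixel displacement is not monotone in depth
    (beyond a small tolerance) are rejected as detection failures.
    """
    cfg = cfg or MaskCascadeConfig()
    grid_cfg = grid_cfg or GridConfig()
    camera = camera or CameraModel(720, 480, 66.0)
    stack = list(stack)
    if len(stack) < 2:
        raise CalibrationFailedError("need at least 2 calibration depths")

    warnings: list[str] = []
    samples: dict[tuple, list] = {}
    usable = 0
    for image, depth in stack:
        res = detect_dots(image, cfg)
        if res.center is None:
            warnings.append(f"depth {depth}: no centre dot; image skipped")
            logger.warning("calibration image at %s cm skipped (no centre)", depth)
            continue
        grid = index_dots(res.dots, grid_cfg)
        usable += 1
        for key, dot in grid.dots.items():
            samples.setdefault(key, []).append((float(depth), dot.x_px, dot.y_px))

    if usable < 2:
        raise CalibrationFailedError("fewer than 2 usable calibration depths")

    trajectories = {}
    for key, rows in samples.items():
        rows.sort(key=lambda r: r[0])
        depths = np.array([r[0] for r in rows])
        xy = np.array([[r[1], r[2]] for r in rows])
        if len(rows) < 2 or np.any(np.diff(depths) <= 0):
            warnings.append(f"index {key}: fewer than 2 distinct depths; dropped")
            continue
        # monotone displacement check along the dominant direction
        span = xy[-1] - xy[0]
        ns = np.linalg.norm(span)
        if ns == 0:
            warnings.append(f"index {key}: degenerate trajectory; dropped")
            continue
        proj = (xy - xy[0]) @ (span / ns)
        if np.any(np.diff(proj) < -monotone_tol_px):
            warnings.append(f"index {key}: non-monotone trajectory; dropped")
            continue
        t = Trajectory(depths=depths, xy=xy)
        t.fit_line()
        trajectories[key] = t

    if not trajectories:
        raise CalibrationFailedError("no usable trajectories")
    all_depths = np.concatenate([t.depths for t in trajectories.values()])
    model = CalibrationModel(
        trajectories=trajectories,
        depth_range_cm=(float(all_depths.min()), float(all_depths.max())),
        camera=camera,
        warnings=warnings,
    )
    return model


def depth_lookup(model: CalibrationModel, index, dot_px, *, with_flag=False):
    """Depth (cm) of a dot of known grid index from its pixel position.

    Projects the position onto the index's calibrated polyline and
    interpolates depth between the bracketing samples; positions beyond
    the calibrated span clamp to the nearest end (flagged when
    ``with_flag``).
    """
    key = (int(index[0]), int(index[1]))
    t = model.trajectories.get(key)
    if t is None:
        raise UncalibratedDotError(f"index {key} missing from calibration model")
    q = np.asarray(dot_px, float)
    p = t.xy
    if len(p) == 1:
        z = float(t.depths[0])
        return (z, True) if with_flag else z
    seg = p[1:] - p[:-1]
    seglen2 = np.sum(seg * seg, axis=1)
    seglen2[seglen2 == 0] = 1e-300
    s = np.sum((q - p[:-1]) * seg, axis=1) / seglen2
    s_clip = np.clip(s, 0.0, 1.0)
    foot = p[:-1] + s_clip[:, None] * seg
    d2 = np.sum((q - foot) ** 2, axis=1)
    k = int(np.argmin(d2))
    z = float(t.depths[k] + s_clip[k] * (t.depths[k + 1] - t.depths[k]))
    clamped = bool((k == 0 and s[k] < 0) or (k == len(seg) - 1 and s[k] > 1))
    return (z, clamped) if with_flag else z


def validate_calibration(model: CalibrationModel, holdout, *,
                         cfg: MaskCascadeConfig | None = None,
                         grid_cfg: GridConfig | None = None,
                         centroid_noise_px: float = 0.0,
                         rng=None) -> dict:
    """Depth-recovery accuracy on held-out planar frames of known depth.

    Runs detection + indexing on each frame, optionally perturbs the
    centroids with Gaussian pixel noise, looks up depth per dot and
    reports ``accuracy = 100 * (1 - mean relative depth error)``.
    """
    holdout = list(holdout)
    if not holdout:
        raise CalibrationFailedError("empty holdout set")
    if centroid_noise_px > 0 and rng is None:
        rng = np.random.default_rng(0)
    cfg = cfg or MaskCascadeConfig()
    grid_cfg = grid_cfg or GridConfig()
    errors = []
    per_frame = []
    for image, depth in holdout:
        res = detect_dots(image, cfg)
        if res.center is None:
            per_frame.append({"depth_cm": depth, "n_dots": 0})
            continue
        grid = index_dots(res.dots, grid_cfg)
        frame_err = []
        for key, dot in grid.dots.items():
            if key not in model.trajectories:
                continue
            pos = np.array([dot.x_px, dot.y_px])
            if centroid_noise_px > 0:
                pos = pos + rng.normal(0.0, centroid_noise_px, 2)
            z = depth_lookup(model, key, pos)
            frame_err.append(abs(z - depth) / depth)
        errors.extend(frame_err)
        per_frame.append(
            {"depth_cm": float(depth), "n_dots": len(frame_err),
             "mean_rel_err": float(np.mean(frame_err)) if frame_err else None}
        )
    if not errors:
        raise CalibrationFailedError("no dots could be evaluated on the holdout")
    mean_rel = float(np.mean(errors))
    return {
        "accuracy_pct": 100.0 * (1.0 - mean_rel),
        "mean_relative_depth_error": mean_rel,
        "n_dots": len(errors),
        "per_frame": per_frame,
    }
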