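"""Synthetic laser-grid scene renderer and IMU trace generator.

Generates everything the pipeline consumes without hardware: planar
calibration stacks at known depths, multi-view food scans with analytic
ground-truth volume, and accelerometer/gyroscope traces with known quiet
windows.  The projector is modelled as a pinhole ray fan: an 11 x 11 grid
of rays with fixed angular pitch, emitted from a point offset from the
camera (the device's folded mirror is absorbed into the offset plus a
small toe-in so the centre dot crosses the optical axis at working
distance).  Dots are rendered as flat-top super-Gaussian splats of a
saturated green laser colour alpha-blended over the scene (the flat core
mimics an overexposed laser spot); the centre dot is brighter,
and optional dimmer "reflection" satellites and Gaussian pixel noise are
added.  Every frame is bit-reproducible given the scene seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon

from .geometry import CameraModel, SlvolError, world_to_pixel

__all__ = [
    "InvalidSceneError",
    "SceneSpec",
    "Pose",
    "look_at",
    "TrueDot",
    "FrameRender",
    "CalibrationStack",
    "Scan",
    "SensorTrace",
    "render_frame",
    "render_calibration_stack",
    "render_scan",
    "add_reflections",
    "simulate_imu",
    "write_calibration_stack",
    "write_scan",
    "load_image",
]

_GRAVITY = 9.81  # m s^-2


class InvalidSceneError(SlvolError):
    """Scene description violates its preconditions."""


# ---------------------------------------------------------------------------
# poses


@dataclass
class Pose:
    """Rigid camera pose: ``world = R @ cam + t``."""

    R: np.ndarray
    t: np.ndarray

    def cam_to_world(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, float) @ self.R.T + self.t

    def world_to_cam(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, float) - self.t) @ self.R

    def to_dict(self) -> dict:
        return {"R": self.R.tolist(), "t": self.t.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Pose":
        return cls(R=np.asarray(d["R"], float), t=np.asarray(d["t"], float))

    @classmethod
    def identity(cls) -> "Pose":
        return cls(R=np.eye(3), t=np.zeros(3))


def look_at(eye, target, up=(0.0, 0.0, 1.0)) -> Pose:
    """Pose with the optical (+z) axis from ``eye`` toward ``target``.

    Camera x points rightward, y downward (matching the pixel convention).
    """
    eye = np.asarray(eye, float)
    z = np.asarray(target, float) - eye
    nz = np.linalg.norm(z)
    if nz < 1e-12:
        raise InvalidSceneError("eye and target coincide")
    z = z / nz
    x = np.cross(z, np.asarray(up, float))
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        x = np.cross(z, np.array([0.0, 1.0, 0.0]))
        nx = np.linalg.norm(x)
    x = x / nx
    y = np.cross(z, x)
    return Pose(R=np.stack([x, y, z], axis=1), t=eye)


# ---------------------------------------------------------------------------
# surfaces


class _Surface:
    volume_cm3: float | None = None
    lookat_height: float = 0.0

    def intersect(self, origins: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        """First positive ray parameter per ray, ``inf`` on miss."""
        raise NotImplementedError

    def sample_points(self) -> np.ndarray:
        """Surface samples used to rasterise the silhouette."""
        raise NotImplementedError


class Ellipsoid(_Surface):
    """Axis-aligned ellipsoid resting on the table (z = 0) plane."""

    def __init__(self, a: float, b: float, c: float, center_xy=(0.0, 0.0)):
        if min(a, b, c) <= 0:
            raise InvalidSceneError("ellipsoid semi-axes must be positive")
        self.semi = np.array([a, b, c], float)
        self.center = np.array([center_xy[0], center_xy[1], c], float)
        self.volume_cm3 = 4.0 / 3.0 * math.pi * a * b * c
        self.lookat_height = c

    def _roots(self, origins, dirs):
        q = (origins - self.center) / self.semi
        dd = dirs / self.semi
        a = np.sum(dd * dd, axis=-1)
        b = 2.0 * np.sum(q * dd, axis=-1)
        c = np.sum(q * q, axis=-1) - 1.0
        disc = b * b - 4 * a * c
        ok = disc >= 0
        sq = np.sqrt(np.where(ok, disc, 0.0))
        t1 = (-b - sq) / (2 * a)
        t2 = (-b + sq) / (2 * a)
        return ok, t1, t2

    def intersect(self, origins, dirs):
        ok, t1, t2 = self._roots(origins, dirs)
        t = np.where(ok & (t1 > 1e-9), t1, np.where(ok & (t2 > 1e-9), t2, np.inf))
        return t

    def sample_points(self):
        th = np.linspace(0, 2 * math.pi, 64, endpoint=False)
        ph = np.linspace(1e-3, math.pi - 1e-3, 32)
        T, P = np.meshgrid(th, ph)
        pts = np.stack(
            [
                self.semi[0] * np.sin(P) * np.cos(T),
                self.semi[1] * np.sin(P) * np.sin(T),
                self.semi[2] * np.cos(P),
            ],
            axis=-1,
        ).reshape(-1, 3)
        return pts + self.center


class Hemisphere(_Surface):
    """Upper half-ball dome of radius r sitting on the table."""

    def __init__(self, radius: float, center_xy=(0.0, 0.0)):
        if radius <= 0:
            raise InvalidSceneError("hemisphere radius must be positive")
        self.r = float(radius)
        self.center = np.array([center_xy[0], center_xy[1], 0.0], float)
        self.volume_cm3 = 2.0 / 3.0 * math.pi * radius**3
        self.lookat_height = radius / 2.0

    def intersect(self, origins, dirs):
        q = origins - self.center
        a = np.sum(dirs * dirs, axis=-1)
        b = 2.0 * np.sum(q * dirs, axis=-1)
        c = np.sum(q * q, axis=-1) - self.r**2
        disc = b * b - 4 * a * c
        ok = disc >= 0
        sq = np.sqrt(np.where(ok, disc, 0.0))
        out = np.full(b.shape, np.inf)
        for tt in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
            z = origins[..., 2] + tt * dirs[..., 2]
            good = ok & (tt > 1e-9) & (z >= -1e-9) & (tt < out)
            out = np.where(good, tt, out)
        return out

    def sample_points(self):
        th = np.linspace(0, 2 * math.pi, 64, endpoint=False)
        ph = np.linspace(0, math.pi / 2, 17)
        T, P = np.meshgrid(th, ph)
        pts = np.stack(
            [
                self.r * np.sin(P) * np.cos(T),
                self.r * np.sin(P) * np.sin(T),
                self.r * np.cos(P),
            ],
            axis=-1,
        ).reshape(-1, 3)
        return pts + self.center


class Box(_Surface):
    """Axis-aligned box of full dimensions (lx, ly, lz) on the table."""

    def __init__(self, lx: float, ly: float, lz: float, center_xy=(0.0, 0.0)):
        if min(lx, ly, lz) <= 0:
            raise InvalidSceneError("box dimensions must be positive")
        self.half = np.array([lx, ly, lz], float) / 2.0
        self.center = np.array([center_xy[0], center_xy[1], lz / 2.0], float)
        self.volume_cm3 = lx * ly * lz
        self.lookat_height = lz / 2.0

    def intersect(self, origins, dirs):
        lo = self.center - self.half
        hi = self.center + self.half
        with np.errstate(divide="ignore", invalid="ignore"):
            t_lo = (lo - origins) / dirs
            t_hi = (hi - origins) / dirs
        t_near = np.nanmax(np.minimum(t_lo, t_hi), axis=-1)
        t_far = np.nanmin(np.maximum(t_lo, t_hi), axis=-1)
        hit = (t_near <= t_far) & (t_far > 1e-9)
        t = np.where(t_near > 1e-9, t_near, t_far)
        return np.where(hit, t, np.inf)

    def sample_points(self):
        # corners + edge midpoints are enough for the convex silhouette hull
        g = np.array(np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1])).reshape(3, -1).T
        g = g[np.max(np.abs(g), axis=1) == 1]
        return self.center + g * self.half


class FrontoPlane(_Surface):
    """Plane perpendicular to the camera axis at a given depth (calibration)."""

    def __init__(self, depth_cm: float):
        if depth_cm <= 0:
            raise InvalidSceneError("plane depth must be positive")
        self.depth = float(depth_cm)

    def intersect(self, origins, dirs):
        dz = dirs[..., 2]
        with np.errstate(divide="ignore"):
            t = (self.depth - origins[..., 2]) / dz
        return np.where((dz > 1e-12) & (t > 0), t, np.inf)


class Table(_Surface):
    """The supporting plane z = 0 in the world frame."""

    def intersect(self, origins, dirs):
        dz = dirs[..., 2]
        with np.errstate(divide="ignore"):
            t = -origins[..., 2] / dz
        return np.where((np.abs(dz) > 1e-12) & (t > 1e-9), t, np.inf)


_SURFACES = ("plane", "ellipsoid", "hemisphere", "box", "composite")


# ---------------------------------------------------------------------------
# scene specification


@dataclass
class SceneSpec:
    """Parametric synthetic scene with analytic ground truth.

    ``params`` carries the shape parameters: ``axes`` (ellipsoid semi-axes),
    ``radius`` (hemisphere), ``dims`` (box full dimensions) or ``items``
    (composite: list of dicts with ``surface``/params/``offset``/``color``).
    """

    surface: str = "plane"
    params: dict = field(default_factory=dict)
    dot_rows: int = 11
    dot_cols: int = 11
    pitch_deg: float = 2.2
    laser_offset_cm: tuple = (4.0, 0.0, 0.0)
    toe_cross_cm: float = 35.0
    dot_sigma_px: float = 2.5
    dot_green: float = 230.0
    dot_mix: float = 0.97
    center_dot_gain: float = 1.5
    satellite_green_factor: float = 0.913
    gaussian_sigma: float = 2.0
    reflection_count: int = 0
    background_color: tuple = (75.0, 75.0, 75.0)
    food_color: tuple = (120.0, 45.0, 40.0)
    orbit_distance_cm: float = 42.0
    elevation_deg: float = 22.0
    orbit_start_deg: float = 0.0
    camera: CameraModel = field(
        default_factory=lambda: CameraModel(720, 480, 66.0)
    )
    seed: int = 0

    def __post_init__(self):
        if self.surface not in _SURFACES:
            raise InvalidSceneError(f"unknown surface {self.surface!r}")
        if self.center_dot_gain <= 1.0:
            raise InvalidSceneError("center_dot_gain must exceed 1")
        if self.dot_rows < 1 or self.dot_cols < 1:
            raise InvalidSceneError("grid must have at least one dot")

    # -- laser geometry -----------------------------------------------------

    def laser_rays(self):
        """Grid indices, camera-frame origin and unit directions of the fan."""
        half_i = (self.dot_cols - 1) // 2
        half_j = (self.dot_rows - 1) // 2
        ii, jj = np.meshgrid(
            np.arange(-half_i, self.dot_cols - half_i),
            np.arange(-half_j, self.dot_rows - half_j),
            indexing="ij",
        )
        ii = ii.ravel()
        jj = jj.ravel()
        off = np.asarray(self.laser_offset_cm, float)
        sx = -off[0] / self.toe_cross_cm
        sy = -off[1] / self.toe_cross_cm
        a = math.radians(self.pitch_deg)
        dirs = np.stack(
            [np.tan(ii * a) + sx, np.tan(jj * a) + sy, np.ones_like(ii, float)],
            axis=-1,
        )
        dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
        return ii, jj, off, dirs

    def make_objects(self):
        """List of (surface, rgb colour) for the food items; [] for plane."""
        p = self.params
        if self.surface == "plane":
            return []
        if self.surface == "ellipsoid":
            a, b, c = p.get("axes", (5.0, 4.0, 3.0))
            return [(Ellipsoid(a, b, c), tuple(self.food_color))]
        if self.surface == "hemisphere":
            return [(Hemisphere(p.get("radius", 5.0)), tuple(self.food_color))]
        if self.surface == "box":
            lx, ly, lz = p.get("dims", (6.0, 6.0, 4.0))
            return [(Box(lx, ly, lz), tuple(self.food_color))]
        # composite
        out = []
        for item in p.get("items", []):
            kind = item["surface"]
            off = tuple(item.get("offset", (0.0, 0.0)))
            color = tuple(item.get("color", self.food_color))
            if kind == "ellipsoid":
                a, b, c = item["axes"]
                out.append((Ellipsoid(a, b, c, off), color))
            elif kind == "hemisphere":
                out.append((Hemisphere(item["radius"], off), color))
            elif kind == "box":
                lx, ly, lz = item["dims"]
                out.append((Box(lx, ly, lz, off), color))
            else:
                raise InvalidSceneError(f"unknown composite item {kind!r}")
        if not out:
            raise InvalidSceneError("composite scene needs at least one item")
        return out

    @property
    def true_volume_cm3(self):
        objs = self.make_objects()
        if not objs:
            return None
        return float(sum(s.volume_cm3 for s, _ in objs))


# ---------------------------------------------------------------------------
# rendering


@dataclass
class TrueDot:
    """Ground-truth record of one rendered laser dot."""

    i: int
    j: int
    x_px: float
    y_px: float
    depth_cm: float
    cam_xyz: np.ndarray
    world_xyz: np.ndarray
    on_object: bool
    is_center: bool

    def to_dict(self):
        return {
            "i": int(self.i),
            "j": int(self.j),
            "x_px": float(self.x_px),
            "y_px": float(self.y_px),
            "depth_cm": float(self.depth_cm),
            "cam_xyz": [float(v) for v in self.cam_xyz],
            "world_xyz": [float(v) for v in self.world_xyz],
            "on_object": bool(self.on_object),
            "is_center": bool(self.is_center),
        }


@dataclass
class FrameRender:
    image: np.ndarray           # (H, W, 3) float, 0..255
    dots: list                  # list[TrueDot], camera-visible only
    satellites: list            # list[(x_px, y_px)]
    pose: Pose


def _splat(img, x, y, sigma, alpha_peak, color, shape_exp=4):
    """Alpha-blend a flat-top (super-Gaussian) laser splat into the image.

    The flat saturated core mimics an overexposed laser spot; the default
    exponent 4 keeps the core wide enough to survive a strict saturation
    gate while the skirt still falls off smoothly.
    """
    h, w, _ = img.shape
    r = int(math.ceil(4 * sigma))
    x0, x1 = int(math.floor(x)) - r, int(math.floor(x)) + r + 1
    y0, y1 = int(math.floor(y)) - r, int(math.floor(y)) + r + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    xs = np.arange(x0c, x1c) - x
    ys = np.arange(y0c, y1c) - y
    r2 = (ys[:, None] ** 2 + xs[None, :] ** 2) / sigma**2
    g = np.exp(-0.5 * r2 ** (shape_exp / 2.0))
    a = (alpha_peak * g)[..., None]
    img[y0c:y1c, x0c:x1c] = img[y0c:y1c, x0c:x1c] * (1 - a) + a * np.asarray(color)


def add_reflections(image, dot_positions, k, rng=None, seed=None, *,
                    green=210.0, mix=0.97, sigma=2.0, r_min=4.0, r_max=8.0):
    """Add ``k`` dimmer satellite blobs adjacent to randomly chosen dots.

    Returns ``(image, satellites)`` where satellites is a list of (x, y)
    pixel positions.  ``k = 0`` returns the image untouched.
    """
    if k < 0:
        raise InvalidSceneError("reflection count must be non-negative")
    if k == 0 or len(dot_positions) == 0:
        return image, []
    if rng is None:
        rng = np.random.default_rng(seed)
    img = image
    sats = []
    pos = np.asarray(dot_positions, float)
    idx = rng.integers(0, len(pos), size=k)
    for parent in idx:
        ang = rng.uniform(0, 2 * math.pi)
        rad = rng.uniform(r_min, r_max)
        sx = pos[parent, 0] + rad * math.cos(ang)
        sy = pos[parent, 1] + rad * math.sin(ang)
        _splat(img, sx, sy, sigma, mix, (14.0, green, 14.0))
        sats.append((float(sx), float(sy)))
    return img, sats


def render_frame(spec: SceneSpec, pose: Pose, rng, *, cal_depth=None) -> FrameRender:
    """Render one frame: scene fill, laser dots, reflections, pixel noise."""
    cam = spec.camera
    h, w = cam.image_height_px, cam.image_width_px
    img = np.empty((h, w, 3), float)
    img[:] = np.asarray(spec.background_color, float)

    if cal_depth is not None:
        objects = []
        ground: _Surface = FrontoPlane(cal_depth)
    else:
        objects = spec.make_objects()
        ground = Table()

    # silhouettes, farthest first
    if objects:
        order = np.argsort(
            [-np.linalg.norm(s.center - pose.t) for s, _ in objects]
        )
        for k in order:
            surf, color = objects[k]
            pts_cam = pose.world_to_cam(surf.sample_points())
            pts_cam = pts_cam[pts_cam[:, 2] > 1e-6]
            if len(pts_cam) < 3:
                continue
            px, py = world_to_pixel(pts_cam, cam)
            from scipy.spatial import ConvexHull

            uv = np.stack([px, py], axis=-1)
            try:
                hull = ConvexHull(uv)
            except Exception:
                continue
            poly = uv[hull.vertices]
            rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=(h, w))
            img[rr, cc] = np.asarray(color, float)

    # laser dots
    ii, jj, origin_cam, dirs_cam = spec.laser_rays()
    o_w = pose.cam_to_world(origin_cam)
    d_w = dirs_cam @ pose.R.T
    t_best = ground.intersect(o_w[None, :], d_w)
    hit_obj = np.full(len(ii), False)
    for surf, _ in objects:
        t_s = surf.intersect(o_w[None, :], d_w)
        better = t_s < t_best
        t_best = np.where(better, t_s, t_best)
        hit_obj = np.where(better, True, hit_obj)

    dots: list[TrueDot] = []
    eye = pose.t
    for n in range(len(ii)):
        if not np.isfinite(t_best[n]):
            continue
        pw = o_w + t_best[n] * d_w[n]
        pc = pose.world_to_cam(pw)
        if pc[2] <= 0.5:
            continue
        # camera occlusion by any object
        view = pw - eye
        dist = np.linalg.norm(view)
        occluded = False
        for surf, _ in objects:
            t_occ = surf.intersect(eye[None, :], (view / dist)[None, :])[0]
            if t_occ < dist - 1e-4:
                occluded = True
                break
        if occluded:
            continue
        px, py = world_to_pixel(pc[None, :], cam)
        px, py = float(px[0]), float(py[0])
        if not (2.0 <= px <= w - 3.0 and 2.0 <= py <= h - 3.0):
            continue
        is_center = ii[n] == 0 and jj[n] == 0
        green = min(255.0, spec.dot_green * spec.center_dot_gain) if is_center else spec.dot_green
        _splat(img, px, py, spec.dot_sigma_px, spec.dot_mix, (14.0, green, 14.0))
        dots.append(
            TrueDot(
                i=int(ii[n]), j=int(jj[n]), x_px=px, y_px=py,
                depth_cm=float(pc[2]), cam_xyz=pc, world_xyz=pw,
                on_object=bool(hit_obj[n]), is_center=bool(is_center),
            )
        )

    sats = []
    if spec.reflection_count > 0 and dots:
        positions = [(d.x_px, d.y_px) for d in dots]
        img, sats = add_reflections(
            img, positions, spec.reflection_count, rng,
            green=spec.dot_green * spec.satellite_green_factor,
            mix=spec.dot_mix, sigma=spec.dot_sigma_px,
        )

    if spec.gaussian_sigma > 0:
        img += rng.normal(0.0, spec.gaussian_sigma, img.shape)
    np.clip(img, 0.0, 255.0, out=img)
    return FrameRender(image=img, dots=dots, satellites=sats, pose=pose)


# ---------------------------------------------------------------------------
# calibration stacks


@dataclass
class CalibrationStack:
    images: list          # list[np.ndarray]
    depths_cm: list       # list[float]
    truth: list           # list[list[TrueDot]] per image
    spec: SceneSpec


def render_calibration_stack(spec: SceneSpec, depths_cm) -> CalibrationStack:
    """Planar grid images at the given depths, camera at the origin."""
    if spec.surface != "plane":
        raise InvalidSceneError("calibration stacks require a plane surface")
    depths = [float(d) for d in depths_cm]
    if any(d <= 0 for d in depths):
        raise InvalidSceneError("depths must be positive")
    images, truth = [], []
    pose = Pose.identity()
    for k, d in enumerate(depths):
        rng = np.random.default_rng([spec.seed, k])
        fr = render_frame(spec, pose, rng, cal_depth=d)
        images.append(fr.image)
        truth.append(fr.dots)
    return CalibrationStack(images=images, depths_cm=depths, truth=truth, spec=spec)


# ---------------------------------------------------------------------------
# IMU traces


@dataclass
class SensorTrace:
    """Timestamped accelerometer and gyroscope samples (body frame)."""

    t: np.ndarray          # seconds, strictly increasing
    accel: np.ndarray      # (N, 3) m s^-2
    gyro: np.ndarray       # (N, 3) rad s^-1

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.accel = np.asarray(self.accel, float)
        self.gyro = np.asarray(self.gyro, float)
        if np.any(np.diff(self.t) <= 0):
            raise InvalidSceneError("trace timestamps must be strictly increasing")

    def to_csv(self, path):
        df = pd.DataFrame(
            {
                "t": self.t,
                "ax": self.accel[:, 0], "ay": self.accel[:, 1], "az": self.accel[:, 2],
                "gx": self.gyro[:, 0], "gy": self.gyro[:, 1], "gz": self.gyro[:, 2],
            }
        )
        df.to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path) -> "SensorTrace":
        df = pd.read_csv(path)
        return cls(
            t=df["t"].to_numpy(),
            accel=df[["ax", "ay", "az"]].to_numpy(),
            gyro=df[["gx", "gy", "gz"]].to_numpy(),
        )


def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3 - 2 * u)


def _yaw_profile(t, frame_times, yaws):
    """Piecewise smooth yaw: plateaus (zero rate) at every frame time."""
    yaw = np.full_like(t, yaws[0], dtype=float)
    for k in range(len(frame_times) - 1):
        t0, t1 = frame_times[k], frame_times[k + 1]
        u = _smoothstep((t - t0) / (t1 - t0))
        seg = (t >= t0) & (t < t1)
        yaw[seg] = yaws[k] + u[seg] * (yaws[k + 1] - yaws[k])
    yaw[t >= frame_times[-1]] = yaws[-1]
    return yaw


def _ou(rng, n, dt, tau=0.25, sigma=1.0):
    x = np.zeros((n, 3))
    k = math.exp(-dt / tau)
    s = sigma * math.sqrt(1 - k * k)
    noise = rng.normal(0.0, s, (n, 3))
    for idx in range(1, n):
        x[idx] = k * x[idx - 1] + noise[idx]
    return x


def simulate_imu(frame_times, yaws, elevation_deg, seed, *, fs=100.0,
                 duration=None, quiet_halfwidth=0.35, jitter_amp=0.8,
                 quiet_factor=0.05) -> SensorTrace:
    """Hand-held IMU trace: gravity + Ornstein-Uhlenbeck jitter, quiet
    windows centred on the frame timestamps, gyro consistent with the
    camera's orbit yaw profile."""
    frame_times = np.asarray(frame_times, float)
    yaws = np.asarray(yaws, float)
    if duration is None:
        duration = frame_times[-1] + frame_times[0]
    t = np.arange(0.0, duration, 1.0 / fs)
    rng = np.random.default_rng(seed)

    env = np.ones_like(t)
    for ft in frame_times:
        env[np.abs(t - ft) <= quiet_halfwidth] = quiet_factor

    yaw = _yaw_profile(t, frame_times, yaws)
    yaw_rate = np.gradient(yaw, t)

    el = math.radians(elevation_deg)
    # camera-to-world rotation per sample (orbit at fixed elevation)
    cy, sy = np.cos(yaw), np.sin(yaw)
    # body z (optical axis) points inward and down toward the target
    zb = np.stack([-np.cos(el) * cy, -np.cos(el) * sy, -np.sin(el) * np.ones_like(cy)], -1)
    up = np.array([0.0, 0.0, 1.0])
    xb = np.cross(zb, up)
    xb /= np.linalg.norm(xb, axis=-1, keepdims=True)
    yb = np.cross(zb, xb)

    g_world = np.array([0.0, 0.0, _GRAVITY])  # specific force, device at rest
    accel = np.stack(
        [xb @ g_world, yb @ g_world, zb @ g_world], axis=-1
    )
    accel += _ou(rng, len(t), 1.0 / fs, sigma=jitter_amp) * env[:, None]

    w_world = np.stack([np.zeros_like(yaw_rate), np.zeros_like(yaw_rate), yaw_rate], -1)
    gyro = np.stack(
        [np.sum(xb * w_world, -1), np.sum(yb * w_world, -1), np.sum(zb * w_world, -1)],
        axis=-1,
    )
    gyro += _ou(rng, len(t), 1.0 / fs, sigma=0.02) * env[:, None]
    return SensorTrace(t=t, accel=accel, gyro=gyro)


# ---------------------------------------------------------------------------
# scans


@dataclass
class Scan:
    frames: list             # list[np.ndarray]
    timestamps: np.ndarray   # one per frame, seconds
    poses: list              # list[Pose]
    trace: SensorTrace
    truth: list              # list[list[TrueDot]] per frame
    true_volume_cm3: float
    spec: SceneSpec


def render_scan(spec: SceneSpec, n_views: int) -> Scan:
    """Render an orbital scan: ``n_views`` frames circling the object,
    with an IMU trace whose quiet windows sit at the frame timestamps."""
    if n_views < 1:
        raise InvalidSceneError("n_views must be at least 1")
    objects = spec.make_objects()
    if not objects:
        raise InvalidSceneError("scan requires a surface with analytic volume")
    target_h = max(s.lookat_height for s, _ in objects)
    target = np.array([0.0, 0.0, target_h])
    el = math.radians(spec.elevation_deg)
    D = spec.orbit_distance_cm

    frame_times = 2.0 * np.arange(n_views) + 2.0
    yaws = (math.radians(spec.orbit_start_deg)
            + 2.0 * math.pi * np.arange(n_views) / n_views)

    frames, poses, truth = [], [], []
    for k in range(n_views):
        phi = yaws[k]
        eye = target + D * np.array(
            [math.cos(el) * math.cos(phi), math.cos(el) * math.sin(phi), math.sin(el)]
        )
        pose = look_at(eye, target)
        rng = np.random.default_rng([spec.seed, 1000 + k])
        fr = render_frame(spec, pose, rng)
        frames.append(fr.image)
        poses.append(pose)
        truth.append(fr.dots)

    trace = simulate_imu(
        frame_times, yaws, spec.elevation_deg,
        seed=np.random.SeedSequence([spec.seed, 5000]),
        duration=frame_times[-1] + 2.0,
    )
    return Scan(
        frames=frames, timestamps=frame_times, poses=poses, trace=trace,
        truth=truth, true_volume_cm3=spec.true_volume_cm3, spec=spec,
    )


def sample_scan_spec(index: int, entropy: int = 0, **overrides) -> SceneSpec:
    """Random food fixture for evaluation suites.

    Cycles ellipsoid / hemisphere / box; dimensions draw from the 2-8 cm
    scale (semi-axes for ellipsoids, radius for hemispheres, proportioned
    full dimensions for boxes).  ``index`` fixes the shape family and,
    with ``entropy``, the dimensions and render seed.
    """
    rng = np.random.default_rng([entropy, index, 77])
    shape = ("ellipsoid", "hemisphere", "box")[index % 3]
    if shape == "ellipsoid":
        ax = np.sort(np.round(rng.uniform(2.0, 8.0, 3), 1))[::-1]
        params = {"axes": tuple(float(v) for v in ax)}
    elif shape == "hemisphere":
        params = {"radius": round(float(rng.uniform(2.0, 8.0)), 1)}
    else:
        dims = np.round(rng.uniform(2.0, 8.0, 3) * np.array([1.6, 1.3, 0.8]), 1)
        params = {"dims": tuple(float(v) for v in dims)}
    seed = int(rng.integers(0, 2**31 - 1))
    kw = dict(surface=shape, params=params, seed=seed, reflection_count=3,
              orbit_start_deg=float(rng.uniform(0, 360)))
    kw.update(overrides)
    return SceneSpec(**kw)


# ---------------------------------------------------------------------------
# disk I/O


def _img_u8(img):
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG as float RGB in 0..255."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        return arr.astype(float)
    return arr[..., :3].astype(float)


def write_calibration_stack(stack: CalibrationStack, outdir) -> Path:
    """Write stack images + manifest CSV + ground-truth JSON; returns the
    manifest path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    gt = {}
    for img, d, dots in zip(stack.images, stack.depths_cm, stack.truth):
        name = f"depth_{d:07.2f}.png"
        iio.imwrite(out / name, _img_u8(img))
        rows.append({"filename": name, "depth_cm": d})
        gt[name] = [t.to_dict() for t in dots]
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    (out / "ground_truth.json").write_text(
        json.dumps({"camera": stack.spec.camera.to_json_dict(), "dots": gt}, indent=1)
    )
    return manifest


def write_scan(scan: Scan, outdir) -> Path:
    """Write scan frames, trace CSV and ground-truth JSON; returns outdir."""
    out = Path(outdir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    names = []
    for k, img in enumerate(scan.frames):
        name = f"frames/frame_{k:03d}.png"
        iio.imwrite(out / name, _img_u8(img))
        names.append(name)
    scan.trace.to_csv(out / "trace.csv")
    gt = {
        "true_volume_cm3": scan.true_volume_cm3,
        "frame_files": names,
        "frame_timestamps": [float(v) for v in scan.timestamps],
        "poses": [p.to_dict() for p in scan.poses],
        "camera": scan.spec.camera.to_json_dict(),
        "surface": scan.spec.surface,
        "seed": scan.spec.seed,
        "dots": {names[k]: [t.to_dict() for t in scan.truth[k]] for k in range(len(names))},
    }
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=1))
    return out
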