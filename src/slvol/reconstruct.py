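"""Frame selection, point-cloud construction, fusion and volume integration.

A scan is a set of frames circling the food plus an IMU trace.  The six
most stable frames (lowest windowed high-pass accelerometer RMS, one per
temporal segment) are pushed through the dot-detection and grid-indexing
stages; each indexed dot gets a depth from the calibration model and a
camera-frame 3D position, frames are transformed into a common world
frame by their poses and fused, the supporting plane is estimated from
the lowest band of points, and the volume is integrated as a 2.5D prism
sum over a Delaunay triangulation of the footprint — the surface is
treated as flat between the visible laser dots, so trapped air under the
food is counted, mirroring the device's stated flat-bottom limitation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError, cKDTree
from scipy.spatial.transform import Rotation

from .calibrate import CalibrationModel, UncalibratedDotError, depth_lookup
from .detect import MaskCascadeConfig, detect_dots
from .geometry import SlvolError, pixel_to_world
from .gridindex import GridConfig, impute_missing, index_dots
from .synth import Pose, SensorTrace

__all__ = [
    "InsufficientScanError",
    "PoseUnavailableError",
    "FramePoints",
    "PointCloud",
    "BottomPlane",
    "VolumeResult",
    "select_stable_frames",
    "frame_to_points",
    "fuse_frames",
    "estimate_bottom",
    "integrate_volume",
    "separate_touching_items",
    "integrate_gyro",
    "measure_scan",
    "write_ply",
]

logger = logging.getLogger("slvol.reconstruct")


class InsufficientScanError(SlvolError):
    pass


class PoseUnavailableError(SlvolError):
    pass


# ---------------------------------------------------------------------------
# frame selection


def select_stable_frames(trace: SensorTrace, frame_timestamps, k: int = 6,
                         *, window_s: float = 0.3, highpass_s: float = 0.5):
    """Pick the ``k`` most stable frames, one per temporal segment.

    The stability score is the RMS of the high-pass-filtered acceleration
    magnitude in a window around each frame timestamp.  Frames are split
    into ``k`` contiguous temporal segments; within each segment the
    minimum-score frame wins, score ties breaking toward the segment
    midpoint.  Returns strictly increasing frame indices.
    """
    ts = np.asarray(frame_timestamps, float)
    if k < 1:
        raise InsufficientScanError("k must be at least 1")
    if len(ts) < k:
        raise InsufficientScanError(f"only {len(ts)} frames for k={k}")
    order = np.argsort(ts)
    fs = 1.0 / float(np.median(np.diff(trace.t)))
    mag = np.linalg.norm(trace.accel, axis=1)
    win = max(3, int(round(highpass_s * fs)))
    hp = mag - ndimage.uniform_filter1d(mag, size=win, mode="nearest")

    scores = np.empty(len(ts))
    for n, t0 in enumerate(ts):
        sel = (trace.t >= t0 - window_s) & (trace.t <= t0 + window_s)
        scores[n] = math.sqrt(float(np.mean(hp[sel] ** 2))) if sel.any() else np.inf

    chosen = []
    for seg in np.array_split(order, k):
        seg_scores = scores[seg]
        best = seg_scores.min()
        tied = seg[seg_scores <= best + 1e-12]
        mid = (ts[seg[0]] + ts[seg[-1]]) / 2.0
        pick = tied[np.argmin(np.abs(ts[tied] - mid))]
        chosen.append(int(pick))
    return sorted(chosen)


# ---------------------------------------------------------------------------
# per-frame points


@dataclass
class FramePoints:
    frame_id: int
    points_cam: np.ndarray      # (N, 3) camera-frame positions, cm
    indices: np.ndarray         # (N, 2) grid indices
    imputed: np.ndarray         # (N,) bool
    on_food: np.ndarray = None  # (N,) bool; dots on the food vs background
    warnings: list = field(default_factory=list)


def classify_food_dots(image, positions, *, background_color=None,
                       color_tol: float = 30.0, r_in: float = 7.0,
                       r_out: float = 10.0) -> np.ndarray:
    """Flag dots lying on the food item rather than the background.

    Samples the mean colour of an annulus around each dot (outside the
    laser splat) and compares it with the background colour estimated
    from the image border.
    """
    img = np.asarray(image, float)
    h, w = img.shape[:2]
    if background_color is None:
        border = np.concatenate([img[:10].reshape(-1, 3), img[-10:].reshape(-1, 3),
                                 img[:, :10].reshape(-1, 3), img[:, -10:].reshape(-1, 3)])
        background_color = np.median(border, axis=0)
    bg = np.asarray(background_color, float)
    out = np.zeros(len(positions), bool)
    rr = int(math.ceil(r_out))
    for k, (x, y) in enumerate(positions):
        x0, x1 = max(int(x) - rr, 0), min(int(x) + rr + 1, w)
        y0, y1 = max(int(y) - rr, 0), min(int(y) + rr + 1, h)
        ys, xs = np.mgrid[y0:y1, x0:x1]
        d2 = (xs - x) ** 2 + (ys - y) ** 2
        ring = (d2 >= r_in**2) & (d2 <= r_out**2)
        if not ring.any():
            continue
        c = img[y0:y1, x0:x1][ring].mean(axis=0)
        out[k] = np.linalg.norm(c - bg) > color_tol
    return out


def frame_to_points(image, model: CalibrationModel, *,
                    cascade_cfg: MaskCascadeConfig | None = None,
                    grid_cfg: GridConfig | None = None,
                    impute: bool = True, frame_id: int = 0) -> FramePoints:
    """Detection -> indexing -> imputation -> depth lookup -> 3D points."""
    cascade_cfg = cascade_cfg or MaskCascadeConfig()
    grid_cfg = grid_cfg or GridConfig()
    empty = FramePoints(
        frame_id=frame_id, points_cam=np.zeros((0, 3)),
        indices=np.zeros((0, 2), int), imputed=np.zeros(0, bool),
        on_food=np.zeros(0, bool),
    )
    res = detect_dots(image, cascade_cfg)
    if res.center is None:
        empty.warnings.append("no centre dot detected; frame skipped")
        logger.warning("frame %d: no centre dot", frame_id)
        return empty
    grid = index_dots(res.dots, grid_cfg)
    if impute:
        grid = impute_missing(grid, grid_cfg)
    pts, idxs, imp, pix, warns = [], [], [], [], list(grid.warnings)
    for key, dot in grid.dots.items():
        try:
            z, clamped = depth_lookup(model, key, (dot.x_px, dot.y_px),
                                      with_flag=True)
        except UncalibratedDotError:
            continue
        if clamped:
            # outside the calibrated depth span: unmeasurable, not clampable
            continue
        pts.append(pixel_to_world(dot.x_px, dot.y_px, z, model.camera))
        idxs.append(key)
        imp.append(key in grid.imputed)
        pix.append((dot.x_px, dot.y_px))
    if not pts:
        empty.warnings.append("no calibrated dots in frame")
        return empty
    return FramePoints(
        frame_id=frame_id,
        points_cam=np.asarray(pts, float),
        indices=np.asarray(idxs, int),
        imputed=np.asarray(imp, bool),
        on_food=classify_food_dots(image, pix),
        warnings=warns,
    )


# ---------------------------------------------------------------------------
# fusion


@dataclass
class PointCloud:
    points: np.ndarray          # (M, 3) world frame, cm
    frame_ids: np.ndarray       # (M,)
    indices: np.ndarray         # (M, 2)
    imputed: np.ndarray         # (M,) bool
    on_food: np.ndarray = None  # (M,) bool, when known
    poses: list = field(default_factory=list)

    def __len__(self):
        return len(self.points)


def _refine_pose(src, dst, iters=10, radius=1.0):
    """Small rigid ICP of src onto dst (point-to-point, Kabsch updates)."""
    R = np.eye(3)
    t = np.zeros(3)
    tree = cKDTree(dst)
    cur = src.copy()
    for _ in range(iters):
        d, j = tree.query(cur, distance_upper_bound=radius)
        ok = np.isfinite(d)
        if ok.sum() < 3:
            break
        a = cur[ok]
        b = dst[j[ok]]
        ca, cb = a.mean(0), b.mean(0)
        H = (a - ca).T @ (b - cb)
        U, _, Vt = np.linalg.svd(H)
        D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
        Rk = Vt.T @ D @ U.T
        tk = cb - Rk @ ca
        cur = cur @ Rk.T + tk
        R = Rk @ R
        t = Rk @ t + tk
        if np.linalg.norm(tk) < 1e-4 and abs(np.trace(Rk) - 3) < 1e-8:
            break
    return R, t


def fuse_frames(frame_points, poses, *, merge_radius_cm: float = 0.5,
                refine: bool = False, refine_iters: int = 10) -> PointCloud:
    """Transform per-frame points into the world frame and deduplicate.

    Points from different frames that land within the merge radius (the
    overlapping edges of consecutive views) are averaged.  Optional rigid
    refinement nudges each frame onto the cloud accumulated so far.
    """
    frame_points = [fp for fp in frame_points]
    if not frame_points:
        raise InsufficientScanError("no frames to fuse")
    all_pts, all_fid, all_idx, all_imp, all_food = [], [], [], [], []
    acc = None
    for fp in frame_points:
        pose = poses.get(fp.frame_id) if isinstance(poses, dict) else (
            poses[fp.frame_id] if fp.frame_id < len(poses) else None
        )
        if pose is None:
            raise PoseUnavailableError(f"no pose for frame {fp.frame_id}")
        if len(fp.points_cam) == 0:
            continue
        w = pose.cam_to_world(fp.points_cam)
        if refine and acc is not None and len(acc) >= 3:
            Rk, tk = _refine_pose(w, np.asarray(acc), iters=refine_iters,
                                  radius=4 * merge_radius_cm)
            w = w @ Rk.T + tk
        all_pts.append(w)
        all_fid.append(np.full(len(w), fp.frame_id))
        all_idx.append(fp.indices)
        all_imp.append(fp.imputed)
        all_food.append(fp.on_food if fp.on_food is not None
                        else np.zeros(len(w), bool))
        acc = w if acc is None else np.vstack([acc, w])
    if not all_pts:
        return PointCloud(points=np.zeros((0, 3)), frame_ids=np.zeros(0, int),
                          indices=np.zeros((0, 2), int), imputed=np.zeros(0, bool),
                          on_food=np.zeros(0, bool),
                          poses=list(poses) if not isinstance(poses, dict) else poses)
    pts = np.vstack(all_pts)
    fid = np.concatenate(all_fid)
    idx = np.vstack(all_idx)
    imp = np.concatenate(all_imp)
    food = np.concatenate(all_food)

    # voxel-hash averaging at the merge radius
    if merge_radius_cm > 0:
        keys = np.round(pts / merge_radius_cm).astype(np.int64)
        _, inv, counts = np.unique(keys, axis=0, return_inverse=True,
                                   return_counts=True)
        order = np.argsort(inv, kind="stable")
        merged_pts = np.zeros((len(counts), 3))
        np.add.at(merged_pts, inv, pts)
        merged_pts /= counts[:, None]
        first = np.zeros(len(counts), int)
        seen = np.full(len(counts), -1)
        for pos_in, cell in zip(order, inv[order]):
            if seen[cell] < 0:
                seen[cell] = pos_in
        first = seen
        pts, fid, idx = merged_pts, fid[first], idx[first]
        merged_imp = np.zeros(len(counts), bool)
        np.logical_or.at(merged_imp, inv, imp)
        imp = merged_imp
        merged_food = np.zeros(len(counts), bool)
        np.logical_or.at(merged_food, inv, food)
        food = merged_food
    return PointCloud(points=pts, frame_ids=fid, indices=idx, imputed=imp,
                      on_food=food, poses=poses)


def clean_cloud(cloud: PointCloud, *, support_axis=(0.0, 0.0, 1.0),
                table_tol_cm: float = 0.75,
                food_link_cm: float = 2.5,
                food_min_links: int = 2) -> PointCloud:
    """Reject physically implausible points from a fused cloud.

    Background (non-food) points should lie on the support surface: a
    robust plane is fit to them (median-height slab, one refit) and
    background points farther than ``table_tol_cm`` from it — typically
    mis-indexed dots whose depth landed on the wrong trajectory — are
    dropped.  Food points must have at least ``food_min_links``
    neighbouring food points within ``food_link_cm``; isolated floaters
    are dropped.
    """
    pts = cloud.points
    if len(pts) < 8 or cloud.on_food is None:
        return cloud
    axis = np.asarray(support_axis, float)
    axis /= np.linalg.norm(axis)
    keep = np.ones(len(pts), bool)
    bg = ~cloud.on_food
    if bg.sum() >= 6:
        hb = pts[bg] @ axis
        # anchor at the low quantile: the table is the lowest coherent
        # background layer, and background may be contaminated by
        # misclassified item-edge points higher up
        anchor = np.quantile(hb, 0.05)
        slab = pts[bg][(hb >= anchor - table_tol_cm)
                       & (hb <= anchor + 2 * table_tol_cm)]
        plane = _fit_plane(slab, axis) if len(slab) >= 3 else None
        if plane is not None:
            d_all = np.abs((pts - plane.origin) @ plane.normal)
            keep[bg & (d_all > table_tol_cm)] = False
    food = cloud.on_food & keep
    if food.sum() >= food_min_links + 1:
        ft = cKDTree(pts[food])
        nlink = np.array([len(ft.query_ball_point(p, food_link_cm)) - 1
                          for p in pts[food]])
        drop = np.where(food)[0][nlink < food_min_links]
        keep[drop] = False
    return PointCloud(points=pts[keep], frame_ids=cloud.frame_ids[keep],
                      indices=cloud.indices[keep], imputed=cloud.imputed[keep],
                      on_food=cloud.on_food[keep], poses=cloud.poses)


# ---------------------------------------------------------------------------
# bottom plane and volume


@dataclass
class BottomPlane:
    origin: np.ndarray
    normal: np.ndarray          # unit, oriented toward the cloud
    low_confidence: bool = False

    def heights(self, pts) -> np.ndarray:
        return (np.asarray(pts, float) - self.origin) @ self.normal

    def to_dict(self):
        return {"origin": self.origin.tolist(), "normal": self.normal.tolist(),
                "low_confidence": self.low_confidence}


def _fit_plane(band, axis):
    """Least-squares plane height = a*u + b*v + c; None when degenerate."""
    e1 = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-9:
        e1 = np.cross(axis, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    U = np.stack([band @ e1, band @ e2, np.ones(len(band))], axis=1)
    try:
        coef, _, rank, _ = np.linalg.lstsq(U, band @ axis, rcond=None)
        if rank < 3:
            return None
    except np.linalg.LinAlgError:
        return None
    a, b, c = coef
    normal = axis - a * e1 - b * e2
    normal /= np.linalg.norm(normal)
    origin = band.mean(axis=0)
    origin = origin + (c + a * (origin @ e1) + b * (origin @ e2) - origin @ axis) * axis
    return BottomPlane(origin=origin, normal=normal)


def estimate_bottom(cloud: PointCloud, *, percentile: float = 5.0,
                    support_axis=(0.0, 0.0, 1.0),
                    refit_window_cm: float = 0.4) -> BottomPlane:
    """Plane through the lowest band of the cloud (the visible support).

    The lowest ``percentile`` of point heights along the support axis
    seeds a least-squares plane; because that band is the noisy lower
    tail of the support-surface points, the plane is then re-fit once on
    the full inlier slab within ``refit_window_cm`` of the seed plane,
    which recentres it on the support surface instead of under it.  A
    band spanning fewer than 3 grid indices (or a degenerate fit) is
    flagged low-confidence.
    """
    pts = np.asarray(cloud.points, float)
    if len(pts) == 0:
        raise InsufficientScanError("empty cloud")
    axis = np.asarray(support_axis, float)
    axis = axis / np.linalg.norm(axis)
    h = pts @ axis
    cut = np.quantile(h, percentile / 100.0)
    in_band = h <= cut + 1e-12
    band = pts[in_band]
    low_conf = False
    if cloud.indices is not None and len(cloud.indices) == len(pts):
        if len({tuple(r) for r in cloud.indices[in_band]}) < 3:
            low_conf = True
    if len(band) < 3:
        origin = pts[np.argmin(h)]
        return BottomPlane(origin=origin, normal=axis, low_confidence=True)
    # seed at the band's median height (robust to stray under-points),
    # fit the slab around it, then refit once on the plane's own inliers
    seed_h = float(np.median(band @ axis))
    slab = pts[np.abs(h - seed_h) <= max(refit_window_cm, 1e-9)]
    plane = _fit_plane(slab if len(slab) >= 3 else band, axis)
    if plane is None:
        return BottomPlane(origin=band.mean(0), normal=axis, low_confidence=True)
    if refit_window_cm > 0:
        d = np.abs((pts - plane.origin) @ plane.normal)
        slab = pts[d <= refit_window_cm]
        if len(slab) >= 3:
            refit = _fit_plane(slab, axis)
            if refit is not None:
                plane = refit
    # orient toward the bulk of the cloud: the mean is pulled decisively
    # by the item points even when on-plane points are the majority
    if np.mean((pts - plane.origin) @ plane.normal) < 0:
        plane.normal = -plane.normal
    plane.low_confidence = low_conf
    return plane


def _under_surface_points(cloud: PointCloud, bottom: BottomPlane, *,
                          neighbor_radius_cm: float = 2.2,
                          n_z_threshold: float = -0.2,
                          min_ring: int = 8) -> np.ndarray:
    """Flag food points lying on an item's under-surface.

    The local surface normal is estimated by PCA over neighbouring food
    points and oriented toward the camera that observed the point; a
    normal pointing clearly below the support plane marks an observed
    under-surface (the tucked lower side of a convex item seen from a
    low viewpoint).
    """
    n_pts = len(cloud.points)
    under = np.zeros(n_pts, bool)
    if cloud.on_food is None or not cloud.on_food.any() or not cloud.poses:
        return under
    poses = cloud.poses
    if not isinstance(poses, dict):
        poses = {k: p for k, p in enumerate(poses)}
    food_idx = np.where(cloud.on_food)[0]
    fp = cloud.points[food_idx]
    tree = cKDTree(fp)
    hts = bottom.heights(cloud.points)
    # local top of the item: max food height within a 2D (footprint) disk;
    # an under-surface lies below the widest extent, i.e. below mid-height
    n_hat = bottom.normal
    fp_uv = fp - np.outer(fp @ n_hat, n_hat)
    uv_tree = cKDTree(fp_uv)
    h_food = hts[food_idx]
    local_top = np.array([
        h_food[uv_tree.query_ball_point(p, 2.0)].max() for p in fp_uv
    ])
    for row, gi in enumerate(food_idx):
        if hts[gi] > 0.6 * local_top[row] or local_top[row] - hts[gi] < 1.2:
            continue
        # direct stack evidence: another food point sits well above this
        # one at (nearly) the same footprint location
        close = uv_tree.query_ball_point(fp_uv[row], 1.1)
        if h_food[close].max() - hts[gi] > 1.8:
            under[gi] = True
            continue
        neigh = tree.query_ball_point(fp[row], neighbor_radius_cm)
        if len(neigh) < 4:
            continue
        local = fp[neigh] - fp[neigh].mean(axis=0)
        _, s, vt = np.linalg.svd(local, full_matrices=False)
        if s[1] < 1e-9:
            continue
        normal = vt[2]
        pose = poses.get(int(cloud.frame_ids[gi]))
        if pose is None:
            continue
        view = pose.t - cloud.points[gi]
        if normal @ view < 0:
            normal = -normal
        if normal @ bottom.normal < n_z_threshold:
            under[gi] = True
    # a genuine under-surface is a coherent ring; a handful of noisy
    # normal flips on a steep rim is not
    if under.sum() < min_ring:
        under[:] = False
        return under
    # one conservative growth pass: nearby food points at or below a seed
    # belong to the same under band even where their own normal estimate
    # was under-determined
    seeds = np.where(under)[0]
    for gi in seeds:
        row = np.nonzero(food_idx == gi)[0][0]
        for nb in tree.query_ball_point(fp[row], neighbor_radius_cm):
            gj = food_idx[nb]
            if (not under[gj] and hts[gj] <= hts[gi] + 0.5
                    and hts[gj] <= 0.6 * local_top[nb]):
                under[gj] = True
    # a true under-surface band floats above the plane; a connected band
    # that reaches the plane is a side wall whose normals merely wobbled
    u_idx = np.where(under)[0]
    if len(u_idx):
        up = cloud.points[u_idx]
        ut = cKDTree(up)
        parent = list(range(len(u_idx)))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for a, b in ut.query_pairs(2.5):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
        comps: dict[int, list[int]] = {}
        for k in range(len(u_idx)):
            comps.setdefault(find(k), []).append(k)
        for members in comps.values():
            mh = hts[u_idx[members]].min()
            if mh <= 0.5 or len(members) < min_ring:
                under[u_idx[members]] = False
    return under


@dataclass
class VolumeResult:
    volume_cm3: float
    bottom_plane: BottomPlane | None
    n_frames_used: int
    per_frame_dots: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json_dict(self):
        return {
            "volume_cm3": float(self.volume_cm3),
            "bottom_plane": self.bottom_plane.to_dict() if self.bottom_plane else None,
            "n_frames_used": int(self.n_frames_used),
            "per_frame_dots": {str(k): int(v) for k, v in self.per_frame_dots.items()},
            "warnings": list(self.warnings),
        }


def integrate_volume(cloud: PointCloud, bottom: BottomPlane, *,
                     restrict_to_food: bool = True,
                     skirt_cm: float = 1.5,
                     skirt_max_height_cm: float = 1.0,
                     undercut_radius_cm: float = 1.5,
                     undercut_gap_cm: float = 1.5,
                     undercut_min_height_cm: float = 0.5) -> VolumeResult:
    """Prism-sum volume over a Delaunay triangulation of the footprint.

    Points project onto the bottom plane; each Delaunay triangle
    contributes its area times the mean column height of its vertices
    (heights below the plane clip to zero).  Two refinements keep the
    prism model honest on real clouds:

    * When the cloud carries food/background classification, integration
      is restricted to the food points plus the surrounding skirt of
      near-plane background points (within ``skirt_cm`` of a food point),
      so the prism sum closes on the support plane at the item's edge
      instead of integrating sensor noise over the whole visible plate.
    * Side views observe the *lower* surface of items that tuck under
      (e.g. the lower half of an ellipsoid).  Where a footprint
      neighbourhood (radius ``undercut_radius_cm``) contains two height
      layers separated by more than ``undercut_gap_cm`` with the lower
      layer clearly off the plane (above ``undercut_min_height_cm``),
      the column height becomes upper minus lower, instead of the full
      column down to the plane.  Nothing is subtracted where the lower
      surface was never observed — the flat-bottom air-gap limitation of
      the method remains.
    """
    pts = np.asarray(cloud.points, float)
    warnings = []
    if (restrict_to_food and cloud.on_food is not None
            and len(cloud.on_food) == len(pts) and cloud.on_food.any()):
        nf = np.asarray(cloud.on_food, bool)
        food_pts = pts[nf]
        tree = cKDTree(food_pts)
        d, _ = tree.query(pts)
        # the skirt exists to close the footprint on the support plane, so
        # only near-plane background points qualify
        hh = bottom.heights(pts)
        keep = nf | ((d <= skirt_cm) & (hh <= skirt_max_height_cm))
        cloud = PointCloud(points=pts[keep], frame_ids=cloud.frame_ids[keep],
                           indices=cloud.indices[keep], imputed=cloud.imputed[keep],
                           on_food=nf[keep], poses=cloud.poses)
        pts = cloud.points
    result = lambda v, w: VolumeResult(  # noqa: E731
        volume_cm3=v, bottom_plane=bottom, n_frames_used=len(set(cloud.frame_ids.tolist())),
        per_frame_dots={int(f): int(np.sum(cloud.frame_ids == f))
                        for f in np.unique(cloud.frame_ids)},
        warnings=w,
    )
    if len(pts) < 4:
        warnings.append("degenerate volume: fewer than 4 points")
        return result(0.0, warnings)
    n = bottom.normal
    h = np.clip(bottom.heights(pts), 0.0, None)
    if np.all(h < 1e-9):
        warnings.append("degenerate volume: cloud coplanar with bottom plane")
        return result(0.0, warnings)
    e1 = np.cross(n, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-9:
        e1 = np.cross(n, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    d = pts - bottom.origin
    uv = np.stack([d @ e1, d @ e2], axis=1)
    # collapse exact-duplicate footprint positions (keep max height)
    try:
        tri = Delaunay(uv)
    except QhullError:
        warnings.append("degenerate volume: footprint triangulation failed")
        return result(0.0, warnings)
    # Per-vertex column height, under-surface aware.  Side views observe
    # the lower surface of items that tuck under; those points are
    # recognised by their camera-oriented local normals pointing downward.
    # In a footprint neighbourhood containing under-surface points, the
    # column spans the upper envelope minus the under-surface envelope
    # (clamped to the plane when the under-surface reaches it); every
    # stacked vertex in such a neighbourhood shares that column, keeping
    # the prism mean consistent.  Neighbourhoods without observed
    # under-surface keep each vertex's own height — the flat-bottom
    # air-gap limitation remains wherever the underside was not seen.
    col = h.copy()
    under = _under_surface_points(cloud, bottom)
    if undercut_radius_cm > 0 and len(uv) > 1 and under.any():
        t2 = cKDTree(uv)
        corrected = np.zeros(len(uv), bool)
        for m, neigh in enumerate(t2.query_ball_point(uv, undercut_radius_cm)):
            neigh = np.asarray(neigh)
            u_mask = under[neigh]
            if not u_mask.any():
                continue
            top = h[neigh].max()
            base = h[neigh[u_mask]].min()
            if top - base < undercut_gap_cm or base <= undercut_min_height_cm:
                continue
            col[m] = top - base
            corrected[m] = True
        # extrapolate the observed under-surface ring inward: a resting
        # convex item's base descends from the ring toward the contact
        # region roughly quadratically; interior columns subtract that
        # extrapolated base instead of reaching the plane
        food_m = cloud.on_food if cloud.on_food is not None else np.zeros(len(uv), bool)
        centroid = uv[food_m].mean(axis=0) if food_m.any() else uv.mean(axis=0)
        u_idx = np.where(under)[0]
        ut = cKDTree(uv[u_idx])
        for m in np.where(food_m & ~corrected)[0]:
            _, qi = ut.query(uv[m])
            q = u_idx[qi]
            rm = np.linalg.norm(uv[m] - centroid)
            rq = np.linalg.norm(uv[q] - centroid)
            if rq < 1e-9 or rm >= rq:
                continue
            base = h[q] * (rm / rq) ** 2
            if h[m] - base > undercut_gap_cm:
                col[m] = h[m] - base
    a = uv[tri.simplices[:, 0]]
    b = uv[tri.simplices[:, 1]]
    c = uv[tri.simplices[:, 2]]
    area = 0.5 * np.abs(
        (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
        - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    )
    hm = col[tri.simplices].mean(axis=1)
    return result(float(np.sum(area * hm)), warnings)


# ---------------------------------------------------------------------------
# touching-item separation


def separate_touching_items(image, dots=None, *, background_color=None,
                            edge_threshold: float = 100.0,
                            background_tol: float = 30.0,
                            min_region_px: int = 200):
    """Split the food region into per-item masks using RGB edges.

    RGB gradient-magnitude edges partition the non-background region;
    dots are assigned to items by containment (with a small dilation for
    dots sitting on an edge ring).  Returns ``(masks, dot_items)`` where
    ``dot_items[k]`` is the mask index for ``dots[k]`` or -1.
    """
    img = np.asarray(image, float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise SlvolError("expected a 3-channel RGB image")
    if background_color is None:
        border = np.concatenate(
            [img[0], img[-1], img[:, 0], img[:, -1]], axis=0
        )
        background_color = np.median(border, axis=0)
    bg = np.asarray(background_color, float)
    food = np.linalg.norm(img - bg, axis=-1) > background_tol

    grad = np.zeros(img.shape[:2])
    for ch in range(3):
        gx = ndimage.sobel(img[..., ch], axis=1)
        gy = ndimage.sobel(img[..., ch], axis=0)
        grad += np.hypot(gx, gy)
    edges = grad > edge_threshold

    labels, n = ndimage.label(food & ~edges)
    masks = []
    keep = []
    for k in range(1, n + 1):
        m = labels == k
        if m.sum() >= min_region_px:
            masks.append(m)
            keep.append(k)
    relabel = np.zeros_like(labels)
    for new, old in enumerate(keep, start=1):
        relabel[labels == old] = new
    from skimage.segmentation import expand_labels

    expanded = expand_labels(relabel, distance=15)
    dot_items = []
    if dots is not None:
        h, w = relabel.shape
        for d in dots:
            x = min(max(int(round(d.x_px)), 0), w - 1)
            y = min(max(int(round(d.y_px)), 0), h - 1)
            dot_items.append(int(expanded[y, x]) - 1)
    return masks, dot_items


# ---------------------------------------------------------------------------
# gyro pose integration


def integrate_gyro(trace: SensorTrace, R0: np.ndarray, times=None):
    """Integrate body-frame angular rates into orientations.

    Returns the camera-to-world rotation matrices at the requested times
    (default: every trace sample), starting from ``R0`` at the first
    sample.
    """
    R = np.asarray(R0, float)
    dt = np.diff(trace.t)
    Rs = [R]
    for k in range(len(dt)):
        w = 0.5 * (trace.gyro[k] + trace.gyro[k + 1])
        R = R @ Rotation.from_rotvec(w * dt[k]).as_matrix()
        Rs.append(R)
    Rs = np.asarray(Rs)
    if times is None:
        return Rs
    pick = np.searchsorted(trace.t, np.asarray(times, float))
    pick = np.clip(pick, 0, len(Rs) - 1)
    return Rs[pick]


def poses_from_gyro(trace: SensorTrace, frame_timestamps, frame_points,
                    R0: np.ndarray, *, pivot=(0.0, 0.0, 0.0)) -> list:
    """Poses from integrated gyro orientation plus a pivot assumption.

    The camera is assumed to keep its optical axis through ``pivot``; the
    per-frame distance comes from the median camera-frame depth of that
    frame's points.
    """
    Rs = integrate_gyro(trace, R0, times=frame_timestamps)
    pivot = np.asarray(pivot, float)
    poses = []
    for R, fp in zip(Rs, frame_points):
        if len(fp.points_cam):
            dist = float(np.median(fp.points_cam[:, 2]))
        else:
            dist = 30.0
        poses.append(Pose(R=R, t=pivot - R @ np.array([0.0, 0.0, dist])))
    return poses


# ---------------------------------------------------------------------------
# end-to-end scan measurement


def measure_scan(frames, timestamps, trace, model: CalibrationModel, *,
                 poses=None, k_frames: int = 6,
                 cascade_cfg: MaskCascadeConfig | None = None,
                 grid_cfg: GridConfig | None = None,
                 impute: bool = True, merge_radius_cm: float = 0.5,
                 refine: bool = False, bottom_percentile: float = 5.0,
                 pose_source: str = "ground_truth",
                 pivot=(0.0, 0.0, 0.0),
                 correction_factor: float = 1.0) -> tuple:
    """Full scan-to-volume pipeline; returns (VolumeResult, PointCloud)."""
    frames = list(frames)
    if len(frames) > k_frames and trace is not None:
        sel = select_stable_frames(trace, timestamps, k=k_frames)
    else:
        sel = list(range(len(frames)))

    fps = []
    warnings = []
    for fid in sel:
        fp = frame_to_points(
            frames[fid], model, cascade_cfg=cascade_cfg, grid_cfg=grid_cfg,
            impute=impute, frame_id=fid,
        )
        warnings.extend(f"frame {fid}: {w}" for w in fp.warnings)
        fps.append(fp)

    if pose_source == "gyro":
        if trace is None:
            raise PoseUnavailableError("gyro pose source needs a trace")
        R0 = poses[sel[0]].R if poses else np.eye(3)
        sel_ts = [timestamps[fid] for fid in sel]
        pose_list = poses_from_gyro(trace, sel_ts, fps, R0, pivot=pivot)
        pose_map = {fid: p for fid, p in zip(sel, pose_list)}
    elif pose_source == "ground_truth":
        if poses is None:
            raise PoseUnavailableError("ground-truth pose source needs poses")
        pose_map = {fid: poses[fid] for fid in sel}
    else:
        raise PoseUnavailableError(f"unknown pose source {pose_source!r}")
    logger.info("pose source: %s", pose_source)

    cloud = fuse_frames(fps, pose_map, merge_radius_cm=merge_radius_cm,
                        refine=refine)
    cloud = clean_cloud(cloud)
    if len(cloud) == 0:
        res = VolumeResult(volume_cm3=0.0, bottom_plane=None,
                           n_frames_used=0, warnings=warnings + ["empty cloud"])
        return res, cloud
    bottom = estimate_bottom(cloud, percentile=bottom_percentile)
    res = integrate_volume(cloud, bottom)
    res.warnings = warnings + res.warnings
    res.volume_cm3 *= correction_factor
    return res, cloud


# ---------------------------------------------------------------------------
# point-cloud output


def write_ply(cloud: PointCloud, path):
    """ASCII PLY point cloud (x y z in cm plus frame id and grid index)."""
    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {len(cloud)}",
        "property float x", "property float y", "property float z",
        "property int frame", "property int gi", "property int gj",
        "end_header",
    ]
    for p, f, (gi, gj) in zip(cloud.points, cloud.frame_ids, cloud.indices):
        lines.append(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {int(f)} {int(gi)} {int(gj)}")
    Path(path).write_text("\n".join(lines) + "\n")


def cloud_to_frame(cloud: PointCloud):
    """Point cloud as a pandas DataFrame (for CSV export)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "x_cm": cloud.points[:, 0],
            "y_cm": cloud.points[:, 1],
            "z_cm": cloud.points[:, 2],
            "frame_id": cloud.frame_ids,
            "i": cloud.indices[:, 0],
            "j": cloud.indices[:, 1],
            "imputed": cloud.imputed,
        }
    )
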