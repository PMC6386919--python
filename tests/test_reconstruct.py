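"""Frame selection, point clouds, fusion, bottom plane, volume."""

import math

import numpy as np
import pytest

from slvol import (
    BottomPlane,
    InsufficientScanError,
    PointCloud,
    Pose,
    PoseUnavailableError,
    SceneSpec,
    estimate_bottom,
    frame_to_points,
    fuse_frames,
    integrate_gyro,
    integrate_volume,
    measure_scan,
    render_calibration_stack,
    render_scan,
    select_stable_frames,
    separate_touching_items,
    simulate_imu,
    write_ply,
)
from slvol.reconstruct import FramePoints
from slvol.synth import SensorTrace


def flat_trace(duration=30.0, fs=100.0):
    t = np.arange(0.0, duration, 1.0 / fs)
    accel = np.tile([0.0, 0.0, 9.81], (len(t), 1))
    return SensorTrace(t=t, accel=accel, gyro=np.zeros((len(t), 3)))


class TestFrameSelection:
    def test_constant_trace_picks_segment_midpoints(self):
        ts = np.arange(1.0, 25.0)  # 24 frames
        picked = select_stable_frames(flat_trace(), ts, k=3)
        # ties everywhere: the midpoint frame of each 8-frame segment wins
        assert picked == [3, 11, 19] or picked == [4, 12, 20]
        assert all(b > a for a, b in zip(picked, picked[1:]))

    def test_quiet_windows_are_selected(self):
        quiet = np.array([3.0, 6.0, 9.0, 12.0, 15.0, 18.0])
        yaws = np.linspace(0, 2 * math.pi, 6, endpoint=False)
        trace = simulate_imu(quiet, yaws, 22.0, seed=8, duration=21.0)
        frame_ts = np.arange(1.0, 20.0, 0.5)
        picked = select_stable_frames(trace, frame_ts, k=6)
        assert len(picked) == 6
        for p in picked:
            assert np.min(np.abs(quiet - frame_ts[p])) <= 0.5

    def test_k_one_returns_single_frame(self):
        ts = np.arange(1.0, 11.0)
        assert len(select_stable_frames(flat_trace(), ts, k=1)) == 1

    def test_too_few_frames(self):
        with pytest.raises(InsufficientScanError):
            select_stable_frames(flat_trace(), [1.0, 2.0], k=6)


class TestFrameToPoints:
    def test_plane_frame_recovers_depth(self, model, clean_plane_spec):
        stack = render_calibration_stack(clean_plane_spec, [25.0])
        fp = frame_to_points(stack.images[0], model)
        assert len(fp.points_cam) >= 121  # includes imputed edge fills, if any
        np.testing.assert_allclose(fp.points_cam[:, 2], 25.0, atol=0.3)

    def test_black_frame_is_empty_with_warning(self, model):
        img = np.zeros((480, 720, 3))
        fp = frame_to_points(img, model)
        assert len(fp.points_cam) == 0
        assert fp.warnings

    def test_hemisphere_centre_nearer_than_rim(self, model):
        """The dome's central dots lie nearer the camera than its rim dots."""
        spec = SceneSpec(surface="hemisphere", params={"radius": 5.0}, seed=6)
        scan = render_scan(spec, 1)
        fp = frame_to_points(scan.frames[0], model)
        on_food = fp.on_food
        assert on_food.any() and (~on_food).any()
        food = fp.points_cam[on_food]
        lateral = np.hypot(food[:, 0] - food[:, 0].mean(),
                           food[:, 1] - food[:, 1].mean())
        order = np.argsort(lateral)
        central = food[order[:3], 2].mean()
        rim = food[order[-3:], 2].mean()
        assert central < rim


def analytic_plane_frame(pose, z_world=0.0, n=7, frame_id=0):
    """FramePoints for a flat grid on the z=0 table, seen from ``pose``."""
    g = np.linspace(-6, 6, n)
    X, Y = np.meshgrid(g, g)
    world = np.stack([X.ravel(), Y.ravel(), np.full(n * n, z_world)], axis=1)
    cam = pose.world_to_cam(world)
    idx = np.array([(i, j) for i in range(n) for j in range(n)])
    return FramePoints(frame_id=frame_id, points_cam=cam, indices=idx,
                       imputed=np.zeros(n * n, bool),
                       on_food=np.zeros(n * n, bool))


class TestFusion:
    def test_single_frame_identity_pose(self):
        pose = Pose.identity()
        fp = analytic_plane_frame(pose)
        cloud = fuse_frames([fp], [pose], merge_radius_cm=0.0)
        np.testing.assert_allclose(cloud.points, fp.points_cam, atol=1e-12)

    def test_two_views_of_plane_fuse_flat(self):
        from slvol.synth import look_at

        p1 = look_at([20.0, 0.0, 15.0], [0.0, 0.0, 0.0])
        p2 = look_at([-14.0, 14.0, 15.0], [0.0, 0.0, 0.0])
        fps = [analytic_plane_frame(p1, frame_id=0),
               analytic_plane_frame(p2, frame_id=1)]
        cloud = fuse_frames(fps, [p1, p2])
        assert np.abs(cloud.points[:, 2]).max() < 0.2
        assert len(cloud) < 2 * 49  # overlapping points merged

    def test_missing_pose_raises(self):
        fp = analytic_plane_frame(Pose.identity(), frame_id=3)
        with pytest.raises(PoseUnavailableError):
            fuse_frames([fp], {0: Pose.identity()})

    def test_hemisphere_cloud_close_to_true_surface(self, model):
        spec = SceneSpec(surface="hemisphere", params={"radius": 5.0}, seed=6)
        scan = render_scan(spec, 6)
        fps = [frame_to_points(f, model, frame_id=k)
               for k, f in enumerate(scan.frames)]
        cloud = fuse_frames(fps, {k: p for k, p in enumerate(scan.poses)})
        food = cloud.on_food
        r = np.linalg.norm(cloud.points[food], axis=1)
        rms = np.sqrt(np.mean((r - 5.0) ** 2))
        assert rms < 0.3


class TestBottomPlane:
    def test_plate_at_common_height(self, rng):
        g = np.linspace(-8, 8, 12)
        X, Y = np.meshgrid(g, g)
        pts = np.stack([X.ravel(), Y.ravel(), np.full(144, 2.5)], axis=1)
        pts += rng.normal(0, 0.02, pts.shape)
        cloud = PointCloud(points=pts, frame_ids=np.zeros(144, int),
                           indices=np.array([(i, j) for i in range(12) for j in range(12)]),
                           imputed=np.zeros(144, bool))
        plane = estimate_bottom(cloud)
        assert plane.origin[2] == pytest.approx(2.5, abs=0.05)
        assert abs(plane.normal[2]) > 0.999

    def test_single_point_degenerate(self):
        cloud = PointCloud(points=np.array([[1.0, 2.0, 3.0]]),
                           frame_ids=np.zeros(1, int),
                           indices=np.zeros((1, 2), int),
                           imputed=np.zeros(1, bool))
        plane = estimate_bottom(cloud)
        assert plane.low_confidence
        assert plane.origin[2] == pytest.approx(3.0)


def grid_cloud(heights, extent=10.0, on_food=True):
    n = heights.shape[0]
    g = np.linspace(0, extent, n)
    X, Y = np.meshgrid(g, g, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), heights.ravel()], axis=1)
    m = n * n
    return PointCloud(points=pts, frame_ids=np.zeros(m, int),
                      indices=np.stack(np.meshgrid(range(n), range(n),
                                                   indexing="ij"), -1).reshape(-1, 2),
                      imputed=np.zeros(m, bool),
                      on_food=np.full(m, on_food))


FLAT = BottomPlane(origin=np.zeros(3), normal=np.array([0.0, 0.0, 1.0]))


class TestIntegration:
    def test_unit_slab_is_area_times_height(self):
        cloud = grid_cloud(np.ones((11, 11)), extent=10.0)
        res = integrate_volume(cloud, FLAT)
        assert res.volume_cm3 == pytest.approx(100.0, rel=1e-9)

    def test_coplanar_cloud_is_zero_with_warning(self):
        cloud = grid_cloud(np.zeros((5, 5)))
        res = integrate_volume(cloud, FLAT)
        assert res.volume_cm3 == 0.0
        assert res.warnings

    def test_too_few_points(self):
        cloud = PointCloud(points=np.zeros((3, 3)), frame_ids=np.zeros(3, int),
                           indices=np.zeros((3, 2), int), imputed=np.zeros(3, bool))
        res = integrate_volume(cloud, FLAT)
        assert res.volume_cm3 == 0.0 and res.warnings

    def test_rotation_invariance(self, rng):
        pts = rng.uniform(0, 10, (80, 3))
        pts[:, 2] = rng.uniform(0.5, 4.0, 80)
        cloud = PointCloud(points=pts, frame_ids=np.zeros(80, int),
                           indices=np.zeros((80, 2), int),
                           imputed=np.zeros(80, bool))
        v0 = integrate_volume(cloud, FLAT).volume_cm3
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", [25, -40, 130], degrees=True).as_matrix()
        rcloud = PointCloud(points=pts @ R.T, frame_ids=cloud.frame_ids,
                            indices=cloud.indices, imputed=cloud.imputed)
        rplane = BottomPlane(origin=R @ FLAT.origin, normal=R @ FLAT.normal)
        v1 = integrate_volume(rcloud, rplane).volume_cm3
        assert v1 == pytest.approx(v0, rel=1e-9)

    def test_adding_point_above_surface_increases_volume(self):
        cloud = grid_cloud(np.ones((6, 6)), extent=10.0)
        v0 = integrate_volume(cloud, FLAT).volume_cm3
        extra = np.vstack([cloud.points, [[5.0, 5.0, 1.5]]])
        bigger = PointCloud(points=extra, frame_ids=np.zeros(37, int),
                            indices=np.zeros((37, 2), int),
                            imputed=np.zeros(37, bool),
                            on_food=np.full(37, True))
        v1 = integrate_volume(bigger, FLAT).volume_cm3
        assert v1 > v0 - 1e-9


class TestSeparateItems:
    def test_single_uniform_item(self):
        img = np.full((120, 160, 3), 75.0)
        img[30:90, 40:120] = (150, 60, 50)
        masks, _ = separate_touching_items(img)
        assert len(masks) == 1

    def test_two_touching_items_split_with_dot_assignment(self):
        img = np.full((120, 200, 3), 75.0)
        img[30:90, 30:100] = (150, 60, 50)     # red item
        img[30:90, 100:170] = (60, 90, 160)    # blue item, touching
        from slvol import LaserDot

        dots = [LaserDot(60.0, 60.0, 100, 5), LaserDot(140.0, 60.0, 100, 5)]
        masks, items = separate_touching_items(img, dots)
        assert len(masks) == 2
        assert items[0] != items[1] and -1 not in items

    def test_background_only(self):
        img = np.full((60, 60, 3), 75.0)
        masks, _ = separate_touching_items(img)
        assert masks == []


def test_gyro_integration_recovers_orbit_yaw():
    frame_times = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
    yaws = np.linspace(0, 2 * math.pi, 6, endpoint=False)
    trace = simulate_imu(frame_times, yaws, 22.0, seed=12, duration=14.0,
                         jitter_amp=0.0)
    el = math.radians(22.0)

    def R_of(yaw):
        zb = np.array([-math.cos(el) * math.cos(yaw),
                       -math.cos(el) * math.sin(yaw), -math.sin(el)])
        xb = np.cross(zb, [0.0, 0.0, 1.0])
        xb /= np.linalg.norm(xb)
        yb = np.cross(zb, xb)
        return np.stack([xb, yb, zb], axis=1)

    Rs = integrate_gyro(trace, R_of(yaws[0]), times=frame_times)
    for R_est, yaw in zip(Rs, yaws):
        err = np.degrees(np.arccos(np.clip((np.trace(R_est.T @ R_of(yaw)) - 1) / 2, -1, 1)))
        assert err < 5.0  # dead-reckoning drift over a 14 s scan


def test_ply_round_trip_via_trimesh(tmp_path):
    import trimesh

    cloud = grid_cloud(np.linspace(0, 2, 25).reshape(5, 5))
    path = tmp_path / "cloud.ply"
    write_ply(cloud, path)
    loaded = trimesh.load(str(path))
    assert len(loaded.vertices) == 25
    np.testing.assert_allclose(np.sort(loaded.vertices[:, 2]),
                               np.sort(cloud.points[:, 2]), atol=1e-5)


def test_end_to_end_hemisphere_scan(model):
    spec = SceneSpec(surface="hemisphere", params={"radius": 5.0}, seed=4,
                     reflection_count=3, gaussian_sigma=2.0)
    scan = render_scan(spec, 6)
    res, cloud = measure_scan(scan.frames, scan.timestamps, scan.trace, model,
                              poses=scan.poses)
    true = scan.true_volume_cm3
    assert res.n_frames_used == 6
    assert abs(res.volume_cm3 - true) / true < 0.11
    assert abs(res.bottom_plane.origin[2]) < 0.2
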