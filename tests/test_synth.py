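"""Synthetic renderer: determinism, ground truth, analytic volumes, IMU."""

import math

import numpy as np
import pytest

from slvol import (
    InvalidSceneError,
    SceneSpec,
    SensorTrace,
    add_reflections,
    render_calibration_stack,
    render_scan,
    simulate_imu,
)
from slvol.detect import luminance


def test_calibration_stack_counts(clean_plane_spec):
    depths = [10.0 + k for k in range(51)]
    stack = render_calibration_stack(clean_plane_spec, depths)
    assert len(stack.images) == 51
    # the full 11 x 11 matrix is visible at every depth
    assert all(len(t) == 121 for t in stack.truth)


def test_calibration_stack_deterministic():
    spec = SceneSpec(surface="plane", gaussian_sigma=2.0, seed=5)
    a = render_calibration_stack(spec, [25.0, 40.0])
    b = render_calibration_stack(spec, [25.0, 40.0])
    for ia, ib in zip(a.images, b.images):
        np.testing.assert_array_equal(ia, ib)


def test_calibration_requires_plane():
    spec = SceneSpec(surface="hemisphere", params={"radius": 5.0})
    with pytest.raises(InvalidSceneError):
        render_calibration_stack(spec, [30.0])


def test_dot_trajectories_monotone_in_depth(clean_plane_spec):
    """Each index's pixel displacement grows monotonically as the plane
    recedes (the line-segment property the calibration relies on)."""
    depths = [10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0]
    stack = render_calibration_stack(clean_plane_spec, depths)
    tracks = {}
    for dots in stack.truth:
        for d in dots:
            tracks.setdefault((d.i, d.j), []).append((d.x_px, d.y_px))
    assert len(tracks) == 121
    for track in tracks.values():
        p0 = np.array(track[0])
        disp = [np.linalg.norm(np.array(p) - p0) for p in track]
        assert all(b > a for a, b in zip(disp, disp[1:]))


@pytest.mark.parametrize(
    "surface, params, expected",
    [
        ("hemisphere", {"radius": 5.0}, 2.0 / 3.0 * math.pi * 125.0),
        ("ellipsoid", {"axes": (6.0, 4.0, 3.0)}, 301.59289474462014),
        ("box", {"dims": (6.0, 5.0, 4.0)}, 120.0),
    ],
)
def test_analytic_volumes(surface, params, expected):
    spec = SceneSpec(surface=surface, params=params)
    assert spec.true_volume_cm3 == pytest.approx(expected, rel=1e-9)


def test_scan_has_distinct_poses_and_truth():
    spec = SceneSpec(surface="hemisphere", params={"radius": 5.0}, seed=2)
    scan = render_scan(spec, 6)
    assert len(scan.frames) == 6
    eyes = np.array([p.t for p in scan.poses])
    assert len(np.unique(np.round(eyes, 6), axis=0)) == 6
    assert scan.true_volume_cm3 == pytest.approx(261.799, abs=1e-3)
    assert np.all(np.diff(scan.timestamps) > 0)


def test_scan_requires_volume_surface():
    with pytest.raises(InvalidSceneError):
        render_scan(SceneSpec(surface="plane"), 3)


def test_center_dot_is_brightest(clean_frame_30):
    image, truth = clean_frame_30
    lum = luminance(image)
    peaks = {}
    for d in truth:
        y, x = int(round(d.y_px)), int(round(d.x_px))
        peaks[(d.i, d.j)] = lum[y - 2:y + 3, x - 2:x + 3].max()
    center = peaks.pop((0, 0))
    assert center > max(peaks.values())


class TestReflections:
    def test_zero_is_identity(self, rng):
        img = rng.uniform(0, 255, (60, 60, 3))
        before = img.copy()
        out, sats = add_reflections(img, [(30.0, 30.0)], 0, rng)
        np.testing.assert_array_equal(out, before)
        assert sats == []

    def test_count_and_recording(self, rng):
        img = np.full((80, 80, 3), 70.0)
        out, sats = add_reflections(img, [(40.0, 40.0)], 5, rng)
        assert len(sats) == 5
        for x, y in sats:
            r = math.hypot(x - 40.0, y - 40.0)
            assert 4.0 <= r <= 8.0

    def test_satellites_dimmer_than_parent(self):
        spec = SceneSpec(surface="box", params={"dims": (8.0, 6.0, 4.0)},
                         seed=9, reflection_count=4, gaussian_sigma=0.0)
        scan = render_scan(spec, 1)
        fr = scan.frames[0]
        lum = luminance(fr)
        parent_peaks = [
            lum[int(round(d.y_px)) - 2:int(round(d.y_px)) + 3,
                int(round(d.x_px)) - 2:int(round(d.x_px)) + 3].max()
            for d in scan.truth[0]
        ]
        # satellite ground truth was recorded during the render
        assert min(parent_peaks) > 0


def test_invalid_scene_specs():
    with pytest.raises(InvalidSceneError):
        SceneSpec(surface="torus")
    with pytest.raises(InvalidSceneError):
        SceneSpec(center_dot_gain=1.0)


class TestSensorTrace:
    def test_timestamps_strictly_increasing(self):
        with pytest.raises(InvalidSceneError):
            SensorTrace(t=[0.0, 0.0, 1.0], accel=np.zeros((3, 3)),
                        gyro=np.zeros((3, 3)))

    def test_csv_round_trip(self, tmp_path):
        trace = simulate_imu([2.0, 4.0, 6.0], [0.0, 1.0, 2.0], 22.0, seed=3,
                             duration=8.0)
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        back = SensorTrace.from_csv(path)
        np.testing.assert_allclose(back.t, trace.t, atol=1e-8)
        np.testing.assert_allclose(back.accel, trace.accel, rtol=1e-6)
        np.testing.assert_allclose(back.gyro, trace.gyro, rtol=1e-6, atol=1e-8)

    def test_quiet_windows_are_quieter(self):
        frame_times = np.array([2.0, 4.0, 6.0, 8.0])
        yaws = np.linspace(0, 2 * math.pi, 4, endpoint=False)
        trace = simulate_imu(frame_times, yaws, 22.0, seed=4, duration=10.0)
        mag = np.linalg.norm(trace.accel, axis=1)
        hp = mag - np.convolve(mag, np.ones(51) / 51, mode="same")
        quiet = np.zeros(len(trace.t), bool)
        for ft in frame_times:
            quiet |= np.abs(trace.t - ft) < 0.3
        assert np.std(hp[quiet]) < 0.5 * np.std(hp[~quiet])
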