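"""Mask cascade: HSV gate, cosine mask, luminance mask, merging, dots."""

import numpy as np
import pytest

from slvol import (
    LaserDot,
    MaskCascadeConfig,
    cosine_similarity_mask,
    detect_dots,
    eliminate_border,
    eliminate_reflections,
    extract_dots,
    find_center_dot,
    hsv_filter,
    luminance,
    luminance_mask,
    manual_correction,
    merge_masks,
)
from slvol.detect import (
    InvalidConfigError,
    InvalidEditError,
    InvalidImageError,
    NoDotsFoundError,
)


def one_px(rgb):
    return np.array(rgb, float).reshape(1, 1, 3)


CFG = MaskCascadeConfig()


class TestHsvFilter:
    @pytest.mark.parametrize(
        "rgb, keep",
        [
            ((0, 255, 0), True),      # pure green: hue 120, sat 100 %
            ((255, 0, 0), False),     # red: hue 0
            ((200, 255, 200), False),  # pale green: sat ~21.6 %
            ((0, 0, 255), False),     # blue: hue 240, outside the gate
            ((0, 255, 255), True),    # cyan: hue 180, boundary inclusive
        ],
    )
    def test_gate(self, rgb, keep):
        assert hsv_filter(one_px(rgb), CFG)[0, 0] == keep

    def test_grayscale_rejected(self):
        with pytest.raises(InvalidImageError):
            hsv_filter(np.zeros((4, 4)), CFG)


class TestCosineMask:
    def test_identical_vector_retained(self):
        img = one_px((10, 200, 30))
        assert cosine_similarity_mask(img, (10, 200, 30), 1.0 - 1e-12)[0, 0]

    def test_gray_against_green(self):
        # cos((200,200,200), (0,255,0)) = 1/sqrt(3) = 0.5774
        img = one_px((200, 200, 200))
        assert cosine_similarity_mask(img, (0, 255, 0), 0.577)[0, 0]
        assert not cosine_similarity_mask(img, (0, 255, 0), 0.578)[0, 0]

    def test_black_always_rejected(self):
        assert not cosine_similarity_mask(one_px((0, 0, 0)), (0, 255, 0), 0.0)[0, 0]

    def test_zero_reference_rejected(self):
        with pytest.raises(InvalidConfigError):
            cosine_similarity_mask(one_px((1, 2, 3)), (0, 0, 0), 0.5)

    def test_matches_per_pixel_brute_force(self, rng):
        """Vectorised mask equals an explicit per-pixel cosine loop."""
        img = rng.uniform(0, 255, (32, 32, 3))
        ref = np.array([30.0, 220.0, 25.0])
        got = cosine_similarity_mask(img, ref, 0.8)
        for y in range(32):
            for x in range(32):
                v = img[y, x]
                cos = v @ ref / (np.linalg.norm(v) * np.linalg.norm(ref))
                assert got[y, x] == (cos >= 0.8 - 1e-12), (y, x)


class TestLuminance:
    @pytest.mark.parametrize(
        "rgb, expected",
        [((255, 255, 255), 255.0), ((0, 255, 0), 182.376), ((0, 0, 0), 0.0)],
    )
    def test_bt709(self, rgb, expected):
        assert luminance(one_px(rgb))[0, 0] == pytest.approx(expected, abs=1e-9)


class TestLuminanceMask:
    def test_uniform_image_gives_empty_mask(self):
        img = np.full((50, 50, 3), 120.0)
        assert not luminance_mask(img, CFG).any()

    def test_gaussian_dot_survives_opening(self):
        img = np.full((60, 60, 3), 20.0)
        ys, xs = np.mgrid[0:60, 0:60]
        g = np.exp(-((ys - 30) ** 2 + (xs - 30) ** 2) / (2 * 2.0**2))
        img[..., 1] += 200 * g
        mask = luminance_mask(img, CFG)
        assert mask[30, 30]
        assert mask.sum() < 100  # only the compact blob, not the background

    def test_invalid_radius(self):
        with pytest.raises(InvalidConfigError):
            luminance_mask(np.zeros((8, 8, 3)), MaskCascadeConfig(opening_disk_radius_px=0))

    def test_full_frame_keeps_all_dots(self, clean_frame_30):
        from scipy import ndimage

        image, truth = clean_frame_30
        mask = luminance_mask(image, CFG)
        _, n = ndimage.label(mask)
        assert n >= 121


class TestBorderElimination:
    def test_interior_component_kept(self):
        mask = np.zeros((40, 40), bool)
        mask[18:22, 18:22] = True
        np.testing.assert_array_equal(eliminate_border(mask, 5), mask)

    def test_border_component_removed(self):
        mask = np.zeros((40, 40), bool)
        mask[0:4, 10:14] = True
        assert not eliminate_border(mask, 5).any()

    def test_mixed(self):
        mask = np.zeros((40, 40), bool)
        mask[18:22, 18:22] = True   # interior
        mask[37:40, 5:9] = True     # touching the bottom band
        out = eliminate_border(mask, 5)
        assert out[19, 19] and out.sum() == 16


class TestMergeMasks:
    a = np.zeros((6, 6), bool)
    a[2:4, 2:4] = True

    def test_idempotent(self):
        np.testing.assert_array_equal(merge_masks(self.a, self.a, self.a), self.a)

    def test_absorbing_empty(self):
        empty = np.zeros_like(self.a)
        assert not merge_masks(self.a, empty, self.a).any()

    def test_subset_of_each_input(self, rng):
        m1, m2, m3 = (rng.random((16, 16)) > 0.5 for _ in range(3))
        out = merge_masks(m1, m2, m3)
        for m in (m1, m2, m3):
            assert not (out & ~m).any()

    def test_shape_mismatch(self):
        with pytest.raises(InvalidImageError):
            merge_masks(self.a, self.a[:4], self.a)


class TestExtractDots:
    def test_empty_mask(self):
        assert extract_dots(np.zeros((10, 10), bool), np.zeros((10, 10))) == []

    def test_uniform_blob_centroid(self):
        mask = np.zeros((30, 30), bool)
        mask[10:15, 10:15] = True
        lum = np.full((30, 30), 9.0)
        dots = extract_dots(mask, lum)
        assert len(dots) == 1
        assert (dots[0].x_px, dots[0].y_px) == (12.0, 12.0)
        assert dots[0].area_px == 25

    def test_min_area_filters(self):
        mask = np.zeros((10, 10), bool)
        mask[2, 2] = True
        assert extract_dots(mask, np.ones((10, 10)), min_area_px=3) == []


class TestEliminateReflections:
    def mk(self, x, y, peak):
        return LaserDot(x, y, peak, 5)

    def test_far_dots_unchanged(self):
        dots = [self.mk(0, 0, 10), self.mk(40, 0, 9), self.mk(0, 40, 8)]
        assert len(eliminate_reflections(dots, 12.0)) == 3

    def test_satellites_collapse_to_parent(self):
        parent = self.mk(50, 50, 200)
        sats = [self.mk(55, 50, 120), self.mk(50, 56, 110)]
        out = eliminate_reflections([parent] + sats, 12.0)
        assert out == [parent]

    def test_brightness_tie_goes_to_cluster_centre(self):
        a, b, c = self.mk(0, 0, 100), self.mk(5, 0, 100), self.mk(10, 0, 90)
        out = eliminate_reflections([a, b, c], 12.0)
        assert out == [b]  # nearest the cluster centroid among the tied pair


class TestFindCenter:
    def test_single_dot(self):
        d = LaserDot(5, 5, 42, 4)
        assert find_center_dot([d]) is d
        assert d.is_center

    def test_brightest_wins(self):
        dots = [LaserDot(0, 0, 100, 4), LaserDot(10, 10, 180, 4)]
        assert find_center_dot(dots) is dots[1]

    def test_tie_breaks_toward_image_centre(self):
        dots = [LaserDot(5, 5, 100, 4), LaserDot(49, 49, 100, 4)]
        c = find_center_dot(dots, image_shape=(100, 100))
        assert c is dots[1]

    def test_empty_raises(self):
        with pytest.raises(NoDotsFoundError):
            find_center_dot([])


class TestManualCorrection:
    dots = [LaserDot(10, 10, 50, 4), LaserDot(20, 20, 60, 4)]

    def test_empty_edits_identity(self):
        out = manual_correction(self.dots, [])
        assert [(d.x_px, d.y_px) for d in out] == [(10, 10), (20, 20)]

    def test_add(self):
        out = manual_correction(self.dots, [{"op": "add", "x": 5, "y": 6}])
        assert len(out) == 3 and out[-1].provenance == "manual"

    def test_move(self):
        out = manual_correction(self.dots, [{"op": "move", "id": 0, "x": 11, "y": 12}])
        assert (out[0].x_px, out[0].y_px) == (11, 12)
        assert out[0].provenance == "manual"

    def test_remove_missing_id(self):
        with pytest.raises(InvalidEditError):
            manual_correction(self.dots, [{"op": "remove", "id": 7}])

    def test_out_of_bounds_add(self):
        with pytest.raises(InvalidEditError):
            manual_correction(self.dots, [{"op": "add", "x": 999, "y": 0}],
                              image_shape=(100, 100))


def test_threshold_monotonicity(clean_frame_30):
    """Raising the similarity or luminance threshold never adds pixels."""
    image, _ = clean_frame_30
    prev = None
    for thr in (0.5, 0.7, 0.9, 0.99):
        m = cosine_similarity_mask(image, (0, 255, 0), thr)
        if prev is not None:
            assert not (m & ~prev).any()
        prev = m
    prev = None
    for thr in (0.3, 0.5, 0.7, 0.9):
        m = luminance_mask(image, MaskCascadeConfig(luminance_threshold=thr))
        if prev is not None:
            assert not (m & ~prev).any()
        prev = m


def test_full_cascade_perfect_on_clean_frame(clean_frame_30):
    """100 % recall and precision on a noise-free frame (1.5 px match)."""
    image, truth = clean_frame_30
    res = detect_dots(image)
    assert len(res.dots) == 121
    tpos = np.array([[t.x_px, t.y_px] for t in truth])
    from scipy.spatial import cKDTree

    tree = cKDTree(tpos)
    dist, idx = tree.query([[d.x_px, d.y_px] for d in res.dots])
    assert dist.max() < 1.5
    assert len(set(idx)) == 121
    center_true = next(t for t in truth if t.is_center)
    assert np.hypot(res.center.x_px - center_true.x_px,
                    res.center.y_px - center_true.y_px) < 1.5
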