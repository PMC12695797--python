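"""Multi-feature scoring, circle fitting and region-level detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orchardvision.cluster import connected_regions
from orchardvision.fusion import (
    DegenerateCircleError,
    Detection,
    FusionWeights,
    GlcmSpec,
    composite_score,
    detect_apples,
    fit_circle,
    fit_circle_region,
    glcm_score,
    shape_score,
    weighted_centroid,
)
from orchardvision.preprocess import HsiImage


def region_of(mask):
    regions = connected_regions(mask)
    assert len(regions) == 1
    return regions[0]


def disc_mask(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


class TestGlcm:
    def test_constant_window(self):
        win = np.full((21, 21), 90, dtype=np.uint8)
        assert glcm_score(win, GlcmSpec(statistic="energy")) == pytest.approx(1.0)
        assert glcm_score(win, GlcmSpec(statistic="contrast")) == pytest.approx(0.0)

    def test_checkerboard_contrast_is_maximal(self):
        win = np.indices((16, 16)).sum(axis=0) % 2 * 255
        spec = GlcmSpec(distance=1, angles=(0.0,), levels=2, statistic="contrast")
        assert glcm_score(win.astype(np.uint8), spec) == pytest.approx(1.0)

    def test_energy_lower_bound(self):
        rng = np.random.default_rng(0)
        win = rng.integers(0, 256, (21, 21), dtype=np.uint8)
        spec = GlcmSpec(levels=8, statistic="energy")
        assert 1.0 / 8**2 <= glcm_score(win, spec) <= 1.0

    def test_window_smaller_than_distance(self):
        with pytest.raises(ValueError):
            glcm_score(np.zeros((2, 2), dtype=np.uint8), GlcmSpec(distance=3))


class TestShapeScore:
    def test_disc_is_nearly_circular(self):
        region = region_of(disc_mask((70, 70), (35, 35), 30))
        assert shape_score(region) >= 0.9

    def test_square_circularity(self):
        mask = np.zeros((40, 40), bool)
        mask[5:35, 5:35] = True
        assert shape_score(region_of(mask)) == pytest.approx(np.pi / 4, abs=0.08)

    def test_thin_line_scores_low(self):
        mask = np.zeros((5, 30), bool)
        mask[2, 2:22] = True
        assert shape_score(region_of(mask)) < 0.3


class TestCompositeScore:
    def test_examples(self):
        w = FusionWeights(0.5, 0.3, 0.2)
        assert composite_score(1, 1, 1, w) == pytest.approx(1.0)
        assert composite_score(0, 0, 0, w) == pytest.approx(0.0)
        assert composite_score(0.8, 0.5, 1.0, w) == pytest.approx(0.75)

    def test_component_out_of_range(self):
        with pytest.raises(ValueError):
            composite_score(1.2, 0.5, 0.5, FusionWeights())

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    def test_convex_combination_bounds(self, h, g, s):
        t = composite_score(h, g, s, FusionWeights(0.5, 0.3, 0.2))
        assert min(h, g, s) - 1e-12 <= t <= max(h, g, s) + 1e-12

    def test_weights_normalized(self):
        w = FusionWeights(5.0, 3.0, 2.0)
        assert w.alpha_color + w.alpha_texture + w.alpha_shape == pytest.approx(1.0)
        assert w.alpha_color == pytest.approx(0.5)


class TestWeightedCentroid:
    def test_uniform_weights_on_disc_give_center(self):
        region = region_of(disc_mask((41, 41), (20, 20), 15))
        c = weighted_centroid(region, np.ones((41, 41)))
        assert c == pytest.approx((20.0, 20.0), abs=1e-9)

    def test_lever_rule(self):
        # three-pixel row whose middle pixel has zero weight: the centroid
        # reduces to the two end pixels (0,0) and (0,2) with weights 1 and 3
        mask = np.zeros((3, 5), bool)
        mask[0, 0:3] = True
        weights = np.zeros((3, 5))
        weights[0, 0], weights[0, 2] = 1.0, 3.0
        region = connected_regions(mask)[0]
        assert weighted_centroid(region, weights) == pytest.approx((0.0, 1.5))

    def test_uniform_equals_unweighted(self):
        rng = np.random.default_rng(2)
        mask = rng.random((20, 20)) > 0.5
        regions = connected_regions(mask)
        for region in regions:
            c = weighted_centroid(region, np.ones(mask.shape))
            assert c == pytest.approx(region.centroid, abs=1e-9)

    def test_zero_weights_error(self):
        region = region_of(disc_mask((21, 21), (10, 10), 6))
        with pytest.raises(ValueError):
            weighted_centroid(region, np.zeros((21, 21)))


class TestFitCircle:
    def test_three_points_circumcircle(self):
        pts = np.array([[0.0, 1.0], [1.0, 0.0], [0.0, -1.0]])
        (r0, c0), radius = fit_circle(pts)
        assert (r0, c0) == pytest.approx((0.0, 0.0), abs=1e-9)
        assert radius == pytest.approx(1.0, abs=1e-9)

    def test_exact_continuous_circle(self):
        theta = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pts = np.column_stack([5 + 7 * np.sin(theta), -3 + 7 * np.cos(theta)])
        (r0, c0), radius = fit_circle(pts)
        assert (r0, c0) == pytest.approx((5.0, -3.0), abs=1e-9)
        assert radius == pytest.approx(7.0, abs=1e-9)

    def test_rasterized_disc_radius_recovery(self):
        region = region_of(disc_mask((50, 50), (25.0, 25.0), 20.0))
        (r0, c0), radius = fit_circle_region(region)
        assert radius == pytest.approx(20.0, abs=0.5)
        assert (r0, c0) == pytest.approx((25.0, 25.0), abs=0.5)

    def test_collinear_points_degenerate(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(DegenerateCircleError):
            fit_circle(pts)


class TestDetectApples:
    def _hsi(self, hue_plane):
        h = np.asarray(hue_plane, dtype=float)
        return HsiImage(h=h, s=np.full(h.shape, 0.8), i=np.full(h.shape, 0.5))

    def test_single_clean_apple(self):
        shape = (80, 80)
        mask = disc_mask(shape, (40.0, 40.0), 18.0)
        hue = np.where(mask, 2.0, 120.0)
        gray = np.where(mask, 160, 60).astype(np.uint8)
        dets = detect_apples(mask, self._hsi(hue), gray, threshold=0.6, hue_reference=0.0)
        assert len(dets) == 1
        assert dets[0].centroid == pytest.approx((40.0, 40.0), abs=1.0)
        assert dets[0].radius == pytest.approx(18.0, abs=1.0)

    def test_empty_mask_gives_no_detections(self):
        shape = (40, 40)
        hsi = self._hsi(np.full(shape, 120.0))
        out = detect_apples(np.zeros(shape, bool), hsi, np.zeros(shape, np.uint8))
        assert out == []

    def test_elongated_streak_rejected(self):
        """A rough, branch-coloured streak fails the fused threshold.

        The components are computed with the individual scoring functions
        first (the oracle for the fused value), confirming T < 0.6, then
        the region-level detector is checked to agree.
        """
        shape = (60, 80)
        mask = np.zeros(shape, bool)
        mask[28:32, 5:75] = True  # 4 x 70 streak
        hue = np.where(mask, 12.0, 120.0)  # bark red-brown vs foliage
        rng = np.random.default_rng(0)
        gray = rng.integers(0, 256, shape).astype(np.uint8)  # rough texture
        region = connected_regions(mask)[0]
        weights = FusionWeights()
        s = shape_score(region)
        g = glcm_score(gray[region.slices], GlcmSpec())
        h = max(0.0, 1.0 - 12.0 / 60.0)
        assert s < 0.3
        assert composite_score(h, g, s, weights) < 0.6
        dets = detect_apples(
            mask, self._hsi(hue), gray, weights=weights, threshold=0.6, hue_reference=0.0, min_area=60.0
        )
        assert dets == []


def test_detection_count_on_clean_scenes(clean_detection):
    """Zero-occlusion, zero-noise scenes: one detection per true apple."""
    result, truth, _ = clean_detection
    assert len(result.detections) == len(truth.apples)
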