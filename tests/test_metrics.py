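"""Detection/segmentation evaluation statistics."""

import numpy as np
import pytest

from orchardvision.fusion import Detection
from orchardvision.metrics import (
    angle_stability,
    correct_recognition_rate,
    match_detections,
    mean_coordinate_deviation,
    precision_recall_f1_map,
    recognition_accuracy,
)
from orchardvision.stereo import StereoRig
from orchardvision.synth import AppleTruth, SceneTruth


def truth_of(centroids, radius=10.0, image_size=(540, 960)):
    return SceneTruth(
        apples=tuple(
            AppleTruth(centroid=c, radius=radius, depth_mm=900.0, overlap_frac=0.0) for c in centroids
        ),
        rig=StereoRig.centered(image_size),
        lighting="day",
        image_size=image_size,
    )


def det(row, col, score=0.9, radius=10.0):
    return Detection(centroid=(row, col), radius=radius, score=score, region_id=0)


class TestMatching:
    def test_perfect_detections(self):
        truth = truth_of([(50.0, 50.0), (100.0, 200.0)])
        m = match_detections([det(50, 50), det(100, 200)], truth)
        assert (m.true_positives, m.false_positives, m.false_negatives) == (2, 0, 0)

    def test_empty_detections(self):
        truth = truth_of([(50.0, 50.0), (100.0, 200.0)])
        m = match_detections([], truth)
        assert (m.true_positives, m.false_positives, m.false_negatives) == (0, 0, 2)

    def test_equidistant_tie_breaks_to_lower_index(self):
        truth = truth_of([(50.0, 50.0)])
        m = match_detections([det(50, 55), det(50, 45)], truth)
        assert m.true_positives == 1 and m.false_positives == 1
        assert m.pairs[0][0] == 0  # lower detection index wins the tie

    def test_conservation_under_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            truth = truth_of([(rng.uniform(0, 500), rng.uniform(0, 900)) for _ in range(6)])
            dets = [det(rng.uniform(0, 500), rng.uniform(0, 900)) for _ in range(8)]
            m = match_detections(dets, truth)
            assert m.true_positives + m.false_negatives == 6
            assert m.true_positives + m.false_positives == 8

    def test_reorder_invariance_of_counts(self):
        rng = np.random.default_rng(1)
        truth = truth_of([(rng.uniform(0, 500), rng.uniform(0, 900)) for _ in range(5)])
        dets = [det(rng.uniform(0, 500), rng.uniform(0, 900)) for _ in range(7)]
        m1 = match_detections(dets, truth)
        m2 = match_detections(dets[::-1], truth)
        assert (m1.true_positives, m1.false_positives) == (m2.true_positives, m2.false_positives)


class TestRates:
    def test_recognition_accuracy(self):
        truth = truth_of([(10.0, 10.0)] )
        assert recognition_accuracy(match_detections([det(10, 10)], truth)) == 100.0
        assert recognition_accuracy(match_detections([], truth)) == 0.0

    def test_recognition_accuracy_ratio(self):
        """39 of 42 recovered -> 92.86%."""
        centroids = [(20.0 + 25 * i, 20.0 + 20 * (i % 20)) for i in range(42)]
        truth = truth_of(centroids, radius=5.0, image_size=(1200, 1200))
        dets = [det(r, c, radius=5.0) for r, c in centroids[:39]]
        ra = recognition_accuracy(match_detections(dets, truth))
        assert ra == pytest.approx(100 * 39 / 42, abs=1e-9)
        assert round(ra, 2) == 92.86

    def test_mcd_single_pair(self):
        truth = truth_of([(100.0, 100.0)], radius=20.0)
        m = match_detections([det(100.0, 111.0, radius=20.0)], truth)
        diag = np.hypot(1920, 1080)
        assert mean_coordinate_deviation(m, diag) == pytest.approx(0.4994, abs=1e-4)

    def test_mcd_zero_and_undefined(self):
        truth = truth_of([(100.0, 100.0)])
        assert mean_coordinate_deviation(match_detections([det(100, 100)], truth), 1000.0) == 0.0
        with pytest.raises(ValueError):
            mean_coordinate_deviation(match_detections([], truth), 1000.0)


class TestCrr:
    def _truth_one(self, center=(30.0, 30.0), radius=12.0):
        return truth_of([center], radius=radius, image_size=(60, 60))

    def test_perfect_mask(self):
        truth = self._truth_one()
        yy, xx = np.mgrid[:60, :60]
        mask = (yy - 30.0) ** 2 + (xx - 30.0) ** 2 <= 12.0**2
        assert correct_recognition_rate(mask, truth) == 100.0

    def test_empty_mask(self):
        assert correct_recognition_rate(np.zeros((60, 60), bool), self._truth_one()) == 0.0

    def test_iou_exactly_at_threshold_counts(self):
        """A half disc has IoU 0.5 against the full disc: counted at >=."""
        truth = self._truth_one()
        yy, xx = np.mgrid[:60, :60]
        disc = (yy - 30.0) ** 2 + (xx - 30.0) ** 2 <= 12.0**2
        half = disc & (xx <= 30)
        iou = half.sum() / disc.sum()
        assert correct_recognition_rate(half, truth, iou_threshold=iou) == 100.0
        assert correct_recognition_rate(half, truth, iou_threshold=iou + 0.01) == 0.0


class TestPrfMap:
    def test_perfect_ranking(self):
        truth = truth_of([(10.0, 10.0), (50.0, 50.0)])
        dets = [det(10, 10, 0.9), det(50, 50, 0.8)]
        m = match_detections(dets, truth)
        p, r, f1, ap = precision_recall_f1_map(m, [0.9, 0.8])
        assert (p, r, f1, ap) == pytest.approx((1.0, 1.0, 1.0, 1.0))

    def test_all_false_positives(self):
        truth = truth_of([(10.0, 10.0)])
        dets = [det(400, 400, 0.9)]
        m = match_detections(dets, truth)
        p, r, f1, ap = precision_recall_f1_map(m, [0.9])
        assert (p, r, f1, ap) == (0.0, 0.0, 0.0, 0.0)

    def test_high_scoring_tp_before_fp(self):
        """TP at 0.9 then FP at 0.8 over one truth apple: AP = 1."""
        truth = truth_of([(10.0, 10.0)])
        dets = [det(10, 10, 0.9), det(400, 400, 0.8)]
        m = match_detections(dets, truth)
        _, _, _, ap = precision_recall_f1_map(m, [0.9, 0.8])
        assert ap == pytest.approx(1.0)

    def test_f1_harmonic_mean(self):
        truth = truth_of([(10.0, 10.0), (50.0, 50.0), (90.0, 90.0)])
        dets = [det(10, 10, 0.9), det(400, 400, 0.8)]
        m = match_detections(dets, truth)
        p, r, f1, _ = precision_recall_f1_map(m, [0.9, 0.8])
        assert p == pytest.approx(0.5)
        assert r == pytest.approx(1 / 3)
        assert f1 == pytest.approx(2 * p * r / (p + r))


class TestAngleStability:
    def test_identical_replicates_have_zero_std(self):
        table = angle_stability({0.0: [92.0, 92.0, 92.0]})
        assert table.std_ra.iloc[0] == 0.0

    def test_two_point_sample_std(self):
        table = angle_stability({15.0: [90.0, 94.0]})
        assert table.std_ra.iloc[0] == pytest.approx(2.828, abs=1e-3)

    def test_std_nonnegative_and_sorted(self):
        rng = np.random.default_rng(0)
        table = angle_stability({a: rng.uniform(80, 100, 4) for a in (45.0, 0.0, 30.0, 15.0)})
        assert (table.std_ra >= 0).all()
        assert list(table.angle_deg) == [0.0, 15.0, 30.0, 45.0]
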