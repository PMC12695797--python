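"""Enhanced K-Means: adaptive centres, weighted distance, morphology, regions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orchardvision.cluster import (
    ClusterModel,
    DegenerateImageError,
    FeatureSpace,
    connected_regions,
    extract_boundary,
    kmeans_segment,
    morph_clean,
    regions_from_labels,
    select_initial_centers,
    split_instances,
    weighted_distance,
)


def space_1d(plane, weight=1.0):
    return FeatureSpace.from_planes(np.asarray(plane, dtype=float), weights=[weight])


def brute_force_scores(space, radius, eps):
    """Independent density-score oracle: direct per-pixel double loop."""
    vals = space.values
    w = space.weights
    h, wd, _ = vals.shape
    scores = np.zeros((h, wd))
    for i in range(h):
        for j in range(wd):
            for di in range(-radius, radius + 1):
                for dj in range(-radius, radius + 1):
                    if di == dj == 0:
                        continue
                    ii = min(max(i + di, 0), h - 1)
                    jj = min(max(j + dj, 0), wd - 1)
                    d = np.sqrt(np.sum(w * (vals[i, j] - vals[ii, jj]) ** 2))
                    scores[i, j] += 1.0 / (d + eps)
    return scores


def optimal_1d_two_means(values):
    """Exhaustive oracle: best 2-cluster split of sorted 1-D values."""
    x = np.sort(values)
    best, best_cut = np.inf, None
    for cut in range(1, len(x)):
        lo, hi = x[:cut], x[cut:]
        ss = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if ss < best:
            best, best_cut = ss, cut
    return x[best_cut - 1], x[best_cut]  # split threshold lies between these


class TestWeightedDistance:
    @pytest.mark.parametrize(
        "x,y,w,expected",
        [
            ((1.0, 2.0), (1.0, 2.0), (1.0, 1.0), 0.0),
            ((0.0, 3.0), (4.0, 0.0), (1.0, 1.0), 5.0),
            ((1.0,), (3.0,), (4.0,), 4.0),
        ],
    )
    def test_examples(self, x, y, w, expected):
        assert weighted_distance(x, y, w) == pytest.approx(expected)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            weighted_distance((1.0, 2.0), (1.0,), (1.0, 1.0))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=4))
    def test_symmetry_and_identity(self, xs):
        x = np.array(xs)
        y = x[::-1].copy()
        w = np.ones_like(x)
        assert weighted_distance(x, x, w) == 0.0
        assert weighted_distance(x, y, w) == pytest.approx(weighted_distance(y, x, w))


class TestSelectInitialCenters:
    def test_two_tone_image_finds_both_tones(self):
        plane = np.zeros((10, 10))
        plane[:, 5:] = 120.0
        centers = select_initial_centers(space_1d(plane), 2, min_separation=12.0)
        assert sorted(centers[:, 0]) == [0.0, 120.0]

    def test_matches_brute_force_scoring(self):
        rng = np.random.default_rng(3)
        plane = rng.normal(50.0, 5.0, (8, 8))
        space = space_1d(plane)
        oracle = brute_force_scores(space, radius=2, eps=1e-3)
        centers = select_initial_centers(space, 1, min_separation=1.0)
        best = np.unravel_index(np.argmax(oracle), oracle.shape)
        assert centers[0, 0] == pytest.approx(plane[best])

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateImageError):
            select_initial_centers(space_1d(np.full((6, 6), 7.0)), 2)

    def test_candidate_mask_restricts_first_center(self):
        plane = np.zeros((10, 10))
        plane[:, 5:] = 120.0
        mask = plane > 60.0
        centers = select_initial_centers(space_1d(plane), 1, candidate_mask=mask)
        assert centers[0, 0] == 120.0

    def test_seed_counts_toward_k(self):
        plane = np.zeros((10, 10))
        plane[:, 5:] = 120.0
        centers = select_initial_centers(
            space_1d(plane), 2, min_separation=12.0, seeds=np.array([[120.0]])
        )
        assert centers[0, 0] == 120.0
        assert centers[1, 0] == 0.0


class TestKmeansSegment:
    def test_matches_exhaustive_two_means_oracle(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate([rng.normal(0, 3, 120), rng.normal(120, 3, 130)])
        plane = vals.reshape(10, 25)
        space = space_1d(plane)
        mask = kmeans_segment(space, ClusterModel(k=2, min_separation=12.0))
        lo_max, hi_min = optimal_1d_two_means(vals)
        threshold = (lo_max + hi_min) / 2
        expected = (plane > threshold).astype(int)
        labels = mask.labels
        if mask.centers[0, 0] > mask.centers[1, 0]:
            labels = 1 - labels
        assert np.array_equal(labels, expected)

    def test_fixed_point_when_centers_exact(self):
        plane = np.zeros((6, 6))
        plane[:, 3:] = 100.0
        model = ClusterModel(k=2, centers=np.array([[0.0], [100.0]]))
        mask = kmeans_segment(space_1d(plane), model)
        assert mask.n_iter == 1
        assert np.array_equal(mask.labels, (plane > 50).astype(int))

    def test_pixel_order_invariance(self):
        rng = np.random.default_rng(11)
        plane = rng.uniform(0, 130, (12, 12))
        space = space_1d(plane)
        model = ClusterModel(k=2, centers=np.array([[10.0], [110.0]]))
        mask = kmeans_segment(space, model)
        # permute rows: the per-pixel assignment must permute identically
        perm = rng.permutation(12)
        mask_p = kmeans_segment(space_1d(plane[perm]), model)
        assert np.array_equal(mask.labels[perm], mask_p.labels)

    @pytest.mark.parametrize("seed", range(10))
    def test_objective_monotone(self, seed):
        rng = np.random.default_rng(seed)
        plane = rng.uniform(0, 130, (15, 15))
        mask = kmeans_segment(space_1d(plane), ClusterModel(k=3, min_separation=5.0))
        obj = np.array(mask.objective)
        assert np.all(np.diff(obj) <= 1e-6 * max(1.0, obj[0]))


class TestMorphology:
    def test_speck_removed(self):
        mask = np.zeros((20, 20), bool)
        mask[10, 10] = True
        assert not morph_clean(mask, selem_radius=1, min_area=5).any()

    def test_large_disc_preserved(self, ):
        yy, xx = np.mgrid[:40, :40]
        disc = (yy - 20) ** 2 + (xx - 20) ** 2 <= 12**2
        out = morph_clean(disc, selem_radius=1, min_area=5)
        assert abs(out.sum() - disc.sum()) / disc.sum() < 0.15

    def test_empty_mask_unchanged(self):
        mask = np.zeros((10, 10), bool)
        assert not morph_clean(mask, 1, 5).any()


class TestBoundary:
    def test_square_frame(self):
        mask = np.zeros((9, 9), bool)
        mask[2:7, 2:7] = True  # 5x5 solid square
        boundary = extract_boundary(mask, selem_radius=1)
        assert boundary.sum() == 16
        assert not boundary[3:6, 3:6].any()

    def test_empty_and_single_pixel(self):
        assert not extract_boundary(np.zeros((5, 5), bool)).any()
        single = np.zeros((5, 5), bool)
        single[2, 2] = True
        assert np.array_equal(extract_boundary(single), single)

    @pytest.mark.parametrize("seed", range(5))
    def test_containment_and_idempotence_subset(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((30, 30)) > 0.4
        boundary = extract_boundary(mask)
        assert not (boundary & ~mask).any()
        again = extract_boundary(boundary)
        assert not (again & ~boundary).any()


class TestRegions:
    def test_two_disjoint_squares(self):
        mask = np.zeros((12, 12), bool)
        mask[1:4, 1:4] = True
        mask[7:10, 7:10] = True
        regions = connected_regions(mask)
        assert len(regions) == 2
        assert all(r.area == 9 for r in regions)

    def test_diagonal_pixels_are_one_region(self):
        mask = np.zeros((5, 5), bool)
        mask[1, 1] = mask[2, 2] = True
        assert len(connected_regions(mask)) == 1

    def test_min_area_filter(self):
        mask = np.zeros((6, 6), bool)
        mask[1, 1:4] = True  # area 3
        assert connected_regions(mask, min_area=4) == []

    def test_split_touching_discs(self):
        yy, xx = np.mgrid[:60, :90]
        a = (yy - 30) ** 2 + (xx - 30) ** 2 <= 15**2
        b = (yy - 30) ** 2 + (xx - 45) ** 2 <= 15**2
        labels = split_instances(a | b, min_distance=6)
        regions = regions_from_labels(labels)
        assert len(regions) == 2
        cols = sorted(r.centroid[1] for r in regions)
        assert cols[0] == pytest.approx(28, abs=3)
        assert cols[1] == pytest.approx(47, abs=3)
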