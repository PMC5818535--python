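"""ROI segmentation, pairwise-distance histograms, CSR normalisation, radii."""

import numpy as np
import pytest

from synucalc import simulate, smlm
from synucalc.errors import InputError
from synucalc.smlm import (
    Disc,
    PointPattern,
    Rect,
    cluster_radius,
    compare_radii,
    csr_normalize,
    pair_distance_histogram,
    segment_rois,
)


def _disc_pattern(points, radius=1000.0):
    c = points.mean(axis=0)
    r = max(np.hypot(*(points - c).T).max() * 1.05, radius)
    return PointPattern(points=points, region=Disc(c[0], c[1], r))


class TestSegmentRois:
    def test_one_blob(self, rng):
        pts = rng.normal(0, 50, (500, 2))
        assert len(segment_rois(pts, linkage=200.0, min_locs=50)) == 1

    def test_two_distant_blobs(self, rng):
        a = rng.normal(0, 50, (300, 2))
        b = rng.normal(5000, 50, (300, 2))
        rois = segment_rois(np.vstack([a, b]), linkage=200.0, min_locs=50)
        assert len(rois) == 2

    def test_small_blob_filtered(self, rng):
        pts = rng.normal(0, 20, (20, 2))
        assert segment_rois(pts, linkage=200.0, min_locs=50) == []

    def test_empty_table(self):
        assert segment_rois(np.empty((0, 2))) == []


class TestPairDistanceHistogram:
    def test_two_points(self):
        pat = _disc_pattern(np.array([[0.0, 0.0], [70.0, 0.0]]))
        h = pair_distance_histogram(pat, bin_width=10.0, max_dist=200.0)
        assert h.counts.sum() == 1
        assert h.counts[7] == 1  # bin [70, 80)

    def test_equilateral_triangle(self):
        s = 100.0
        pts = np.array([[0, 0], [s, 0], [s / 2, s * np.sqrt(3) / 2]])
        h = pair_distance_histogram(_disc_pattern(pts), bin_width=10.0, max_dist=300.0)
        assert h.counts[10] == 3  # bin [100, 110)
        assert h.counts.sum() == 3

    def test_total_pair_count(self, rng):
        pts = rng.uniform(-400, 400, (40, 2))
        pat = _disc_pattern(pts)
        h = pair_distance_histogram(pat, bin_width=10.0)
        assert h.counts.sum() <= 40 * 39 // 2

    def test_single_point_rejected(self):
        with pytest.raises(InputError):
            pair_distance_histogram(
                PointPattern(points=np.array([[0.0, 0.0]]), region=Disc(0, 0, 10))
            )


class TestCsrNormalize:
    def test_uniform_pattern_near_unity(self):
        # CSR self-consistency at 100 randomizations, within 3 MC SDs
        rng = np.random.default_rng(42)
        region = Disc(0.0, 0.0, 1000.0)
        pat = PointPattern(points=region.sample(rng, 400), region=region)
        h = pair_distance_histogram(pat, bin_width=50.0)
        norm = csr_normalize(h, pat, n_rand=100, seed=7)
        ok = norm.csr_mean > 20  # bins with enough expected mass
        dev = np.abs(norm.values[ok] - 1.0)
        tol = 3.0 * norm.csr_sd[ok] / norm.csr_mean[ok]
        assert np.all(dev <= tol + 0.02)

    def test_coincident_points_first_bin(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 1.0, (50, 2))
        pat = PointPattern(points=pts, region=Disc(0, 0, 1000.0))
        h = pair_distance_histogram(pat, bin_width=10.0)
        norm = csr_normalize(h, pat, n_rand=50, seed=1)
        assert norm.values[0] > 10

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 40, (150, 2))
        pat1 = PointPattern(points=pts, region=Disc(0, 0, 500.0))
        pat2 = PointPattern(points=pts * 3.0, region=Disc(0, 0, 1500.0))
        h1 = pair_distance_histogram(pat1, bin_width=10.0, max_dist=1000.0)
        h2 = pair_distance_histogram(pat2, bin_width=30.0, max_dist=3000.0)
        n1 = csr_normalize(h1, pat1, n_rand=80, seed=5)
        n2 = csr_normalize(h2, pat2, n_rand=80, seed=5)
        ok = (n1.csr_mean > 5) & (n2.csr_mean > 5)
        assert np.allclose(n1.values[ok], n2.values[ok], rtol=0, atol=0.25)


class TestClusterRadius:
    def test_gaussian_cluster_radius_band(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(0, 30.0, (400, 2))
        pat = PointPattern(points=pts, region=Disc(0, 0, 1000.0))
        res = cluster_radius(pat, seed=2)
        assert 20.0 <= res.radius <= 80.0
        pts2 = rng.normal(0, 100.0, (400, 2))
        pat2 = PointPattern(points=pts2, region=Disc(0, 0, 1000.0))
        res2 = cluster_radius(pat2, seed=2)
        assert res2.radius > res.radius

    def test_monotone_in_cluster_scale(self):
        rng = np.random.default_rng(23)
        radii = []
        for sigma in (20.0, 50.0, 100.0):
            pts = rng.normal(0, sigma, (400, 2))
            pat = PointPattern(points=pts, region=Disc(0, 0, 1200.0))
            radii.append(cluster_radius(pat, seed=3).radius)
        assert radii[0] < radii[1] < radii[2]

    def test_uniform_pattern_unreliable(self):
        rng = np.random.default_rng(5)
        region = Disc(0, 0, 1000.0)
        pat = PointPattern(points=region.sample(rng, 300), region=region)
        res = cluster_radius(pat, seed=4)
        assert not res.reliable

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(29)
        pts = rng.normal(0, 40.0, (200, 2))
        pat = PointPattern(points=pts, region=Disc(0, 0, 800.0))
        base = cluster_radius(pat, seed=6)
        shift = np.array([1234.5, -987.6])
        pat_t = PointPattern(points=pts + shift, region=Disc(*shift, 800.0))
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pat_r = PointPattern(points=pts @ rot.T, region=Disc(0, 0, 800.0))
        assert cluster_radius(pat_t, seed=6).radius == base.radius
        assert cluster_radius(pat_r, seed=6).radius == base.radius

    def test_argmax_method_prefers_smaller_tie(self):
        rng = np.random.default_rng(31)
        pts = rng.normal(0, 30.0, (300, 2))
        pat = PointPattern(points=pts, region=Disc(0, 0, 900.0))
        res = cluster_radius(pat, seed=8, method="argmax")
        # per-bin ratio of a unimodal cluster peaks in the first bins
        assert res.radius <= 30.0

    def test_too_few_points_rejected(self):
        pat = PointPattern(points=np.zeros((5, 2)), region=Disc(0, 0, 100.0))
        with pytest.raises(InputError):
            cluster_radius(pat)


class TestCompareRadii:
    def test_identical_groups(self):
        res = compare_radii([50.0, 50.0], [50.0, 50.0])
        assert res.mean_diff == 0.0
        assert res.p_value == 1.0
        assert res.degenerate

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(77)
        a = rng.normal(60, 5, 20)
        b = rng.normal(120, 5, 20)
        res = compare_radii(a, b)
        assert res.p_value < 1e-3
        assert res.mean_diff < 0

    def test_unbalanced_groups_accepted(self):
        rng = np.random.default_rng(78)
        res = compare_radii(rng.normal(60, 5, 22), rng.normal(80, 5, 30))
        assert res.n_a == 22 and res.n_b == 30


class TestConditionOrdering:
    def test_dispersed_larger_than_clustered(self):
        radii = {}
        for preset in ("clustered", "dispersed"):
            locs, _ = simulate.generate_synaptosome_locs(seed=19, preset=preset)
            rois = segment_rois(locs)
            radii[preset] = [
                cluster_radius(r, seed=100 + i).radius for i, r in enumerate(rois)
            ]
        assert np.mean(radii["dispersed"]) > np.mean(radii["clustered"])
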