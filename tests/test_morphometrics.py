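"""Cluster detection, alpha-shape outlines and shape classification."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon, box

import spatialtme as st
from spatialtme.morphometrics import (
    circularity,
    classify_cluster,
    convexity,
    grow_alpha_shape,
)

W = box(0, 0, 3000, 3000)


class TestDetectClusters:
    def test_two_blobs(self):
        rng = np.random.default_rng(0)
        pts = np.vstack(
            [rng.normal([500, 500], 50, (100, 2)), rng.normal([2200, 2200], 50, (100, 2))]
        )
        clusters, labels = st.detect_clusters(st.PointPattern("m", pts, W))
        assert len(clusters) == 2
        assert all(len(c.points) >= 30 for c in clusters)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_sparse_poisson_all_noise(self, seed):
        pat = st.sim_poisson(10.0, W, seed=seed)  # ~90 points over 9 mm2
        clusters, labels = st.detect_clusters(pat)
        assert clusters == []
        assert (labels == -1).all()

    def test_below_min_pts_is_noise(self):
        rng = np.random.default_rng(2)
        pts = rng.normal([500, 500], 30, (29, 2))
        clusters, labels = st.detect_clusters(st.PointPattern("m", pts, W))
        assert clusters == []

    def test_order_invariant(self):
        rng = np.random.default_rng(3)
        pts = np.vstack(
            [rng.normal([600, 600], 40, (80, 2)), rng.normal([2400, 900], 40, (80, 2))]
        )
        c1, l1 = st.detect_clusters(st.PointPattern("m", pts, W))
        perm = rng.permutation(len(pts))
        c2, l2 = st.detect_clusters(st.PointPattern("m", pts[perm], W))
        sets1 = {frozenset(map(tuple, c.points)) for c in c1}
        sets2 = {frozenset(map(tuple, c.points)) for c in c2}
        assert sets1 == sets2


class TestAlphaShape:
    def test_three_points_triangle(self):
        poly, alpha, degenerate = grow_alpha_shape([(0, 0), (100, 0), (0, 100)])
        assert not degenerate
        assert poly.area == pytest.approx(5000.0)

    def test_ring_is_concave(self):
        theta = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        ring = np.column_stack([500 + 300 * np.cos(theta), 500 + 300 * np.sin(theta)])
        rng = np.random.default_rng(4)
        ring += rng.normal(0, 5, ring.shape)
        poly, alpha, degenerate = grow_alpha_shape(ring)
        hull = Polygon(ring[np.argsort(theta)]).convex_hull
        assert not degenerate
        assert convexity(poly, hull) < 1.0  # the hole keeps it concave

    def test_collinear_degenerate(self):
        poly, alpha, degenerate = grow_alpha_shape([(0, 0), (10, 0), (20, 0), (30, 0)])
        assert degenerate
        assert poly.area == 0.0

    def test_contains_all_members(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(0, 50, (120, 2))
        poly, _, _ = grow_alpha_shape(pts)
        import shapely

        assert shapely.contains_xy(poly.buffer(1e-6), pts[:, 0], pts[:, 1]).all()


class TestShapeMetrics:
    def test_square_circularity(self):
        sq = Polygon([(0, 0), (100, 0), (100, 100), (0, 100)])
        assert circularity(sq) == pytest.approx(np.pi / 4, abs=1e-6)

    def test_rectangle_circularity(self):
        rect = Polygon([(0, 0), (400, 0), (400, 100), (0, 100)])
        assert circularity(rect) == pytest.approx(4 * np.pi * 4 / 100, abs=1e-6)

    @pytest.mark.parametrize("n", [4, 8, 16, 64])
    def test_ngon_circularity_increases(self, n):
        def ngon(k):
            t = np.linspace(0, 2 * np.pi, k, endpoint=False)
            return Polygon(np.column_stack([np.cos(t), np.sin(t)]) * 100)

        if n > 4:
            assert circularity(ngon(n)) > circularity(ngon(n // 2))
        assert circularity(ngon(n)) < 1.0

    def test_convex_cluster_unity(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 200, (200, 2))
        # alpha0 beyond the circumradius cap -> the convex-hull cap applies
        poly, _, _ = grow_alpha_shape(pts, alpha0=1e6)
        from shapely.geometry import MultiPoint

        hull = MultiPoint(pts).convex_hull
        assert convexity(poly, hull) == pytest.approx(1.0, abs=1e-9)


class TestCovarianceEllipse:
    def test_isotropic_low_eccentricity(self):
        # sampling noise in the eigenvalue gap scales ~ n^(-1/2), so the
        # eccentricity of an isotropic sample decays like n^(-1/4)
        rng = np.random.default_rng(7)
        small = [st.eccentricity(*st.covariance_ellipse(rng.normal(0, 10, (10_000, 2)))[:2]) for _ in range(5)]
        large = [st.eccentricity(*st.covariance_ellipse(rng.normal(0, 10, (100_000, 2)))[:2]) for _ in range(5)]
        assert max(small) < 0.25
        assert np.mean(large) < np.mean(small)
        lam1, lam2, _, a, b = st.covariance_ellipse(rng.normal(0, 10, (10_000, 2)))
        assert a >= b

    def test_collinear_full_eccentricity(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10)])
        lam1, lam2, _, _, _ = st.covariance_ellipse(pts)
        assert st.eccentricity(lam1, lam2) == pytest.approx(1.0)

    def test_four_to_one_ratio(self):
        assert st.eccentricity(4.0, 1.0) == pytest.approx(np.sqrt(0.75), abs=1e-9)

    def test_axes_scale(self):
        # diag(400, 100) covariance -> a = sqrt(400*5.991), b = sqrt(100*5.991)
        rng = np.random.default_rng(8)
        pts = rng.normal(0, [20.0, 10.0], (50_000, 2))
        lam1, lam2, _, a, b = st.covariance_ellipse(pts)
        assert a == pytest.approx(np.sqrt(400 * 5.991), rel=0.03)
        assert b == pytest.approx(np.sqrt(100 * 5.991), rel=0.03)

    def test_coincident_rejected(self):
        with pytest.raises(ValueError):
            st.covariance_ellipse(np.zeros((5, 2)))


CLASSIFY_CASES = [
    # (convexity, circularity, eccentricity, expected)
    (0.95, 0.90, 0.20, "nodular"),
    (0.90, 0.90, 0.95, "elongated"),
    (0.50, 0.40, 0.85, "other"),
    (0.85, 0.60, 0.70, "nodular"),
    (0.81, 0.51, 0.79, "nodular"),  # just inside every nodular bound
    (0.80, 0.90, 0.10, "other"),  # convexity not strictly above 0.8
    (0.95, 0.50, 0.10, "other"),  # circularity not strictly above 0.5
    (0.95, 0.90, 0.80, "other"),  # eccentricity not strictly below 0.8
    (0.25, 0.90, 0.10, "elongated"),  # low convexity alone
    (0.95, 0.25, 0.10, "elongated"),  # low circularity alone
    (0.95, 0.90, 0.95, "elongated"),  # high eccentricity alone
    (0.29, 0.29, 0.95, "elongated"),
    (0.31, 0.31, 0.89, "other"),
    (0.60, 0.80, 0.50, "other"),
    (0.99, 0.99, 0.01, "nodular"),
    (0.10, 0.10, 0.99, "elongated"),
    (0.85, 0.45, 0.50, "other"),
    (0.75, 0.75, 0.50, "other"),
    (0.90, 0.55, 0.85, "other"),
    (0.90, 0.55, 0.91, "elongated"),
]


@pytest.mark.parametrize("cvx,circ,ecc,want", CLASSIFY_CASES)
def test_classification_rules(cvx, circ, ecc, want):
    assert classify_cluster(cvx, circ, ecc) == want


class TestRegionStats:
    def test_counts_and_assignment(self):
        circle = Point(1500, 1500).buffer(900, quad_segs=64)
        part = st.partition_regions(circle, W, if_width_mm=0.4)
        rng = np.random.default_rng(9)
        # one blob in CT (center), one in N (corner)
        pts = np.vstack(
            [rng.normal([1500, 1500], 60, (60, 2)), rng.normal([2700, 300], 60, (60, 2))]
        )
        clusters, _ = st.detect_clusters(st.PointPattern("m", pts, W), partition=part)
        stats = st.cluster_region_stats(clusters, part)
        assert stats["n_clusters"].sum() == len(clusters)
        ct_row = stats.set_index("region").loc["CT"]
        assert ct_row["n_clusters"] >= 1
        assert (stats["clusters_per_mm2"] >= 0).all()
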