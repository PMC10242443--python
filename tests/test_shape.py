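"""Ellipse classification and equal-length polyline fitting tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecsmap.geometry import polyline_distances
from ecsmap.shape import (
    EllipseShapeClassifier,
    EqualLengthPolyline,
    PointCloud,
    PolylineSegmentCV,
    classify_shape,
    extract_segments,
    fit_ellipse,
    fit_polyline,
)
from helpers import make_l_cloud, make_straight_cloud


def dense_polyline_distance_oracle(points, vertices, per_segment=8000):
    """Brute-force oracle: distance to a densely sampled polyline.

    Each segment is sampled including both endpoints, so corner-nearest
    points are handled exactly and the residual error is quadratic in the
    sample spacing.
    """
    vertices = np.asarray(vertices, dtype=float)
    chunks = []
    for a, b in zip(vertices[:-1], vertices[1:]):
        f = np.linspace(0.0, 1.0, per_segment)[:, None]
        chunks.append(a + f * (b - a))
    samples = np.vstack(chunks)
    d = np.linalg.norm(points[:, None, :] - samples[None, :, :], axis=-1)
    return d.min(axis=1)


class TestEllipse:
    def test_square_corners_isotropic(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        e = fit_ellipse(pts)
        assert e.ratio == pytest.approx(1.0)
        assert classify_shape(e).label == "0D"
        assert classify_shape(e).length == 0.0

    def test_collinear_cloud_degenerate(self):
        pts = np.column_stack([np.linspace(0, 1, 9), np.zeros(9)])
        e = fit_ellipse(pts)
        assert e.b == 0.0 and e.ratio == math.inf
        assert classify_shape(e).label == "1D"

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            PointCloud(np.ones((5, 2)))

    def test_anisotropic_gaussian_ratio_recovered(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 1, (1000, 2)) * [2.0, 1.0]
        e = fit_ellipse(pts)
        assert e.ratio == pytest.approx(2.0, rel=0.10)
        assert e.orientation == pytest.approx(0.0, abs=0.1) or e.orientation == pytest.approx(
            np.pi, abs=0.1
        )

    def test_ratio_just_below_threshold_is_0d(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, (500, 2))
        e = fit_ellipse(base * [1.05, 1.0])
        assert classify_shape(e).label == "0D"

    @settings(deadline=None, max_examples=20)
    @given(
        angle=st.floats(0, np.pi),
        dx=st.floats(-5, 5),
        dy=st.floats(-5, 5),
    )
    def test_classification_rigid_motion_invariant(self, angle, dx, dy):
        rng = np.random.default_rng(7)
        pts = rng.normal(0, 1, (300, 2)) * [2.0, 1.0]
        rot = np.array(
            [[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]]
        )
        moved = pts @ rot.T + [dx, dy]
        assert (
            classify_shape(fit_ellipse(pts)).label
            == classify_shape(fit_ellipse(moved)).label
        )

    def test_estimator_interface(self):
        rng = np.random.default_rng(1)
        clf = EllipseShapeClassifier().fit(rng.normal(0, 1, (100, 2)) * [3.0, 1.0])
        assert clf.predict() == "1D"
        assert clf.get_params()["threshold"] == pytest.approx(math.sqrt(2))


class TestPolyline:
    def test_points_on_segment_zero_residual(self):
        t = np.linspace(0, 1, 30)
        pts = np.column_stack([t, t])
        fit = fit_polyline(pts, k=1, penalty=0.0, seed=0)
        assert fit.mse < 1e-8
        assert fit.total_length >= math.sqrt(2) - 1e-3

    def test_two_points_closed_form(self):
        # exact optimum for two points at distance d, k=1: the segment lies
        # on the joining line but retreats eps = lambda from each point
        # (the length saving lambda*2*eps balances the residual eps^2), so
        # J* = lambda*d - lambda^2 and mse* = lambda^2; J ~ lambda*d for
        # small lambda
        pts = np.array([[0.0, 0.0], [0.0, 2.0]])
        lam = 0.05
        est = EqualLengthPolyline(n_segments=1, penalty=lam, random_state=0).fit(pts)
        assert est.mse_ == pytest.approx(lam**2, rel=1e-3)
        assert est.objective_ == pytest.approx(lam * 2.0 - lam**2, rel=1e-4)
        assert est.segment_length_ == pytest.approx(2.0 - 2 * lam, rel=1e-3)

    def test_segment_lengths_equal_by_construction(self):
        rng = np.random.default_rng(2)
        fit = fit_polyline(make_l_cloud(rng), k=3, seed=1)
        seg_lens = np.linalg.norm(np.diff(fit.vertices, axis=0), axis=1)
        assert np.all(np.abs(seg_lens - fit.segment_length) <= 1e-6 * fit.segment_length)

    def test_l_shape_corner_recovered(self):
        sigma = 0.02
        rng = np.random.default_rng(4)
        pts = make_l_cloud(rng, n=100, sigma=sigma)
        fit = fit_polyline(pts, k=2, seed=3)
        corner = fit.vertices[1]
        assert np.linalg.norm(corner - [1.0, 0.0]) < 3 * sigma
        rms = math.sqrt(np.mean(polyline_distances(pts, fit.vertices) ** 2))
        assert rms <= 2 * sigma

    def test_distance_matches_dense_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            vertices = rng.normal(0, 1, (4, 2))
            pts = rng.normal(0, 2, (50, 2))
            fast = polyline_distances(pts, vertices)
            slow = dense_polyline_distance_oracle(pts, vertices)
            assert np.all(np.abs(fast - slow) < 1e-6 * (1 + slow))

    def test_objective_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(6)
        pts = make_straight_cloud(rng, n=50)
        fit = fit_polyline(pts, k=1, penalty=0.01, seed=0)
        angle = 0.7
        rot = np.array(
            [[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]]
        )
        fit2 = fit_polyline(pts @ rot.T + [3.0, -1.0], k=1, penalty=0.01, seed=0)
        assert fit2.objective == pytest.approx(fit.objective, rel=1e-2)

    def test_penalty_monotonically_shrinks_length(self):
        rng = np.random.default_rng(8)
        pts = make_straight_cloud(rng, n=60, sigma=0.03)
        lengths = [
            fit_polyline(pts, k=2, penalty=lam, seed=0).total_length
            for lam in (0.0, 0.01, 0.05, 0.2)
        ]
        for a, b in zip(lengths, lengths[1:]):
            assert b <= a * 1.02  # small optimizer slack


class TestSegmentCountSelection:
    def test_straight_cloud_selects_one_segment(self):
        picks = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            cv = PolylineSegmentCV(k_min=1, k_max=3, n_repeats=2, random_state=seed).fit(
                make_straight_cloud(rng)
            )
            picks.append(cv.best_k_)
        assert picks.count(1) >= 9

    def test_l_cloud_selects_two_segments(self):
        picks = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            cv = PolylineSegmentCV(k_min=1, k_max=3, n_repeats=2, random_state=seed).fit(
                make_l_cloud(rng)
            )
            picks.append(cv.best_k_)
        assert picks.count(2) > 5

    def test_training_error_non_increasing_in_k(self):
        # nested-model sanity: training MSE cannot grow with k (small
        # multi-start slack)
        rng = np.random.default_rng(9)
        pts = make_l_cloud(rng, n=80)
        mses = [
            EqualLengthPolyline(n_segments=k, penalty=0.0, random_state=0).fit(pts).mse_
            for k in (1, 2, 3)
        ]
        for a, b in zip(mses, mses[1:]):
            assert b <= a * 1.05

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            PolylineSegmentCV().fit(np.zeros((5, 2)))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(11)
        pts = make_straight_cloud(rng)
        a = PolylineSegmentCV(k_max=3, n_repeats=2, random_state=5).fit(pts)
        b = PolylineSegmentCV(k_max=3, n_repeats=2, random_state=5).fit(pts)
        assert a.best_k_ == b.best_k_
        assert np.array_equal(a.vertices_, b.vertices_)


class TestExtractSegments:
    def test_horizontal_single_segment(self):
        pts = np.column_stack([np.linspace(0, 1, 20), np.zeros(20)])
        fit = fit_polyline(pts, k=1, penalty=0.0, seed=0)
        segs = extract_segments(fit)
        assert segs.n == 1
        theta = segs.orientations[0]
        assert min(theta, np.pi - theta) < 0.02
        assert segs.lengths[0] == pytest.approx(fit.segment_length)

    def test_right_angle_orientations_orthogonal(self):
        rng = np.random.default_rng(12)
        fit = fit_polyline(make_l_cloud(rng, sigma=0.01), k=2, seed=2)
        segs = extract_segments(fit)
        d = abs(segs.orientations[0] - segs.orientations[1])
        assert min(d, np.pi - d) == pytest.approx(np.pi / 2, abs=0.1)

    def test_total_length_conserved(self):
        rng = np.random.default_rng(13)
        fit = fit_polyline(make_l_cloud(rng), k=3, seed=4)
        segs = extract_segments(fit)
        assert segs.total_length() == pytest.approx(fit.total_length)
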