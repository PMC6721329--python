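"""Spine-curve reconstruction geometry and offset shapes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinechange.spine import arc_chord, offset_shape, reconstruct_curve

from conftest import make_pair


def integrate_chord(tau0, tau1, length, n_steps=200_001):
    """Numeric-integration oracle: chord of the arc whose tangent angle varies
    linearly in arc length, integrated with Simpson's rule."""
    s = np.linspace(0.0, length, n_steps)
    theta = tau0 + (tau1 - tau0) * s / length
    from scipy.integrate import simpson

    return np.array([simpson(np.sin(theta), x=s), simpson(np.cos(theta), x=s)])


angles5 = st.lists(
    st.floats(min_value=-179.0, max_value=179.0, allow_nan=False), min_size=5, max_size=5
)


class TestReconstructCurve:
    def test_vertical_line_at_zero_angles(self):
        curve = reconstruct_curve([0, 0, 0, 0, 0], 1.0)
        expected = np.array([[0, -1], [0, 0], [0, 1], [0, 2], [0, 3], [0, 4]], float)
        np.testing.assert_allclose(curve.points, expected, atol=1e-15)

    @pytest.mark.parametrize("c", [10.0, -25.0, 89.0])
    def test_constant_angle_gives_straight_line(self, c):
        curve = reconstruct_curve([c] * 5, 1.0)
        step = np.array([math.sin(math.radians(c)), math.cos(math.radians(c))])
        for i in range(5):
            np.testing.assert_allclose(curve.points[i + 1] - curve.points[i], step, atol=1e-12)

    def test_quarter_turn_chord(self):
        # tangent from vertical to horizontal over unit arc length:
        # chord = (2/pi, 2/pi), frozen from the integral oracle
        curve = reconstruct_curve([0, 90, 0, 0, 0], 1.0)
        np.testing.assert_allclose(
            curve.points[2] - curve.points[1],
            [0.6366197723675814, 0.6366197723675814],
            atol=1e-12,
        )

    def test_pinned_frame_and_point_count(self):
        curve = reconstruct_curve([19.6, 10.1, -4.1, -12.3, -12.0], 1.0)
        assert curve.points.shape == (6, 2)
        np.testing.assert_array_equal(curve.points[1], [0.0, 0.0])

    def test_arc_endpoints_match_integration_oracle(self, rng):
        taus = rng.uniform(-np.pi, np.pi, size=(40, 2))
        taus = taus[np.abs(taus[:, 1] - taus[:, 0]) <= np.pi]
        for tau0, tau1 in taus:
            chord = arc_chord(tau0, tau1, 1.0)
            np.testing.assert_allclose(chord, integrate_chord(tau0, tau1, 1.0), atol=1e-8)

    @settings(derandomize=True, max_examples=50)
    @given(angles5)
    def test_mirror_symmetry(self, angles):
        plus = reconstruct_curve(angles, 1.0).points
        minus = reconstruct_curve([-a for a in angles], 1.0).points
        np.testing.assert_allclose(minus[:, 0], -plus[:, 0], atol=1e-12)
        np.testing.assert_allclose(minus[:, 1], plus[:, 1], atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(angles5)
    def test_polyline_length_bounded_by_arc_length(self, angles):
        pts = reconstruct_curve(angles, 1.0).points
        chord_sum = np.linalg.norm(np.diff(pts[1:], axis=0), axis=1).sum()
        assert chord_sum <= 4.0 + 1e-12
        if len(set(angles)) == 1:
            assert chord_sum == pytest.approx(4.0, abs=1e-12)

    def test_continuity_through_straight_limit(self):
        base = reconstruct_curve([30, 30, 30, 30, 30], 1.0).points
        eps = math.degrees(1e-9)
        near = reconstruct_curve([30, 30 + eps, 30, 30, 30], 1.0).points
        assert np.abs(near - base).max() < 1e-8

    @pytest.mark.parametrize(
        "angles, length",
        [([0, 0, 0, 0, float("nan")], 1.0), ([0] * 5, 0.0), ([0] * 5, -2.0), ([0] * 4, 1.0)],
    )
    def test_domain_errors(self, angles, length):
        with pytest.raises(ValueError):
            reconstruct_curve(angles, length)

    def test_scale_covariance(self):
        a = [19.6, 10.1, -4.1, -12.3, -12.0]
        np.testing.assert_allclose(
            reconstruct_curve(a, 2.5).points, 2.5 * reconstruct_curve(a, 1.0).points
        )


class TestOffsetShape:
    def test_identity_pair_is_vertical_all_zero_signs(self):
        a = (19.6, 10.1, -4.1, -12.3, -12.0)
        shape = offset_shape(make_pair(a, a))
        assert shape.signs == ("o",) * 6
        np.testing.assert_allclose(shape.points[:, 0], 0.0, atol=1e-15)

    def test_constant_positive_delta_signs(self):
        # constant delta c > 0: straight line leaning anteriorly; the basal
        # extension points the opposite way, P1 is pinned at zero
        shape = offset_shape(make_pair((0,) * 5, (5.0,) * 5))
        assert shape.signs == ("-", "o", "+", "+", "+", "+")

    def test_swapping_snapshots_mirrors_the_shape(self):
        t0 = (19.6, 10.1, -4.1, -12.3, -12.0)
        t1 = (22.5, 13.8, -0.1, -8.2, -7.6)
        fwd = offset_shape(make_pair(t0, t1))
        rev = offset_shape(make_pair(t1, t0))
        np.testing.assert_allclose(rev.points[:, 0], -fwd.points[:, 0], atol=1e-12)
        np.testing.assert_allclose(rev.points[:, 1], fwd.points[:, 1], atol=1e-12)
        flip = {"+": "-", "-": "+", "o": "o"}
        assert rev.signs == tuple(flip[s] for s in fwd.signs)

    def test_points_ordered_by_increasing_y_for_moderate_deltas(self, rng):
        for _ in range(20):
            t0 = rng.uniform(-30, 30, 5)
            t1 = t0 + rng.uniform(-20, 20, 5)
            shape = offset_shape(make_pair(tuple(t0), tuple(t1)))
            assert np.all(np.diff(shape.points[:, 1]) > 0)
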