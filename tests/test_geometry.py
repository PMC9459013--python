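"""Stenosis parameterization: constraint solve, sampling, rasters, markers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stenoflow.geometry import (
    AsymmetricShape3D,
    DegenerateParameterError,
    RejectedSampleError,
    StenosisShape,
    evaluate_profile,
    markers_channel_2d,
    markers_tube_3d,
    radius_asymmetric,
    radius_axisymmetric,
    rasterize_2d,
    rasterize_3d,
    sample_stenosis,
    sample_surface_points,
    solve_stenosis_polynomial,
)


def brute_force_coefficients(D, h, x_star):
    """Independent 6x6 solve written against the raw Vandermonde system."""
    import itertools

    A = []
    b = []
    for x, val, deriv in [
        (0.0, D, False),
        (D, D, False),
        (0.0, 0.0, True),
        (D, 0.0, True),
        (x_star, D - h, False),
        (x_star, 0.0, True),
    ]:
        if deriv:
            A.append([(5 - k) * x ** (4 - k) if k < 5 else 0.0 for k in range(6)])
        else:
            A.append([x ** (5 - k) for k in range(6)])
        b.append(val)
    return np.linalg.solve(np.array(A), np.array(b))


class TestPolynomialSolve:
    def test_matches_independent_linear_solve(self):
        sh = solve_stenosis_polynomial(1.0, 0.5, 0.5)
        expect = brute_force_coefficients(1.0, 0.5, 0.5)
        assert np.allclose(sh.coefficients, expect, atol=1e-12)
        assert abs(evaluate_profile(sh, 0.5) - 0.5) < 1e-12

    @pytest.mark.parametrize("h,xs", [(0.3, 0.4), (0.5, 0.5), (0.7, 0.6), (0.45, 0.42)])
    def test_constraint_residuals_tiny(self, h, xs):
        sh = solve_stenosis_polynomial(1.0, h, xs)
        assert np.abs(sh.constraint_residuals()).max() < 1e-10

    def test_depth_and_throat_roundtrip(self):
        sh = solve_stenosis_polynomial(1.0, 0.42, 0.57)
        assert abs(sh.depth - 0.42) < 1e-8
        assert abs(sh.throat - 0.57) < 1e-8

    def test_near_zero_depth_approaches_flat(self):
        sh = solve_stenosis_polynomial(1.0, 1e-9, 0.5)
        xs = np.linspace(0, 1, 50)
        assert np.allclose(evaluate_profile(sh, xs), 1.0, atol=1e-8)

    def test_degenerate_throat_rejected(self):
        with pytest.raises(DegenerateParameterError):
            solve_stenosis_polynomial(1.0, 0.5, 0.0)
        with pytest.raises(DegenerateParameterError):
            solve_stenosis_polynomial(1.0, 0.5, 1.0)

    def test_off_centre_throat_rejected(self):
        # the clamped quintic overshoots D when the throat is pushed to
        # the edges of the extent; such samples are rejected
        with pytest.raises((RejectedSampleError, DegenerateParameterError)):
            solve_stenosis_polynomial(1.0, 0.45, 0.35)


class TestSampling:
    def test_seed_determinism(self):
        a = sample_stenosis(0, h_range=(0.3, 0.7), x_star_range=(0.3, 0.7))
        b = sample_stenosis(0, h_range=(0.3, 0.7), x_star_range=(0.3, 0.7))
        assert np.array_equal(a.coefficients, b.coefficients)

    def test_range_membership(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            sh = sample_stenosis(rng, h_range=(0.3, 0.7), x_star_range=(0.35, 0.65))
            assert 0.3 - 1e-8 <= sh.depth <= 0.7 + 1e-8
            assert 0.35 - 1e-6 <= sh.throat <= 0.65 + 1e-6

    def test_uniform_depth_mean(self):
        # Monte-Carlo: mean depth within 3 standard errors of the range centre
        rng = np.random.default_rng(2)
        hs = [sample_stenosis(rng, h_range=(0.2, 0.8)).depth for _ in range(1000)]
        se = np.std(hs) / np.sqrt(len(hs))
        assert abs(np.mean(hs) - 0.5) < 3 * se

    def test_infeasible_range_raises(self):
        with pytest.raises(RejectedSampleError):
            sample_stenosis(0, h_range=(0.95, 0.999), x_star_range=(0.01, 0.02), max_tries=50)


class TestProfileEvaluation:
    def test_flat_everywhere(self, flat_shape):
        assert evaluate_profile(flat_shape, 0.37) == 1.0
        assert np.all(evaluate_profile(flat_shape, np.linspace(-1, 2, 20)) == 1.0)

    def test_outside_extent_returns_D(self, half_depth_shape):
        assert evaluate_profile(half_depth_shape, -0.5) == 1.0
        assert evaluate_profile(half_depth_shape, 1.5) == 1.0

    def test_continuity_at_joins(self, half_depth_shape):
        eps = 1e-9
        assert abs(evaluate_profile(half_depth_shape, -eps) - evaluate_profile(half_depth_shape, 0.0)) < 1e-8
        assert abs(evaluate_profile(half_depth_shape, 1.0 + eps) - evaluate_profile(half_depth_shape, 1.0)) < 1e-8

    def test_axisymmetric_radius_is_half_gap(self, half_depth_shape, flat_shape):
        assert radius_axisymmetric(flat_shape, 0.3) == 0.5
        assert abs(radius_axisymmetric(half_depth_shape, half_depth_shape.throat) - 0.25) < 1e-8
        # throat cross-section area ratio (0.5 D gap -> 1/4 of healthy area)
        a_ratio = (radius_axisymmetric(half_depth_shape, 0.5) / 0.5) ** 2
        assert abs(a_ratio - 0.25) < 1e-8


class TestAsymmetricRadius:
    def test_zero_amplitude_no_invasion(self, half_depth_shape):
        sh3 = AsymmetricShape3D(axial_profile=half_depth_shape, amplitude=0.0)
        th = np.linspace(0, 2 * np.pi, 17)
        assert np.allclose(radius_asymmetric(sh3, 0.5, th), 0.5)

    def test_opposite_side_untouched_for_small_sigma(self, half_depth_shape):
        sh3 = AsymmetricShape3D(axial_profile=half_depth_shape, theta0=0.0, sigma=0.3, amplitude=1.0)
        assert abs(radius_asymmetric(sh3, 0.5, np.pi) - 0.5) < 1e-6

    def test_peak_matches_axisymmetric(self, half_depth_shape):
        sh3 = AsymmetricShape3D(axial_profile=half_depth_shape, theta0=1.0, sigma=0.8, amplitude=1.0)
        for x in (0.2, 0.5, 0.8):
            assert abs(radius_asymmetric(sh3, x, 1.0) - radius_axisymmetric(half_depth_shape, x)) < 1e-10

    def test_axisymmetric_limit_wide_sigma(self, half_depth_shape):
        sh3 = AsymmetricShape3D(axial_profile=half_depth_shape, sigma=200.0, amplitude=1.0)
        th = np.linspace(0, 2 * np.pi, 33)
        r = radius_asymmetric(sh3, 0.4, th)
        assert np.abs(r - radius_axisymmetric(half_depth_shape, 0.4)).max() < 1e-6

    def test_periodicity(self, half_depth_shape):
        sh3 = AsymmetricShape3D(axial_profile=half_depth_shape, theta0=0.7, sigma=0.5, amplitude=0.8)
        th = np.linspace(0, 2 * np.pi, 11)
        assert np.allclose(
            radius_asymmetric(sh3, 0.5, th), radius_asymmetric(sh3, 0.5, th + 2 * np.pi), atol=1e-10
        )


class TestRaster2D:
    def test_flat_fills_single_top_row(self, flat_shape):
        img = rasterize_2d(flat_shape)
        assert img.values.shape == (214, 214)
        filled_rows = np.unique(np.nonzero(img.values)[1])
        assert list(filled_rows) == [213]

    def test_supercover_spans_all_columns(self, half_depth_shape):
        img = rasterize_2d(half_depth_shape)
        cols = np.unique(np.nonzero(img.values)[0])
        assert len(cols) == 214
        assert img.values.sum() >= 214

    def test_throat_row_matches_dense_sampling(self, half_depth_shape):
        img = rasterize_2d(half_depth_shape)
        min_row = np.nonzero(img.values)[1].min()
        # oracle: dense curve sampling
        xs = np.linspace(0, 1, 20001)
        y_min = evaluate_profile(half_depth_shape, xs).min()
        expect = int(y_min / img.pixel_spacing)
        assert abs(min_row - expect) <= 1

    def test_scale_consistency_under_pooling(self, half_depth_shape):
        fine = rasterize_2d(half_depth_shape, resolution=428).values
        coarse = rasterize_2d(half_depth_shape, resolution=214).values
        pooled = fine.reshape(214, 2, 214, 2).max(axis=(1, 3))
        assert np.array_equal(pooled, coarse)


class TestRaster3D:
    @pytest.fixture(scope="class")
    def shell(self, half_depth_shape):
        sh3 = AsymmetricShape3D(axial_profile=half_depth_shape, sigma=0.8, amplitude=0.9, theta0=0.5)
        return rasterize_3d(sh3)

    def test_resolution_and_spacing(self, shell):
        assert shell.values.shape == (61, 61, 61)
        assert abs(shell.pixel_spacing - 1.2 / 60) < 1e-12

    def test_flat_tube_is_cylinder_shell(self, flat_shape):
        sh3 = AsymmetricShape3D(axial_profile=flat_shape, amplitude=0.0)
        vol = rasterize_3d(sh3).values
        dp = 1.2 / 60
        c = 0.6
        # every filled voxel center lies within a voxel diagonal of r = 0.5
        idx = np.argwhere(vol)
        r = np.sqrt((idx[:, 1] * dp - c) ** 2 + (idx[:, 2] * dp - c) ** 2)
        assert np.abs(r - 0.5).max() < dp * 1.0
        # and every axial slice has a filled ring
        assert (vol.sum(axis=(1, 2)) > 0).all()

    def test_axisymmetric_slices_rotationally_symmetric(self, half_depth_shape):
        from scipy import ndimage

        sh3 = AsymmetricShape3D(axial_profile=half_depth_shape, sigma=100.0, amplitude=1.0)
        vol = rasterize_3d(sh3).values
        mid = vol[30].astype(bool)
        grown = ndimage.binary_dilation(mid, np.ones((3, 3)))
        for other in (mid[::-1, :], mid[:, ::-1], mid.T):
            # symmetric counterpart within one voxel
            assert (grown | ~other).all()

    def test_shell_connected(self, shell):
        from scipy import ndimage

        lab, n = ndimage.label(shell.values, structure=np.ones((3, 3, 3)))
        assert n == 1


class TestSurfacePoints:
    def test_flat_2d_all_D(self, flat_shape):
        pts = sample_surface_points(flat_shape, 201)
        assert pts.shape == (201,)
        assert np.allclose(pts, 1.0)

    def test_2d_endpoints_clamped(self, half_depth_shape):
        pts = sample_surface_points(half_depth_shape, 201)
        assert abs(pts[0] - 1.0) < 1e-10 and abs(pts[-1] - 1.0) < 1e-10
        assert abs(pts.min() - 0.5) < 1e-6

    def test_3d_axisymmetric_rings_equal_radius(self, half_depth_shape):
        sh3 = AsymmetricShape3D(axial_profile=half_depth_shape, sigma=100.0, amplitude=1.0)
        pts = sample_surface_points(sh3, 400)
        assert pts.shape == (400, 2)
        r = pts[:, 0].reshape(20, 20)
        assert np.abs(r - r[:, :1]).max() < 1e-6


class TestMarkers:
    def test_channel_markers_on_surface_and_spacing(self, half_depth_shape):
        mk = markers_channel_2d(half_depth_shape, 0.04, 0.0, 1.0, y_bottom=0.2)
        assert abs(mk.spacing - 0.02) < 1e-12
        # every marker on one of the analytic wall curves
        x = mk.positions[:, 0]
        y = mk.positions[:, 1]
        yb = 0.2 + (1.0 - evaluate_profile(half_depth_shape, x))
        dist = np.minimum(np.abs(y - yb), np.abs(y - 1.2))
        assert dist.max() < 1e-8

    def test_straight_wall_marker_count(self, flat_shape):
        mk = markers_channel_2d(flat_shape, 0.1, 0.0, 2.0, y_bottom=0.0)
        per_wall = len(mk) // 2
        assert abs(per_wall - round(2.0 / 0.05)) <= 1

    def test_max_gap_below_three_quarters_spacing(self, half_depth_shape):
        mk = markers_channel_2d(half_depth_shape, 0.04, 0.0, 1.0, y_bottom=0.2)
        top = np.abs(mk.positions[:, 1] - 1.2) < 1e-9
        for wall in (mk.positions[~top], mk.positions[top]):
            gaps = np.linalg.norm(np.diff(wall, axis=0), axis=1)
            assert gaps.max() < 0.75 * 0.04

    def test_tube_markers_on_surface(self, half_depth_shape):
        sh3 = AsymmetricShape3D(axial_profile=half_depth_shape, sigma=0.7, amplitude=0.8)
        mk = markers_tube_3d(sh3, 0.08, 0.0, 1.0, 0.0, 0.0)
        x = mk.positions[:, 0]
        r = np.linalg.norm(mk.positions[:, 1:], axis=1)
        th = np.arctan2(mk.positions[:, 2], mk.positions[:, 1])
        r_wall = np.array([radius_asymmetric(sh3, xi, ti) for xi, ti in zip(x, th)])
        assert np.abs(r - r_wall).max() < 1e-8


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    h=st.floats(0.2, 0.75),
    xs=st.floats(0.4, 0.6),
)
def test_property_solve_extract_identity(h, xs):
    """Solving then re-measuring (depth, throat) is the identity map."""
    try:
        sh = solve_stenosis_polynomial(1.0, h, xs)
    except (RejectedSampleError, DegenerateParameterError):
        return
    assert abs(sh.depth - h) < 1e-8
    assert abs(sh.throat - xs) < 1e-6
    assert np.abs(sh.constraint_residuals()).max() < 1e-10
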