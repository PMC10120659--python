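"""Affine fitting, velocity-field integration, and map application."""

import numpy as np
import pytest

from stwarp.geometry import (
    AffineTransform,
    DiffeoMap,
    LandmarkSet,
    VelocityField,
    apply_map_to_points,
    fit_affine_landmarks,
    flow_points,
    integrate_velocity,
    jacobian_determinant,
    resample_image,
)
from stwarp.raster import PointSet, RasterImage, rasterize


def _axes(shape, dx, origin=0.0):
    return [origin + dx * (np.arange(n) + 0.5) for n in shape]


def _smooth_field(axes, nt=3, amplitude=30.0, scale=400.0, a=500.0):
    yy, xx = np.meshgrid(*axes, indexing="ij")
    cy, cx = yy.mean(), xx.mean()
    bump = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * scale**2))
    v = np.stack([amplitude * bump, -0.6 * amplitude * bump])
    return VelocityField(np.repeat(v[None], nt, axis=0), axes, a=a)


class TestFitAffineLandmarks:
    def test_identity_from_identical_pairs(self):
        pts = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
        A, res = fit_affine_landmarks(LandmarkSet(pts, pts))
        np.testing.assert_allclose(A.matrix, np.eye(3), atol=1e-10)
        assert res == pytest.approx(0.0, abs=1e-16)

    def test_recovers_generating_rotation_translation(self):
        rng = np.random.default_rng(7)
        src = rng.uniform(0, 1000, size=(6, 2))
        th = np.deg2rad(30)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        t = np.array([100.0, -50.0])
        tgt = src @ R.T + t
        A, _ = fit_affine_landmarks(LandmarkSet(src, tgt))
        np.testing.assert_allclose(A.linear, R, atol=1e-8)
        np.testing.assert_allclose(A.translation, t, atol=1e-8)

    def test_noisy_fit_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        src = np.array([[0.0, 0.0], [500.0, 20.0], [30.0, 700.0], [400.0, 500.0]])
        tgt = src + rng.normal(0, 15, src.shape)
        A, res = fit_affine_landmarks(LandmarkSet(src, tgt))
        # independent normal-equations oracle
        X = np.hstack([src, np.ones((4, 1))])
        beta = np.linalg.solve(X.T @ X, X.T @ tgt)
        pred = X @ beta
        np.testing.assert_allclose(A.apply(src), pred, atol=1e-8)
        assert res == pytest.approx(np.sum((pred - tgt) ** 2), rel=1e-10)

    def test_degenerate_configuration_raises(self):
        src = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])  # collinear
        with pytest.raises(ValueError, match="landmark"):
            fit_affine_landmarks(LandmarkSet(src, src))


class TestIntegrateVelocity:
    def test_zero_field_gives_identity(self):
        axes = _axes((8, 9), 50.0)
        v = VelocityField.zeros(axes)
        phi = integrate_velocity(v)
        grid = np.stack(np.meshgrid(*axes, indexing="ij"))
        np.testing.assert_array_equal(phi.positions, grid)

    @pytest.mark.parametrize("nt", [1, 3, 10])
    def test_constant_field_translates_exactly(self, nt):
        axes = _axes((8, 9), 50.0)
        samples = np.zeros((nt, 2, 8, 9))
        samples[:, 0] = 17.0
        v = VelocityField(samples, axes)
        phi = integrate_velocity(v, "forward")
        grid = np.stack(np.meshgrid(*axes, indexing="ij"))
        np.testing.assert_allclose(phi.positions[0], grid[0] + 17.0, atol=1e-10)
        np.testing.assert_allclose(phi.positions[1], grid[1], atol=1e-10)

    def test_euler_convergence_order(self):
        """Coarse (nt=3) integration error is bounded by the O(1/nt) law
        fitted from a fine-step reference."""
        axes = _axes((20, 22), 50.0)
        pts = np.stack(np.meshgrid(*axes, indexing="ij")).reshape(2, -1).T[::7]

        def mapped(nt):
            base = _smooth_field(axes, nt=1)
            samples = np.repeat(base.samples, nt, axis=0)
            return flow_points(VelocityField(samples, axes), pts)

        ref = mapped(300)
        errs = {nt: np.abs(mapped(nt) - ref).max() for nt in (3, 10, 30)}
        c = errs[30] * 30  # calibrate the O(1/nt) constant from the finest
        assert errs[3] <= 2.5 * c / 3
        assert errs[10] <= 2.5 * c / 10

    def test_forward_backward_roundtrip_within_one_pixel(self):
        axes = _axes((20, 22), 50.0)
        v = _smooth_field(axes, nt=3, amplitude=40.0)
        pts = np.stack(np.meshgrid(*axes, indexing="ij")).reshape(2, -1).T[::5]
        fwd = flow_points(v, pts, "forward")
        back = flow_points(v, fwd, "backward")
        assert np.abs(back - pts).max() < 50.0


class TestApplyMap:
    def test_identity_is_bitwise(self, small_cloud):
        axes = _axes((8, 8), 300.0)
        phi = integrate_velocity(VelocityField.zeros(axes))
        out = apply_map_to_points(AffineTransform.identity(2), phi, small_cloud)
        np.testing.assert_array_equal(out.coords, small_cloud.coords)
        np.testing.assert_array_equal(out.features, small_cloud.features)
        np.testing.assert_array_equal(out.labels, small_cloud.labels)

    def test_pure_affine_matches_matrix_multiply(self, small_cloud):
        A = AffineTransform.from_linear_translation(
            [[1.1, 0.2], [-0.1, 0.95]], [40.0, -30.0]
        )
        out = apply_map_to_points(A, None, small_cloud)
        want = small_cloud.coords @ A.linear.T + A.translation
        np.testing.assert_allclose(out.coords, want, atol=1e-12)

    def test_push_pull_inverse_consistency(self, small_cloud):
        axes = _axes((50, 50), 50.0)
        v = _smooth_field(axes, amplitude=30.0)
        fwd = integrate_velocity(v, "forward")
        back = integrate_velocity(v, "backward")
        pushed = apply_map_to_points(None, fwd, small_cloud)
        pulled = apply_map_to_points(None, back, pushed)
        disp = np.linalg.norm(pulled.coords - small_cloud.coords, axis=1)
        assert disp.max() < 50.0  # one velocity-grid pixel

    def test_dimension_mismatch_raises(self, small_cloud):
        with pytest.raises(ValueError):
            apply_map_to_points(AffineTransform.identity(3), None, small_cloud)

    def test_out_of_grid_flagging(self, small_cloud):
        axes = _axes((4, 4), 100.0)  # covers only a corner of the cloud
        phi = integrate_velocity(VelocityField.zeros(axes))
        _, flags = apply_map_to_points(None, phi, small_cloud, return_flags=True)
        lo = np.array([axes[0][0], axes[1][0]])
        hi = np.array([axes[0][-1], axes[1][-1]])
        want = np.all((small_cloud.coords >= lo) & (small_cloud.coords <= hi), axis=1)
        np.testing.assert_array_equal(flags, want)


class TestResampleImage:
    def test_identity_is_exact(self, smooth_image):
        out = resample_image(smooth_image, None, None, smooth_image.axis_coords)
        np.testing.assert_allclose(out.values, smooth_image.values, atol=1e-12)

    def test_integer_pixel_translation_shifts_array(self, smooth_image):
        dx = smooth_image.dx[1]
        A = AffineTransform.from_linear_translation(np.eye(2), [0.0, 3 * dx])
        out = resample_image(smooth_image, A, None, smooth_image.axis_coords, fill=0.0)
        np.testing.assert_allclose(
            out.values[0, :, 3:], smooth_image.values[0, :, :-3], atol=1e-9
        )

    def test_deform_roundtrip_error_bounded(self, smooth_image):
        axes = smooth_image.axis_coords
        v = _smooth_field(axes, amplitude=20.0, scale=300.0)
        fwd = integrate_velocity(v, "forward")
        back = integrate_velocity(v, "backward")
        warped = resample_image(smooth_image, None, back, axes)
        restored = resample_image(warped, None, fwd, axes)
        # interior comparison; bound relative to the linear-interp error of
        # shifting the image by the same displacement magnitude
        inner = (slice(None), slice(3, -3), slice(3, -3))
        err = np.abs(restored.values - smooth_image.values)[inner].max()
        assert err < 0.05 * smooth_image.values.max()

    def test_singular_affine_rejected(self, smooth_image):
        with pytest.raises(ValueError):
            AffineTransform.from_linear_translation([[1.0, 0.0], [1.0, 0.0]], [0, 0])


class TestJacobianDeterminant:
    def test_identity_map(self):
        axes = _axes((6, 7), 50.0)
        phi = integrate_velocity(VelocityField.zeros(axes))
        np.testing.assert_allclose(jacobian_determinant(phi), 1.0, atol=1e-12)

    def test_uniform_scale(self):
        axes = _axes((6, 7), 50.0)
        grid = np.stack(np.meshgrid(*axes, indexing="ij"))
        phi = DiffeoMap(1.3 * grid, axes)
        np.testing.assert_allclose(jacobian_determinant(phi), 1.3**2, atol=1e-10)

    def test_positive_for_integrated_smooth_fields(self):
        axes = _axes((20, 22), 50.0)
        v = _smooth_field(axes, amplitude=45.0)
        for direction in ("forward", "backward"):
            phi = integrate_velocity(v, direction)
            assert jacobian_determinant(phi).min() > 0


def test_raster_transform_commutation(rng):
    """rasterize(move points) ≈ resample(rasterize(points)) within 5%."""
    coords = rng.normal([1500, 1500], 400, size=(20000, 2))
    pts = PointSet(coords)
    A = AffineTransform.from_linear_translation(np.eye(2), [200.0, -150.0])
    moved = apply_map_to_points(A, None, pts)
    img_moved = rasterize(moved, dx=100.0, blur_std=2.0)
    img = rasterize(pts, dx=100.0, blur_std=2.0)
    warped = resample_image(img, A, None, img_moved.axis_coords, fill=0.0)
    err = np.abs(warped.values - img_moved.values).max() / img_moved.values.max()
    assert err < 0.05
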