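"""Landmark interpolants, warping, intensity edits, field inversion."""

import numpy as np
import pytest
from conftest import (
    interior,
    random_landmarks,
    smooth_random_field_array,
    tps_dense_solve,
    tps_point_eval,
    trilinear_point,
    wendland_point_sum,
)

from dirqa import (
    AnalyticFieldSpec,
    BinaryMask,
    GridMismatchError,
    ImageGrid,
    LandmarkSet,
    ScalarVolume,
    VectorField,
    add_default_anchors,
    add_fields,
    analytic_field,
    edit_intensity,
    evaluate_field,
    fit_csrbf,
    fit_tps,
    invert_field,
    rmse,
    warp_image,
    warp_mask,
)
from dirqa.deform import SingularSystemError


class TestDefaultAnchors:
    def test_empty_set_gets_eight_corner_anchors(self, small_grid):
        lm = add_default_anchors(None, small_grid)
        assert len(lm) == 8
        assert lm.anchor_flags.all()
        np.testing.assert_allclose(
            np.sort(lm.source_points, axis=0),
            np.sort(small_grid.corner_points(), axis=0),
        )

    def test_idempotent(self, small_grid, rng):
        lm = random_landmarks(rng, 5)
        once = add_default_anchors(lm, small_grid)
        twice = add_default_anchors(once, small_grid)
        assert len(once) == len(twice) == 13

    def test_anchors_pin_displacement_to_zero_after_fitting(self, small_grid, rng):
        lm = add_default_anchors(random_landmarks(rng, 6, 5, 20), small_grid)
        model = fit_tps(lm)
        at_corners = model.displacement(small_grid.corner_points())
        assert np.abs(at_corners).max() < 1e-6


class TestTPS:
    def test_identity_landmarks_give_zero_model(self, rng):
        sp = rng.uniform(0, 50, (8, 3))
        lm = LandmarkSet(sp, sp.copy(), np.zeros(8, bool))
        model = fit_tps(lm)
        assert np.abs(model.nonaffine_weights).max() < 1e-8
        pts = rng.uniform(-10, 60, (50, 3))
        assert np.abs(model.displacement(pts)).max() < 1e-8

    def test_pure_translation_reproduced_exactly_off_landmarks(self, rng):
        t = np.array([5.0, -3.0, 2.0])
        sp = rng.uniform(0, 64, (9, 3))
        lm = LandmarkSet(sp, sp + t, np.zeros(9, bool))
        model = fit_tps(lm)
        pts = rng.uniform(-20, 84, (100, 3))
        assert np.abs(model.displacement(pts) - t).max() < 1e-6

    def test_general_affine_data_leave_zero_bending_weights(self, rng):
        a = np.eye(3) + rng.normal(0, 0.05, (3, 3))
        b = rng.normal(0, 5, 3)
        sp = rng.uniform(0, 64, (10, 3))
        lm = LandmarkSet(sp, sp @ a.T + b, np.zeros(10, bool))
        model = fit_tps(lm)
        assert np.abs(model.nonaffine_weights).max() < 1e-8
        pts = rng.uniform(0, 64, (100, 3))
        expected = pts @ a.T + b - pts
        assert np.abs(model.displacement(pts) - expected).max() < 1e-6

    def test_interpolation_and_agreement_with_dense_double_loop_solve(self, rng):
        lm = random_landmarks(rng, 10, 0, 64)
        model = fit_tps(lm)
        residual = model.displacement(lm.source_points) - lm.displacements
        assert np.abs(residual).max() < 1e-6
        weights, affine = tps_dense_solve(lm)
        for x in rng.uniform(0, 64, (20, 3)):
            expected = tps_point_eval(weights, affine, lm.source_points, x)
            assert np.allclose(model.displacement(x)[0], expected, atol=1e-8)

    def test_side_conditions_hold(self, rng):
        lm = random_landmarks(rng, 12, 0, 64)
        model = fit_tps(lm)
        w, c = model.nonaffine_weights, model.control_points
        scale = np.abs(w).sum() + 1e-30
        assert np.abs(w.sum(axis=0)).max() / scale < 1e-8
        assert np.abs(np.einsum("ni,nj->ij", w, c)).max() / (scale * 64) < 1e-8

    def test_coplanar_landmarks_raise_singular_error(self):
        sp = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [10, 10, 0], [5, 5, 0]], float)
        lm = LandmarkSet(sp, sp + [1, 0, 0], np.zeros(5, bool))
        with pytest.raises(SingularSystemError, match="regulari"):
            fit_tps(lm)

    def test_too_few_landmarks_raise(self, rng):
        lm = random_landmarks(rng, 3)
        with pytest.raises(SingularSystemError):
            fit_tps(lm)


class TestCSRBF:
    def test_single_landmark_compact_support(self):
        d = np.array([2.0, -1.0, 3.0])
        lm = LandmarkSet([[30, 30, 30]], [32, 29, 33], [False])
        model = fit_csrbf(lm, support_radius=20.0)
        assert np.allclose(model.displacement([[30, 30, 30]])[0], d, atol=1e-9)
        far = np.array([[30 + 20, 30, 30], [30, 30 - 25, 30], [0, 0, 0]])
        assert np.abs(model.displacement(far)).max() == 0.0

    def test_identity_landmarks_give_zero_field(self, rng):
        sp = rng.uniform(0, 40, (6, 3))
        lm = LandmarkSet(sp, sp.copy(), np.zeros(6, bool))
        model = fit_csrbf(lm, 25.0)
        assert np.abs(model.weights).max() < 1e-12

    def test_interpolation_and_double_loop_kernel_sum_agreement(self, rng):
        lm = random_landmarks(rng, 5, 10, 50)
        model = fit_csrbf(lm, support_radius=30.0)
        residual = model.displacement(lm.source_points) - lm.displacements
        assert np.abs(residual).max() < 1e-6
        for x in rng.uniform(0, 60, (50, 3)):
            expected = wendland_point_sum(
                model.weights, model.control_points, 30.0, x
            )
            assert np.allclose(model.displacement(x)[0], expected, atol=1e-9)

    def test_compact_support_beyond_radius_of_all_controls(self, rng):
        lm = random_landmarks(rng, 5, 20, 40)
        a = 15.0
        model = fit_csrbf(lm, a)
        pts = rng.uniform(-50, 110, (200, 3))
        dists = np.linalg.norm(
            pts[:, None, :] - lm.source_points[None, :, :], axis=-1
        )
        outside = dists.min(axis=1) >= a
        assert outside.any()
        assert np.abs(model.displacement(pts)[outside]).max() == 0.0

    def test_invalid_support_radius(self, rng):
        from dirqa import ValidationError

        with pytest.raises(ValidationError):
            fit_csrbf(random_landmarks(rng, 4), -1.0)


class TestEvaluateField:
    def test_zero_model_gives_zero_field(self, iso_grid, rng):
        sp = rng.uniform(5, 25, (6, 3))
        lm = LandmarkSet(sp, sp.copy(), np.zeros(6, bool))
        f = evaluate_field(fit_tps(lm), iso_grid)
        assert np.abs(f.vectors).max() < 1e-8

    def test_translation_model_gives_constant_field(self, iso_grid, rng):
        t = np.array([1.0, 2.0, -1.5])
        sp = rng.uniform(2, 28, (8, 3))
        lm = LandmarkSet(sp, sp + t, np.zeros(8, bool))
        f = evaluate_field(fit_tps(lm), iso_grid)
        assert np.abs(f.vectors - t).max() < 1e-6

    def test_per_voxel_agreement_with_pointwise_model(self, iso_grid, rng):
        lm = random_landmarks(rng, 6, 4, 26)
        model = fit_csrbf(lm, 18.0)
        f = evaluate_field(model, iso_grid)
        for _ in range(20):
            idx = tuple(rng.integers(0, s) for s in iso_grid.size)
            x = iso_grid.index_to_physical(np.array(idx))
            assert np.allclose(f.vectors[idx], model.displacement(x)[0], atol=1e-9)


class TestAddFields:
    def test_identity_commutativity_and_constants(self, iso_grid, rng):
        f1 = VectorField(iso_grid, rng.normal(size=iso_grid.size + (3,)))
        f2 = VectorField(iso_grid, rng.normal(size=iso_grid.size + (3,)))
        zero = VectorField.zeros(iso_grid)
        np.testing.assert_array_equal(add_fields(f1, zero).vectors, f1.vectors)
        np.testing.assert_array_equal(
            add_fields(f1, f2).vectors, add_fields(f2, f1).vectors
        )

    def test_grid_mismatch_rejected(self, iso_grid, small_grid):
        with pytest.raises(GridMismatchError):
            add_fields(VectorField.zeros(iso_grid), VectorField.zeros(small_grid))


class TestWarpImage:
    def test_zero_field_is_identity(self, iso_grid, rng):
        img = ScalarVolume(iso_grid, rng.normal(0, 100, iso_grid.size))
        out = warp_image(img, VectorField.zeros(iso_grid))
        np.testing.assert_allclose(out.values, img.values, atol=1e-12)

    def test_one_voxel_shift_moves_data_and_fills_vacated_face(self, iso_grid, rng):
        img = ScalarVolume(iso_grid, rng.normal(0, 100, iso_grid.size))
        shift = np.zeros(iso_grid.size + (3,))
        shift[..., 0] = iso_grid.spacing[0]  # +1 voxel along axis 0
        out = warp_image(img, VectorField(iso_grid, shift), fill_value=-1000.0)
        np.testing.assert_allclose(out.values[:-1], img.values[1:], atol=1e-9)
        np.testing.assert_array_equal(out.values[-1], -1000.0)

    def test_agrees_with_pointwise_trilinear_oracle(self, rng):
        grid = ImageGrid((12, 12, 12), (2.0, 2.0, 2.0))
        img = ScalarVolume(grid, rng.normal(0, 50, grid.size))
        f = VectorField(grid, smooth_random_field_array(rng, grid, amplitude=3.0))
        out = warp_image(img, f, fill_value=-1000.0)
        centers = grid.voxel_centers()
        for _ in range(30):
            idx = tuple(rng.integers(0, 12, 3))
            target = centers[idx] + f.vectors[idx]
            expected = trilinear_point(img.values, grid, target, -1000.0)
            assert out.values[idx] == pytest.approx(expected, abs=1e-6)


class TestWarpMask:
    def test_zero_field_identity_and_integer_shift(self, iso_grid, rng):
        mask = BinaryMask(iso_grid, rng.random(iso_grid.size) > 0.7)
        out = warp_mask(mask, VectorField.zeros(iso_grid))
        np.testing.assert_array_equal(out.values, mask.values)
        shift = np.zeros(iso_grid.size + (3,))
        shift[..., 2] = 2 * iso_grid.spacing[2]
        shifted = warp_mask(mask, VectorField(iso_grid, shift))
        np.testing.assert_array_equal(shifted.values[:, :, :-2], mask.values[:, :, 2:])

    def test_uniform_scaling_scales_voxel_count_as_s_cubed(self):
        grid = ImageGrid((64, 64, 64), (1.0, 1.0, 1.0))
        center = np.array([31.5, 31.5, 31.5])
        centers = grid.voxel_centers()
        sphere = BinaryMask(
            grid, np.sum((centers - center) ** 2, axis=-1) <= 15.0**2
        )
        s = 1.2
        # pull-back scaling about the sphere center: output(x) = input(c + (x-c)/s)
        # grows the sphere by s, so the forward pull field uses scale 1/s
        spec = AnalyticFieldSpec("uniform_scaling", center=tuple(center), scale=1 / s)
        f, _ = analytic_field(spec, grid)
        warped = warp_mask(sphere, f)
        assert warped.voxel_count == pytest.approx(s**3 * sphere.voxel_count, rel=0.05)


class TestEditIntensity:
    def test_additive_edit_preserves_structure(self, iso_grid, rng):
        img = ScalarVolume(iso_grid, rng.normal(0, 100, iso_grid.size))
        region = BinaryMask(iso_grid, rng.random(iso_grid.size) > 0.5)
        out = edit_intensity(img, region, -1000.0)
        inside, outside = region.values, ~region.values
        np.testing.assert_allclose(
            out.values[inside], img.values[inside] - 1000.0
        )
        np.testing.assert_array_equal(out.values[outside], img.values[outside])
        # pairwise differences inside the region are unchanged
        vals_in = img.values[inside][:50]
        out_in = out.values[inside][:50]
        np.testing.assert_allclose(
            np.subtract.outer(out_in, out_in), np.subtract.outer(vals_in, vals_in),
            atol=1e-12,
        )

    def test_zero_delta_is_identity(self, iso_grid, rng):
        img = ScalarVolume(iso_grid, rng.normal(size=iso_grid.size))
        region = BinaryMask(iso_grid, np.ones(iso_grid.size, bool))
        np.testing.assert_array_equal(
            edit_intensity(img, region, 0.0).values, img.values
        )


class TestInvertField:
    def test_zero_field_inverts_to_zero(self, iso_grid):
        res = invert_field(VectorField.zeros(iso_grid))
        assert res.converged and res.iterations == 1
        assert np.abs(res.field.vectors).max() == 0.0

    def test_translation_inverts_to_negated_translation(self, iso_grid):
        t = np.array([1.5, -2.0, 0.5])
        f = VectorField(iso_grid, np.broadcast_to(t, iso_grid.size + (3,)).copy())
        res = invert_field(f, tolerance=1e-6)
        assert res.converged
        assert np.abs(res.field.vectors + t).max() < 1e-9

    def test_uniform_scaling_matches_closed_form_inverse(self):
        grid = ImageGrid((32, 32, 32), (2.0, 2.0, 2.0))
        c = (31.0, 31.0, 31.0)
        f, gt = analytic_field(
            AnalyticFieldSpec("uniform_scaling", center=c, scale=1.25), grid
        )
        res = invert_field(f, tolerance=1e-4, max_iterations=200)
        assert res.converged
        expected, _ = analytic_field(gt.inverse_spec, grid)
        err = np.abs(res.field.vectors - expected.vectors)
        assert interior(err, 3).max() < 0.01

    def test_non_convergence_reports_warning_status(self, iso_grid, rng):
        wild = VectorField(iso_grid, rng.normal(0, 40, iso_grid.size + (3,)))
        with pytest.warns(RuntimeWarning, match="did not converge"):
            res = invert_field(wild, tolerance=1e-9, max_iterations=2)
        assert not res.converged
        assert res.residual > 1e-9

    def test_warp_then_inverse_warp_recovers_image(self, rng):
        """Round-trip warping error is bounded by pure interpolation blur."""
        grid = ImageGrid((24, 24, 24), (2.0, 2.0, 2.0))
        c = (23.0, 23.0, 23.0)
        img = ScalarVolume(
            grid, 100 * np.sin(grid.voxel_centers().sum(-1) / 11.0)
        )
        f, _ = analytic_field(
            AnalyticFieldSpec("uniform_scaling", center=c, scale=1.15), grid
        )
        res = invert_field(f, tolerance=1e-4, max_iterations=100)
        round_trip = warp_image(warp_image(img, f), res.field)
        inner = BinaryMask(grid, np.zeros(grid.size, bool))
        inner.values[4:-4, 4:-4, 4:-4] = True
        err = rmse(img, round_trip, inner)
        # oracle: two zero-displacement resampling passes at the same
        # sample locations bound the interpolation-blur level
        zero = VectorField.zeros(grid)
        blur = warp_image(warp_image(img, zero), zero)
        blur_err = rmse(img, blur, inner)
        assert err <= blur_err + 3.0  # mm-scale smooth image: blur-limited
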