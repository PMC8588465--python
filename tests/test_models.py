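import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snilp import (
    SNILP,
    AxisOrder,
    LocalPolynomial,
    ModelKind,
    ModelParams,
    Polynomial2D,
    RadialPolynomial,
    SimulationSpec,
    SmoothLocalPolynomial,
    evaluate_params,
    export_params,
    find_optical_center,
    fit_lines_1d,
    fit_lp,
    fit_p2d,
    fit_rp,
    fit_slp,
    fit_snilp,
    make_flat_image,
    make_vignetting,
    parameter_count,
)


def normal_equations_fit(x, y, degree):
    """Independent oracle: (X^T X)^-1 X^T y with an explicit inverse."""
    design = np.vander(x, degree + 1, increasing=True)
    beta = np.linalg.inv(design.T @ design) @ design.T @ y
    return design @ beta


class TestFitLines1D:
    def test_exact_fit_of_polynomial_rows(self):
        i = np.arange(32, dtype=float)
        row = 2.0 + 3.0 * i + i**2
        img = np.tile(row, (10, 1))
        out = fit_lines_1d(img, "horizontal", 2)
        assert np.max(np.abs(out - img)) <= 1e-10

    @pytest.mark.parametrize("axis", ["horizontal", "vertical"])
    @pytest.mark.parametrize("degree", [0, 1, 3])
    def test_constant_image_any_degree(self, axis, degree):
        img = np.full((12, 15), 4.2)
        np.testing.assert_allclose(fit_lines_1d(img, axis, degree), 4.2,
                                   atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        row = rng.standard_normal(20)
        img = row[None, :].repeat(3, axis=0)
        out = fit_lines_1d(img, "horizontal", 3)
        expected = normal_equations_fit(np.arange(20.0), row, 3)
        np.testing.assert_allclose(out[0], expected, atol=1e-8)

    def test_vertical_matches_transposed_horizontal(self, rng):
        img = rng.random((9, 14))
        v = fit_lines_1d(img, "vertical", 2)
        h = fit_lines_1d(img.T, "horizontal", 2)
        np.testing.assert_allclose(v, h.T, atol=1e-12)

    def test_underdetermined_line_raises(self):
        with pytest.raises(ValueError, match="line length"):
            fit_lines_1d(np.zeros((4, 10)), "vertical", 4)


class TestLP:
    def test_constant_raw_surface_preserved(self):
        est = fit_lp(np.full((10, 10), 7.0), 2)
        np.testing.assert_allclose(est.values * est.norm_constant, 7.0,
                                   atol=1e-12)
        assert est.values.max() == 1.0

    def test_recovers_additive_polynomial_surface(self):
        i = np.arange(32.0)
        j = np.arange(32.0)
        surface = (1 + 0.1 * i + 0.01 * i**2)[None, :] + (2 + 0.05 * j**2)[:, None]
        est = fit_lp(surface, 2)
        recon = est.values * est.norm_constant
        assert np.max(np.abs(recon - surface)) <= 1e-9

    def test_degree_2_is_the_local_parabolic_model(self, noisy_flat_small):
        generic = LocalPolynomial(degree=2).fit(noisy_flat_small)
        np.testing.assert_array_equal(
            generic.vignetting_, fit_lp(noisy_flat_small, 2).values
        )


class TestSLP:
    def test_k1_bit_identical_to_lp(self, noisy_flat_small):
        slp = fit_slp(noisy_flat_small, 4, 1)
        lp = fit_lp(noisy_flat_small, 4)
        np.testing.assert_array_equal(slp.values, lp.values)

    def test_constant_image_fixed_point(self):
        est = fit_slp(np.full((10, 12), 3.0), 2, 5)
        np.testing.assert_allclose(est.values * est.norm_constant, 3.0,
                                   atol=1e-12)

    def test_invalid_k(self, noisy_flat_small):
        with pytest.raises(ValueError, match="k"):
            fit_slp(noisy_flat_small, 2, 0)

    def test_distance_to_snilp_halves_each_iteration(self, noisy_flat_small):
        # SLP_k = SNILP + (cross terms) / 2^(k-1): geometric approach
        sn = fit_snilp(noisy_flat_small, 4).values
        diffs = [
            np.max(np.abs(fit_slp(noisy_flat_small, 4, k).values - sn))
            for k in (1, 2, 3, 6)
        ]
        assert diffs[0] > diffs[1] > diffs[2] > diffs[3]
        assert diffs[1] / diffs[0] == pytest.approx(0.5, rel=0.2)


class TestSNILP:
    def test_recovers_separable_polynomial_surface(self, separable_surface):
        est = fit_snilp(separable_surface, 2)
        expected = separable_surface / separable_surface.max()
        assert np.max(np.abs(est.values - expected)) <= 1e-10
        assert est.normalized and est.values.max() == 1.0

    def test_constant_image_gives_all_ones(self):
        est = fit_snilp(np.full((8, 9), 5.0), 3)
        np.testing.assert_allclose(est.values, 1.0, atol=1e-12)

    def test_axis_order_immaterial(self, noisy_flat_small):
        a = fit_snilp(noisy_flat_small, 6, AxisOrder.X_THEN_Y).values
        b = fit_snilp(noisy_flat_small, 6, AxisOrder.Y_THEN_X).values
        assert np.max(np.abs(a - b)) <= 2e-12

    def test_idempotent(self, noisy_flat_small):
        once = fit_snilp(noisy_flat_small, 6).values
        twice = fit_snilp(once, 6).values
        assert np.mean(np.abs(twice - once)) <= 1e-13

    @given(scale=st.floats(0.25, 8.0))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_normalized_output_scale_invariant(self, scale):
        img = np.random.default_rng(5).random((24, 30)) + 0.5
        base = fit_snilp(img, 3).values
        scaled = fit_snilp(scale * img, 3).values
        np.testing.assert_allclose(scaled, base, atol=1e-11)


class TestP2D:
    def test_exact_fit_of_bilinear_surface(self):
        i = np.arange(20.0)
        j = np.arange(16.0)
        surface = 1 + i[None, :] + j[:, None] + j[:, None] * i[None, :]
        est = fit_p2d(surface, 2)
        recon = est.values * est.norm_constant
        assert np.max(np.abs(recon - surface)) <= 1e-9

    def test_degree_zero_is_pixel_mean(self, rng):
        img = rng.random((10, 11))
        est = fit_p2d(img, 0)
        np.testing.assert_allclose(est.values * est.norm_constant,
                                   img.mean(), atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        img = rng.random((16, 16))
        est = fit_p2d(img, 3)
        # independent solve: raw-coordinate monomial design, explicit inverse
        jj, ii = np.mgrid[0:16, 0:16]
        cols = [
            (ii.ravel() ** p) * (jj.ravel() ** q)
            for p in range(4)
            for q in range(4 - p)
        ]
        design = np.column_stack(cols)
        beta = np.linalg.inv(design.T @ design) @ design.T @ img.ravel()
        expected = (design @ beta).reshape(16, 16)
        np.testing.assert_allclose(est.values * est.norm_constant, expected,
                                   atol=1e-8)

    def test_too_few_pixels_raises(self):
        with pytest.raises(ValueError):
            fit_p2d(np.ones((2, 2)), 2)


class TestOpticalCenter:
    @pytest.mark.parametrize("r0,c0", [(12.0, 20.0), (5.5, 33.25)])
    def test_paraboloid_stationary_point(self, r0, c0):
        jj, ii = np.mgrid[0:32, 0:48].astype(float)
        img = 1.0 - 2e-4 * (jj - r0) ** 2 - 1e-4 * (ii - c0) ** 2
        center = find_optical_center(img)
        assert not center.flagged
        assert center.row == pytest.approx(r0, abs=1e-6)
        assert center.col == pytest.approx(c0, abs=1e-6)

    def test_centered_vignetting_center_near_image_center(self):
        spec = SimulationSpec(focal_length_mm=50.0, resolution=(96, 128),
                              sigma_add=0.0, sigma_multi=0.0, seed=0)
        center = find_optical_center(make_vignetting(spec).pixels)
        assert abs(center.row - 95 / 2) <= 0.5
        assert abs(center.col - 127 / 2) <= 0.5

    def test_tilted_plane_falls_back_and_flags(self):
        jj, ii = np.mgrid[0:20, 0:30].astype(float)
        center = find_optical_center(1.0 + 0.01 * ii)
        assert center.flagged
        assert center.method == "smoothed_argmax_fallback"
        assert 0 <= center.row <= 19 and 0 <= center.col <= 29


class TestRP:
    def test_exact_fit_of_radial_quadratic(self):
        jj, ii = np.mgrid[0:40, 0:50].astype(float)
        r = np.hypot(jj - 19.0, ii - 24.0)
        surface = 1.0 - 0.3 * (r / r.max()) ** 2
        est = fit_rp(surface, 2, center=(19.0, 24.0))
        recon = est.values * est.norm_constant
        assert np.max(np.abs(recon - surface)) <= 1e-9

    def test_constant_image_all_ones(self):
        est = fit_rp(np.full((12, 12), 2.0), 2, center=(5.5, 5.5))
        np.testing.assert_allclose(est.values, 1.0, atol=1e-12)

    def test_center_found_automatically_and_recorded(self):
        spec = SimulationSpec(focal_length_mm=24.0, resolution=(48, 64),
                              sigma_add=0.0, sigma_multi=0.0, seed=0)
        est = fit_rp(make_vignetting(spec).pixels, 4)
        assert est.center is not None
        assert abs(est.center[0] - 47 / 2) <= 0.5
        assert abs(est.center[1] - 63 / 2) <= 0.5

    def test_even_basis_matches_full_on_symmetric_surface(self):
        jj, ii = np.mgrid[0:30, 0:30].astype(float)
        r = np.hypot(jj - 14.5, ii - 14.5)
        surface = 1.0 - 0.2 * (r / r.max()) ** 2 + 0.05 * (r / r.max()) ** 4
        full = fit_rp(surface, 4, center=(14.5, 14.5))
        even = fit_rp(surface, 4, center=(14.5, 14.5), even_only=True)
        np.testing.assert_allclose(full.values, even.values, atol=1e-9)

    def test_worse_than_snilp_on_asymmetric_vignetting(self):
        from snilp import rmse

        spec = SimulationSpec(
            focal_length_mm=24.0, resolution=(96, 128),
            center_offset_px=(10.0, 14.0), anisotropy=1.4,
            sigma_add=0.0, sigma_multi=0.0, seed=0,
        )
        truth = make_vignetting(spec).pixels
        assert rmse(fit_rp(truth, 6).values, truth) > rmse(
            fit_snilp(truth, 6).values, truth
        )


class TestParams:
    @pytest.mark.parametrize(
        "model,degree,shape,expected",
        [
            (ModelKind.P2D, 5, (100, 100), 21),
            (ModelKind.RP, 6, (100, 100), 9),
            (ModelKind.SNILP, 4, (480, 640), 2400),
            (ModelKind.SLP, 4, (480, 640), 5600),
        ],
    )
    def test_parameter_count_formulas(self, model, degree, shape, expected):
        assert parameter_count(model, degree, shape) == expected

    @pytest.mark.parametrize("degree", range(2, 11))
    def test_counts_consistent_across_degrees(self, degree):
        shape = (60, 80)
        assert parameter_count("p2d", degree, shape) == (
            (degree**2 + 3 * degree + 2) // 2
        )
        assert parameter_count("rp", degree, shape) == degree + 3
        assert parameter_count("slp", degree, shape) == 140 * (degree + 1)
        assert parameter_count("snilp", degree, shape) == 60 * (degree + 1)

    @pytest.mark.parametrize("maker,kwargs", [
        (fit_p2d, {}),
        (fit_rp, {}),
        (fit_snilp, {}),
        (fit_lp, {}),
    ])
    def test_export_evaluate_round_trip(self, noisy_flat_small, maker, kwargs):
        est = maker(noisy_flat_small, 4, keep_coefficients=True, **kwargs)
        params = export_params(est)
        assert params.payload_count == parameter_count(
            est.model, 4, noisy_flat_small.shape
        )
        recon = evaluate_params(params)
        assert np.max(np.abs(recon.values - est.values)) <= 1e-12

    def test_slp_round_trip_and_count(self, noisy_flat_small):
        est = fit_slp(noisy_flat_small, 3, 4, keep_coefficients=True)
        params = export_params(est)
        m, n = noisy_flat_small.shape
        assert params.payload_count == (m + n) * 4
        recon = evaluate_params(params)
        assert np.max(np.abs(recon.values - est.values)) <= 1e-12

    def test_snilp_tall_image_uses_smaller_side(self, rng):
        img = rng.random((40, 24)) + 1.0
        est = fit_snilp(img, 2, keep_coefficients=True)
        params = export_params(est)
        assert params.payload_count == 24 * 3  # min(M, N) * (s + 1)
        recon = evaluate_params(params)
        assert np.max(np.abs(recon.values - est.values)) <= 1e-12

    def test_json_file_round_trip(self, tmp_path, noisy_flat_small):
        est = fit_p2d(noisy_flat_small, 3, keep_coefficients=True)
        path = tmp_path / "p2d.params.json"
        export_params(est).save(path)
        recon = evaluate_params(ModelParams.load(path))
        assert np.max(np.abs(recon.values - est.values)) <= 1e-12

    def test_export_without_retention_raises(self, noisy_flat_small):
        with pytest.raises(ValueError, match="keep_coefficients"):
            export_params(fit_snilp(noisy_flat_small, 2))

    def test_corrupted_payload_raises_format_error(self, noisy_flat_small):
        est = fit_p2d(noisy_flat_small, 3, keep_coefficients=True)
        params = export_params(est)
        params.payload["beta"] = np.asarray(params.payload["beta"])[:-1]
        with pytest.raises(ValueError, match="payload"):
            evaluate_params(params)


class TestSklearnCompat:
    def test_get_set_params_clone(self, noisy_flat_small):
        from sklearn.base import clone

        model = SNILP(degree=4, order=AxisOrder.Y_THEN_X)
        assert clone(model).get_params()["degree"] == 4
        model.set_params(degree=6)
        fitted = model.fit(noisy_flat_small)
        assert fitted.vignetting_.shape == noisy_flat_small.shape
        assert fitted.vignetting_.max() == 1.0

    def test_transform_corrects_to_flat(self):
        spec = SimulationSpec(focal_length_mm=24.0, resolution=(48, 64),
                              sigma_add=0.0, sigma_multi=0.0, seed=0)
        truth = make_vignetting(spec).pixels
        model = SNILP(degree=8, clip_range=None).fit(truth)
        flat = model.transform(truth)
        assert np.std(flat) <= 1e-3  # degree-8 lines track cos^4 closely

    def test_unfitted_transform_raises(self):
        with pytest.raises(AttributeError, match="fit"):
            SNILP().transform(np.ones((4, 4)))
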