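import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from dcmstereo.camsim import render_distorted_stereo, scale_distortion_spec
from dcmstereo.cli_io import calibrate_from_images
from dcmstereo.dcm_core import (
    Correspondences,
    DistortionCorrector,
    RatioField,
    build_dcm,
    coefficient_k,
    correspondences_from_lines,
    distortion_ratio,
    fit_ratio_field,
    lambda_coefficient,
    map_point,
)


def synthetic_correspondences(c_left, c_right, n=40, rmax=450.0, seed=3):
    """Pairs generated from an exact even-polynomial ratio R = 1 + c*rd^2."""
    rng = np.random.default_rng(seed)
    rd = rng.uniform(20.0, rmax, n)
    theta = rng.uniform(0.2, np.pi - 0.2, n)  # keep xd well off the midline
    sign = np.where(np.arange(n) % 2 == 0, -1.0, 1.0)
    xd = sign * rd * np.sin(theta)
    yd = rd * np.cos(theta)
    c = np.where(xd <= 0, c_left, c_right)
    R = 1.0 + c * rd**2
    return Correspondences(xd * R, yd * R, xd, yd, center=(400.0, 300.0))


class TestDistortionRatio:
    @pytest.mark.parametrize(
        "ru, rd, expected",
        [(1.0, 0.9, 1.111111), (1.7, 1.7, 1.0), (2.0, 1.6, 1.25)],
    )
    def test_quotient(self, ru, rd, expected):
        corr = Correspondences([ru], [0.0], [rd], [0.0], center=(400.0, 300.0))
        assert distortion_ratio(corr)[0] == pytest.approx(expected, abs=1e-6)

    def test_center_pair_rejected(self):
        with pytest.raises(ValueError):
            Correspondences([1.0], [1.0], [0.0], [0.0], center=(400.0, 300.0))


class TestCoefficientK:
    @pytest.mark.parametrize(
        "R, rd, expected",
        [(1.111111, 0.9, -0.137174), (1.0, 5.0, 0.0), (1.25, 2.0, -0.0625)],
    )
    def test_values(self, R, rd, expected):
        assert coefficient_k(R, rd) == pytest.approx(expected, abs=1e-6)

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError):
            coefficient_k(1.1, 0.0)


class TestLambdaCoefficient:
    def test_limit_value_at_zero_product(self):
        assert lambda_coefficient(0.0, 123.0) == 1.0
        assert lambda_coefficient(-1e-15, 1.0) == 1.0

    @staticmethod
    def _root_oracle(q):
        # independent quadratic-root oracle for q*lam^2 + lam - 1 = 0,
        # taking the branch continuous at q = 0 (root near 1)
        roots = np.roots([q, 1.0, -1.0])
        return float(roots[np.argmin(np.abs(roots - 1.0))])

    def test_reference_value(self):
        q = -0.137174  # k*ru^2 for R = 1.111111 (k = (1-R)/rd^2, ru = 1)
        lam = lambda_coefficient(q, 1.0)
        assert lam == pytest.approx(self._root_oracle(q), abs=1e-12)
        assert lam == pytest.approx(1.1963, abs=1e-4)
        assert abs(q * lam**2 + lam - 1.0) < 1e-9

    def test_relocation_approximates_ideal(self):
        # rd = 0.990099 with R = 1.01 has ideal radius 1; lam*rd overshoots
        # it by ~4e-4 — the second-order error of the reduced model
        q = -0.0102010
        lam = lambda_coefficient(q, 1.0)
        assert lam == pytest.approx(self._root_oracle(q), abs=1e-12)
        assert lam * 0.990099 == pytest.approx(1.0004, abs=1e-4)

    def test_too_strong_distortion_signalled(self):
        with pytest.raises(ValueError):
            lambda_coefficient(-0.3, 1.0)  # 1 + 4*k*ru^2 < 0

    @settings(deadline=None, derandomize=True)
    @given(
        R=st.floats(min_value=1.0, max_value=1.15),
        ru=st.floats(min_value=1e-3, max_value=500.0),
    )
    def test_quadratic_root_property(self, R, ru):
        rd = ru / R
        k = float(coefficient_k(R, rd))
        lam = lambda_coefficient(k, R * rd)
        assert abs(k * (R * rd) ** 2 * lam**2 + lam - 1.0) < 1e-9


class TestRatioFieldFit:
    def test_single_coefficient_recovery(self):
        corr = synthetic_correspondences(2e-7, 2e-7)
        field = fit_ratio_field(corr, degree=2)
        assert field.coef_left[0] == pytest.approx(2e-7, rel=0.01)
        assert field.coef_right[0] == pytest.approx(2e-7, rel=0.01)

    def test_asymmetric_halves_recovered_independently(self):
        corr = synthetic_correspondences(1e-7, 2e-7)
        field = fit_ratio_field(corr, degree=2)
        assert field.coef_left[0] == pytest.approx(1e-7, rel=0.01)
        assert field.coef_right[0] == pytest.approx(2e-7, rel=0.01)

    def test_undistorted_pairs_give_identity_field(self):
        corr = synthetic_correspondences(0.0, 0.0)
        field = fit_ratio_field(corr, degree=2)
        assert np.allclose(field.coef_left, 0.0, atol=1e-15)
        dcm = build_dcm(field, 100, 80)
        assert np.all(dcm.lam == 1.0)

    def test_underdetermined_fit_rejected(self):
        corr = synthetic_correspondences(1e-7, 1e-7, n=4)
        with pytest.raises(ValueError):
            fit_ratio_field(corr, degree=4)

    def test_extrapolation_clamps_with_warning(self):
        corr = synthetic_correspondences(1e-7, 1e-7, rmax=200.0)
        field = fit_ratio_field(corr, degree=2)
        with pytest.warns(UserWarning):
            far = field(np.array([400.0]), left=np.array([True]))
        clamped = field(np.array([field.rd_max_left]), left=np.array([True]))
        assert far[0] == pytest.approx(clamped[0])


class TestBuildDCM:
    def test_quadratic_root_holds_on_full_grid(self):
        corr = synthetic_correspondences(1e-7, 2.2e-7, rmax=480.0)
        dcm = build_dcm(fit_ratio_field(corr, degree=2), 200, 150)
        q = (1.0 - dcm.R) * dcm.R**2
        resid = np.abs(q * dcm.lam**2 + dcm.lam - 1.0)
        assert resid.max() < 1e-9

    def test_pincushion_lambda_monotone_outward(self):
        corr = synthetic_correspondences(1e-7, 1e-7, rmax=480.0)
        dcm = build_dcm(fit_ratio_field(corr, degree=2), 200, 150)
        assert np.all(dcm.lam >= 1.0)
        row = dcm.lam[75, 100:]  # rightward from the center row
        assert np.all(np.diff(row) >= -1e-12)

    def test_asymmetric_field_differs_across_midline(self):
        corr = synthetic_correspondences(1e-7, 2e-7)
        dcm = build_dcm(fit_ratio_field(corr, degree=2), 200, 150)
        assert not np.allclose(dcm.lam[:, 60], dcm.lam[:, 140])

    def test_center_pixel_is_identity(self):
        corr = synthetic_correspondences(1e-7, 1e-7)
        dcm = build_dcm(fit_ratio_field(corr, degree=2), 200, 150)
        # even dimensions put pixel (75, 100) exactly at the center
        assert dcm.lam[75, 100] == 1.0
        assert dcm.k[75, 100] == 0.0


class TestMapPoint:
    def _field_with_ratio(self, R_at_9=1.111111):
        # strong toy ratio; keep the fitted range tight so the clamped R
        # stays inside the model's validity (1 + 4*k*ru^2 >= 0)
        c = (R_at_9 - 1.0) / 81.0
        return RatioField(np.array([2]), np.array([c]), np.array([c]), 10.0, 10.0)

    def test_center_maps_to_itself(self):
        dcm = build_dcm(self._field_with_ratio(), 200, 200)
        assert np.allclose(map_point(dcm, np.array([100.0, 100.0])), [100.0, 100.0])

    def test_reference_relocation(self):
        # R(9) = 1.111 -> lam = 1.1963 (k*ru^2 is scale invariant), so a
        # point 9 px left of center relocates to 100 - 9*1.1963 = 89.23
        dcm = build_dcm(self._field_with_ratio(), 200, 200)
        out = map_point(dcm, np.array([91.0, 100.0]))
        assert out[0] == pytest.approx(89.233, abs=1e-3)
        assert out[1] == pytest.approx(100.0, abs=1e-9)

    def test_identity_dcm_is_identity_map(self):
        field = RatioField(np.array([2]), np.array([0.0]), np.array([0.0]), 500.0, 500.0)
        dcm = build_dcm(field, 200, 200)
        pts = np.array([[10.0, 20.0], [150.0, 199.0]])
        assert np.allclose(map_point(dcm, pts), pts)

    def test_out_of_bounds_rejected(self):
        dcm = build_dcm(self._field_with_ratio(), 200, 200)
        with pytest.raises(ValueError):
            map_point(dcm, np.array([250.0, 10.0]))


class TestApproximationQuality:
    def test_second_order_error_bound(self):
        # |lam*rd - ru| <= C*(R-1)^2*ru with C ~ 4 for fine distortion
        R = np.linspace(1.0005, 1.01, 50)
        ru = 300.0
        rd = ru / R
        lam = lambda_coefficient(coefficient_k(R, rd), ru)
        err = np.abs(lam * rd - ru)
        assert np.all(err <= 5.0 * (R - 1.0) ** 2 * ru)

    def test_fine_distortion_end_to_end_recovery(self, default_cfg):
        # simulate at one twentieth of the reference lens, calibrate, and
        # relocate the true distorted line positions: within 0.05 px of ideal
        from dcmstereo.camsim import pattern_for_config, project_pattern

        spec = scale_distortion_spec(default_cfg.distortion_spec(), 0.05)
        config = default_cfg.stereo_config(60.0)
        pattern = pattern_for_config(default_cfg.stereo_config(80.0), 1.0, 0.5)
        pair = render_distorted_stereo(pattern, config, spec, pattern_offset_mm=0.5)
        ideal_img, *_ = project_pattern(pattern, config, 0.5)
        corrector = calibrate_from_images(ideal_img, pair.reference, degree=4)
        pts = np.column_stack(
            [pair.distorted_lines_reference,
             np.full(pair.distorted_lines_reference.size, 300.0)]
        )
        recovered = corrector.transform(pts)[:, 0]
        assert np.abs(recovered - pair.ideal_lines_reference).max() < 0.05


class TestCorrespondencesFromLines:
    def test_radial_reconstruction_is_exact_for_radial_distortion(self):
        # place points on a known radial map and recover R = Xu/xd
        c = 1.5e-7
        rd = np.array([100.0, 200.0, 300.0])
        R = 1.0 + c * rd**2
        xd, yd = rd * 0.8, rd * 0.6
        Xu = xd * R
        corr = correspondences_from_lines(
            Xu + 400.0, xd + 400.0, yd + 300.0, center=(400.0, 300.0)
        )
        assert np.allclose(distortion_ratio(corr), R, atol=1e-12)

    def test_midline_observations_dropped(self):
        corr = correspondences_from_lines(
            [404.0, 600.0], [403.0, 590.0], [300.0, 300.0], center=(400.0, 300.0)
        )
        assert corr.n_pairs == 1

    def test_csv_roundtrip(self, tmp_path):
        corr = synthetic_correspondences(1e-7, 2e-7, n=12)
        corr.to_csv(tmp_path / "corr.csv")
        back = Correspondences.from_csv(tmp_path / "corr.csv", corr.center)
        assert np.allclose(back.xd, corr.xd)
        assert np.allclose(back.yu, corr.yu)


class TestDistortionCorrectorEstimator:
    def test_sklearn_protocol(self):
        est = DistortionCorrector(image_width=200, image_height=150, degree=2)
        params = est.get_params()
        assert params == {"image_width": 200, "image_height": 150, "degree": 2}
        cloned = clone(est)
        assert cloned.get_params() == params

    def test_fit_transform_matches_map_point(self):
        corr = synthetic_correspondences(1e-7, 2e-7)
        X = np.column_stack([corr.xd + 400.0, corr.yd + 300.0])
        y = np.column_stack([corr.xu + 400.0, corr.yu + 300.0])
        est = DistortionCorrector(image_width=800, image_height=600, degree=2).fit(X, y)
        inb = (np.abs(corr.xd) < 395) & (np.abs(corr.yd) < 295)
        assert inb.sum() > 10
        assert np.allclose(est.transform(X[inb]), map_point(est.dcm_, X[inb]))

    def test_unfitted_raises(self):
        est = DistortionCorrector()
        with pytest.raises(RuntimeError):
            est.transform(np.array([[1.0, 1.0]]))


def test_dcm_save_load_roundtrip(tmp_path):
    corr = synthetic_correspondences(1e-7, 2e-7)
    dcm = build_dcm(fit_ratio_field(corr, degree=2), 120, 90)
    dcm.save(tmp_path / "dcm")
    from dcmstereo.dcm_core import DCM

    back = DCM.load(tmp_path / "dcm")
    assert np.allclose(back.lam, dcm.lam)
    assert back.center == dcm.center
    pts = np.array([[10.0, 10.0], [110.0, 80.0]])
    assert np.allclose(map_point(back, pts), map_point(dcm, pts))
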