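"""The four pre-treatments: splice correction, SNV, SG derivative, range cut."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isoleaf import (
    PreprocessConfig,
    ProcessingState,
    Spectrum,
    SpectraSet,
    correct_sensor_jumps,
    preprocess_pipeline,
    savgol_first_derivative,
    snv_transform,
    subset_model_range,
)

WL = np.arange(350, 2501)


def _smooth_curve(wl=WL):
    """A smooth leaf-like curve used as the ground truth for splice tests."""
    x = (wl - 350) / 2150.0
    return 0.1 + 0.4 / (1.0 + np.exp(-(wl - 710) / 25.0)) - 0.1 * x**2


class TestJumpCorrection:
    def test_constant_segments_example(self):
        values = np.where(WL <= 1000, 0.40, np.where(WL <= 1800, 0.44, 0.50))
        out = correct_sensor_jumps(Spectrum(WL, values))
        np.testing.assert_allclose(out.values[WL <= 1000], 0.44)  # f_V = 1.1
        np.testing.assert_allclose(out.values[(WL >= 1001) & (WL <= 1800)], 0.44)

    def test_continuous_spectrum_unchanged(self):
        # make the curve exactly continuous at both splices: factors become 1
        values = _smooth_curve().copy()
        values[WL == 1000] = values[WL == 1001]
        values[WL == 1801] = values[WL == 1800]
        out = correct_sensor_jumps(Spectrum(WL, values))
        np.testing.assert_allclose(out.values, values, rtol=1e-12)

    def test_planted_distortion_recovered(self):
        # oracle: the pre-distortion curve itself
        truth = _smooth_curve()
        distorted = truth.copy()
        distorted[WL <= 1000] *= 0.95
        distorted[WL >= 1801] *= 1.06
        out = correct_sensor_jumps(Spectrum(WL, distorted))
        near_splices = ((WL >= 990) & (WL <= 1010)) | ((WL >= 1790) & (WL <= 1810))
        # multiplicative correction is exact up to the truth's own slope at
        # the splice; on a smooth curve the residual is far below 1e-3
        np.testing.assert_allclose(
            out.values[near_splices], truth[near_splices], rtol=2e-3
        )

    def test_swir1_reference_untouched(self):
        rng = np.random.default_rng(3)
        values = 0.3 + 0.1 * rng.random(WL.size)
        out = correct_sensor_jumps(Spectrum(WL, values))
        mid = (WL >= 1001) & (WL <= 1800)
        assert np.array_equal(out.values[mid], values[mid])

    def test_zero_at_splice_rejected(self):
        values = _smooth_curve().copy()
        values[WL == 1000] = 0.0
        with pytest.raises(ValueError, match="factor undefined"):
            correct_sensor_jumps(Spectrum(WL, values))

    def test_extreme_factor_warns(self):
        values = _smooth_curve().copy()
        values[WL <= 1000] *= 0.1  # factor 10 at the splice
        with pytest.warns(UserWarning, match="suspect"):
            correct_sensor_jumps(Spectrum(WL, values))

    def test_state_machine_forbids_reapplication(self):
        out = correct_sensor_jumps(Spectrum(WL, _smooth_curve()))
        with pytest.raises(ValueError, match="expected state"):
            correct_sensor_jumps(out)


class TestSNV:
    def test_canonical_example(self):
        out = snv_transform(Spectrum(np.arange(400, 403), np.array([0.0, 1.0, 2.0])))
        np.testing.assert_allclose(out.values, [-1.0, 0.0, 1.0], atol=1e-15)

    def test_output_moments(self, rng):
        values = 0.2 + 0.3 * rng.random(WL.size)
        out = snv_transform(Spectrum(WL, values))
        assert abs(out.values.mean()) < 1e-12
        assert abs(out.values.std(ddof=1) - 1.0) < 1e-12

    @settings(max_examples=30, derandomize=True)
    @given(
        a=st.floats(0.01, 50.0),
        b=st.floats(0.0, 5.0),
        seed=st.integers(0, 10_000),
    )
    def test_affine_invariance(self, a, b, seed):
        # snv(a*x + b) == snv(x) for a > 0: scatter removal contract
        x = np.random.default_rng(seed).random(200) + 0.1
        wl = np.arange(400, 600)
        base = snv_transform(Spectrum(wl, x)).values
        scaled = snv_transform(Spectrum(wl, a * x + b)).values
        np.testing.assert_allclose(scaled, base, atol=1e-8)

    def test_constant_spectrum_rejected(self):
        with pytest.raises(ValueError, match="SNV undefined"):
            snv_transform(Spectrum(np.arange(400, 500), np.full(100, 0.3)))

    def test_rowwise_on_sets(self, rng):
        sset = SpectraSet(["a", "b"], 0.2 + rng.random((2, WL.size)) * 0.5, WL)
        out = snv_transform(sset)
        np.testing.assert_allclose(out.matrix.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.matrix.std(axis=1, ddof=1), 1.0, atol=1e-12)


class TestSavitzkyGolay:
    def test_reproduces_linear_derivative(self):
        wl = np.arange(400, 500)
        out = savgol_first_derivative(Spectrum(wl, 3.0 * wl))
        np.testing.assert_allclose(out.values, 3.0, atol=1e-10)

    def test_reproduces_quadratic_derivative(self):
        wl = np.arange(400, 500)
        out = savgol_first_derivative(Spectrum(wl, (wl / 100.0) ** 2))
        np.testing.assert_allclose(out.values, 2.0 * out.wavelengths / 100.0**2, atol=1e-10)

    def test_edges_dropped(self):
        wl = np.arange(400, 500)
        out = savgol_first_derivative(Spectrum(wl, np.linspace(0, 1, wl.size)))
        assert out.wavelengths[0] == 404 and out.wavelengths[-1] == 495
        assert out.values.size == wl.size - 8

    def test_noise_suppression_vs_finite_difference(self, rng):
        # oracle: direct computation of both derivative estimators on the
        # same white-noise draws; the 9-point local fit must average noise down
        noise = rng.normal(size=(50, 500))
        sg = np.array(
            [savgol_first_derivative(Spectrum(np.arange(400, 900), 5 + row)).values
             for row in noise + 5]
        )
        fd = np.diff(noise, axis=1) / 1.0
        assert sg.var() < fd.var()

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            savgol_first_derivative(Spectrum(np.arange(400, 405), np.ones(5)))

    def test_derivative_state_rejected(self):
        wl = np.arange(400, 500)
        d = savgol_first_derivative(Spectrum(wl, 3.0 * wl))
        with pytest.raises(ValueError, match="already"):
            savgol_first_derivative(d)


class TestModelRange:
    def test_default_band_count(self):
        out = subset_model_range(Spectrum(WL, _smooth_curve()))
        assert out.values.size == 1401  # 400..1800 inclusive
        assert out.wavelengths[0] == 400 and out.wavelengths[-1] == 1800

    def test_derivative_axis_intersection(self):
        d = savgol_first_derivative(Spectrum(WL, _smooth_curve()))
        out = subset_model_range(d)  # derivative axis starts at 354
        assert out.wavelengths[0] == 400 and out.wavelengths[-1] == 1800

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="intersect"):
            subset_model_range(
                Spectrum(WL, _smooth_curve()), PreprocessConfig(model_range=(2600, 2700))
            )


class TestPipeline:
    def test_states_and_axis(self, greenhouse):
        _, sset, _ = greenhouse
        out, log = preprocess_pipeline(sset)
        assert out.state == ProcessingState.FIRST_DERIVATIVE
        assert out.wavelengths[0] >= 400 and out.wavelengths[-1] <= 1800
        assert len(log) == 4

    def test_double_application_rejected(self, greenhouse):
        _, sset, _ = greenhouse
        out, _ = preprocess_pipeline(sset)
        with pytest.raises(ValueError, match="raw"):
            preprocess_pipeline(out)

    def test_planted_feature_zero_crossing(self):
        # a Gaussian dip has derivative zero at its center: the pipeline's
        # derivative must cross zero at the planted center (oracle = the
        # analytic derivative of the generating curve)
        center, width = 1200.0, 30.0
        values = 0.5 * (1.0 - 0.3 * np.exp(-((WL - center) ** 2) / (2 * width**2)))
        sset = SpectraSet(["a"], values[None, :], WL)
        out, _ = preprocess_pipeline(sset)
        idx = np.searchsorted(out.wavelengths, int(center))
        window = out.matrix[0, idx - 3 : idx + 3]
        assert np.any(np.diff(np.sign(window)) != 0)  # sign change at center

    def test_config_validation(self):
        with pytest.raises(ValueError, match="filter width"):
            PreprocessConfig(sg_half_window=1, sg_poly_order=3)
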