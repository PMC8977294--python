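"""Noise estimation, adaptive thresholds, and neighborhood shrinkage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyashrink import (
    IWTDenoiser,
    NoiseSpec,
    PhantomSpec,
    ShrinkageParams,
    add_noise,
    bspline_filters,
    compute_threshold,
    denoise_iwt,
    dyadic_forward,
    estimate_image_sigma,
    estimate_sigma,
    make_phantom,
    mse,
    propagate_noise_variance,
    shrink_coefficient,
    window_max,
)
from dyashrink.errors import InvalidParameterError
from dyashrink.wavelet import FilterPair


def _haar_like():
    # two-tap pair with highpass [0.5, -0.5]
    return FilterPair(
        np.array([0.5, 0.5]), np.array([0.5, -0.5]),
        np.array([1.0]), np.array([1.0]), center=0,
    )


class TestEstimateSigma:
    def test_constant_magnitude_cancels_mad_constant(self):
        plane = np.full((4, 4), 0.6745)
        assert estimate_sigma(plane) == pytest.approx(1.0)

    def test_direct_median_evaluation(self):
        coeffs = np.array([1.0, -2.0, 3.0, -4.0, 5.0])
        assert estimate_sigma(coeffs) == pytest.approx(3.0 / 0.6745)

    def test_zero_plane_gives_zero(self):
        assert estimate_sigma(np.zeros((8, 8))) == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidParameterError):
            estimate_sigma(np.array([]))

    def test_image_domain_recovery_from_pure_noise(self):
        noise = np.random.default_rng(5).normal(0.0, 15.0, (256, 256))
        decomp = dyadic_forward(noise, scales=2)
        est = estimate_image_sigma(decomp, bspline_filters())
        assert est == pytest.approx(15.0, rel=0.05)


class TestPropagateNoiseVariance:
    def test_zero_sigma_propagates_zero(self):
        assert propagate_noise_variance(0.0, bspline_filters(), 3) == 0.0

    def test_two_tap_highpass_energy(self):
        # direction-1 scale-1 variance is the high-pass tap energy
        assert propagate_noise_variance(1.0, _haar_like(), 1, direction=1) == pytest.approx(0.5)

    def test_quadratic_scaling_in_sigma(self):
        f = bspline_filters()
        for j in (1, 2, 3):
            assert propagate_noise_variance(2.0, f, j) == pytest.approx(
                4.0 * propagate_noise_variance(1.0, f, j)
            )

    def test_negative_sigma_rejected(self):
        with pytest.raises(InvalidParameterError):
            propagate_noise_variance(-1.0, bspline_filters(), 1)

    @pytest.mark.parametrize("j", [1, 2, 3])
    def test_matches_monte_carlo_white_noise(self, j):
        """Pooled scale-j detail variance of unit white noise matches the
        propagated prediction within 5% relative error."""
        noise = np.random.default_rng(42).normal(size=(256, 256))
        decomp = dyadic_forward(noise, scales=3)
        empirical = 0.5 * (decomp.detail(j, 1).var() + decomp.detail(j, 2).var())
        predicted = propagate_noise_variance(1.0, bspline_filters(), j)
        assert empirical == pytest.approx(predicted, rel=0.05)


class TestComputeThreshold:
    def test_noiseless_subband_needs_no_threshold(self):
        assert compute_threshold(0.0, 256, 2, 2.0) == 0.0

    def test_trivial_subband_needs_no_threshold(self):
        assert compute_threshold(4.0, 1, 2, 2.0) == 0.0

    def test_variance_ratio_hand_value(self):
        lam = compute_threshold(4.0, 256, 2, 2.0, rule="variance-ratio")
        assert lam == pytest.approx(2.0 * np.sqrt(np.log(256) / 2.0), abs=1e-4)
        assert lam == pytest.approx(3.3302, abs=1e-4)

    def test_noisy_variance_hand_value(self):
        lam = compute_threshold(4.0, 256, 2, 2.0, rule="noisy-variance")
        assert lam == pytest.approx(4.0 / np.sqrt(2.0) * np.sqrt(np.log(256) / 2.0))

    def test_bayes_hand_value(self):
        # signal spread sqrt(6 - 2) = 2
        lam = compute_threshold(2.0, 256, 2, 6.0, rule="bayes")
        assert lam == pytest.approx(1.0 * np.sqrt(np.log(256) / 2.0))

    def test_invalid_beta_rejected(self):
        with pytest.raises(InvalidParameterError):
            compute_threshold(1.0, 256, 2, 0.0)

    @pytest.mark.parametrize("rule", ["bayes", "noisy-variance", "variance-ratio"])
    def test_monotone_in_noise_and_signal(self, rule):
        """lambda is nondecreasing in sigma_j^2 and nonincreasing in beta_j."""
        beta = 25.0
        lams = [compute_threshold(s2, 4096, 3, beta, rule=rule) for s2 in (1.0, 4.0, 9.0)]
        assert lams == sorted(lams)
        lams_b = [compute_threshold(4.0, 4096, 3, b, rule=rule) for b in (9.0, 25.0, 100.0)]
        assert lams_b == sorted(lams_b, reverse=True)


class TestWindowMax:
    def test_max_of_absolute_values(self):
        plane = np.array([[1.0, -5.0, 3.0], [0.0, 2.0, 1.0], [0.5, -1.0, 0.0]])
        assert window_max(plane, 1, 1) == 5.0

    def test_zero_plane(self):
        assert window_max(np.zeros((5, 5)), 2, 2) == 0.0

    def test_corner_with_symmetric_boundary_matches_enumeration(self):
        plane = np.array([[1.0, -2.0, 3.0], [4.0, 0.5, -6.0], [7.0, 8.0, -9.0]])
        # symmetric reflection around (0, 0): the 3x3 window covers
        # rows {0r, 0, 1} x cols {0r, 0, 1} -> |values| {1, 2, 4, 0.5}
        assert window_max(plane, 0, 0) == 4.0
        assert window_max(plane, 2, 2, ShrinkageParams(3, "periodic")) == max(
            abs(v) for v in (0.5, -6.0, 4.0, 8.0, -9.0, 7.0, -2.0, 3.0, 1.0)
        )

    def test_out_of_bounds_position_rejected(self):
        with pytest.raises(IndexError):
            window_max(np.zeros((4, 4)), 4, 0)

    def test_even_window_rejected(self):
        with pytest.raises(InvalidParameterError):
            ShrinkageParams(window_size=4)


class TestShrinkCoefficient:
    @pytest.mark.parametrize(
        "x, lam, M, expected",
        [
            (5.0, 3.0, 5.0, 5.0),    # keep branch: |x| >= lambda
            (2.0, 3.0, 2.5, 0.0),    # zero branch: window max below lambda
            (2.0, 3.0, 4.0, 1.0),    # middle branch: x*(1-(3-2)/(4-2))
            (-2.0, 3.0, 4.0, -1.0),  # sign preservation in the middle branch
            (2.0, 3.0, 3.0, 0.0),    # clamp: factor would be negative
            (2.0, 3.0, 2.0, 0.0),    # degenerate M == |x| < lambda
            (-5.0, 3.0, 5.0, -5.0),  # keep branch preserves sign
            (1.0, 0.0, 0.0, 1.0),    # zero threshold keeps everything
        ],
    )
    def test_branch_surface(self, x, lam, M, expected):
        assert shrink_coefficient(x, lam, M) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=200)
    @given(
        x=st.floats(-1e6, 1e6),
        lam=st.floats(0, 1e6),
        extra=st.floats(0, 1e6),
    )
    def test_shrinkage_is_a_contraction(self, x, lam, extra):
        M = abs(x) + extra  # window max always >= |x|
        y = shrink_coefficient(x, lam, M)
        assert abs(y) <= abs(x) + 1e-9
        assert y * x >= 0  # sign preserved or zero


class TestDenoiseIWT:
    def test_noiseless_constant_image_is_identity(self):
        x = np.full((64, 64), 42.0)
        out, diag = denoise_iwt(x)
        np.testing.assert_allclose(out, x, atol=1e-8)
        assert diag.noise_model.sigma == 0.0
        assert all(lam == 0.0 for row in diag.thresholds.lambdas for lam in row)

    def test_noiseless_phantom_is_near_identity(self):
        clean = make_phantom(PhantomSpec(64, 64, (0.0, 255.0), 6, seed=3))
        out, diag = denoise_iwt(clean)
        # piecewise-constant image: MAD sees a majority of zero coefficients
        assert diag.noise_model.sigma == 0.0
        np.testing.assert_allclose(out.values, clean.values, atol=1e-8)

    def test_improves_fidelity_on_noisy_phantom(self, phantom_pair):
        clean, noisy = phantom_pair
        out, _ = denoise_iwt(noisy)
        assert mse(clean, out) < mse(clean, noisy)

    def test_branch_counts_partition_each_subband(self, phantom_pair):
        _, noisy = phantom_pair
        _, diag = denoise_iwt(noisy, scales=3)
        n = noisy.values.size
        for row in diag.branch_counts:
            for kept, shrunk, zeroed in row:
                assert kept + shrunk + zeroed == n

    def test_translation_invariance_periodic(self, phantom_pair):
        _, noisy = phantom_pair
        x = noisy.values
        shifted, _ = denoise_iwt(np.roll(x, (7, 11), (0, 1)), boundary="periodic")
        plain, _ = denoise_iwt(x, boundary="periodic")
        assert np.abs(shifted - np.roll(plain, (7, 11), (0, 1))).max() <= 1e-8

    def test_diagnostics_serialize_to_json(self, phantom_pair):
        import json

        _, noisy = phantom_pair
        _, diag = denoise_iwt(noisy)
        blob = json.loads(diag.to_json())
        assert blob["scales"] == 3
        assert len(blob["lambda_per_subband"]) == 3
        assert blob["sigma"] > 0


class TestIWTDenoiserEstimator:
    def test_get_set_params_roundtrip(self):
        est = IWTDenoiser(scales=2, window=5)
        params = est.get_params()
        assert params["scales"] == 2 and params["window"] == 5
        est.set_params(scales=4)
        assert est.scales == 4
        with pytest.raises(ValueError):
            est.set_params(bogus=1)

    def test_fit_transform_matches_function(self, phantom_pair):
        _, noisy = phantom_pair
        est = IWTDenoiser()
        out_est = est.fit_transform(noisy.values)
        out_fn, diag = denoise_iwt(noisy.values)
        np.testing.assert_allclose(out_est, out_fn)
        assert est.noise_model_.sigma == diag.noise_model.sigma

    def test_sklearn_clone_compatibility(self):
        from sklearn.base import clone

        est = IWTDenoiser(wavelet="haar", scales=2)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
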