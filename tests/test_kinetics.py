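"""Bolus-kinetics tests: model evaluation against hand values, fitting
self-consistency, closed-form/numeric oracle agreement, and the derived
perfusion parameters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.special import gamma as gamma_fn

from bubbleflow import (
    BolusParams,
    GammaVariateModel,
    InvalidInputError,
    TimeIntensityCurve,
    auc,
    derive_parameters,
    ellipsoid_volume,
    extract_tic,
    fit_gamma_variate,
    gamma_variate,
    generate_tic,
    half_auc_time,
    mean_transit_time,
    normalize_tic,
)
from bubbleflow.containers import FrameStack, GammaVariateFit
from bubbleflow.kinetics import first_pass_window


def _fit_for(alpha, beta, A=1.0, t0=0.0):
    return GammaVariateFit(A=A, alpha=alpha, beta=beta, t0=t0, rss=0.0,
                           converged=True)


class TestGammaVariate:
    def test_zero_at_onset(self):
        assert gamma_variate(np.array([3.0]), 1.0, 2.0, 5.0, t0=3.0)[0] == 0.0

    def test_hand_value(self):
        # A=1, alpha=1, beta=1 at t=1: 1 * 1 * e^-1
        val = gamma_variate(np.array([1.0]), 1.0, 1.0, 1.0)[0]
        assert val == pytest.approx(np.exp(-1.0), rel=1e-12)

    @pytest.mark.parametrize("alpha,beta,t0", [(2.0, 5.0, 0.0), (0.7, 3.0, 4.0),
                                               (4.0, 1.5, 10.0)])
    def test_argmax_at_alpha_beta(self, alpha, beta, t0):
        t = np.linspace(t0, t0 + 20 * alpha * beta, 200_001)
        y = gamma_variate(t, 1.0, alpha, beta, t0)
        assert t[np.argmax(y)] == pytest.approx(t0 + alpha * beta,
                                                abs=t[1] - t[0] + 1e-9)


class TestExtractAndNormalize:
    def test_uniform_real_stack(self):
        stack = FrameStack(np.full((5, 4, 4), 3.5), frame_rate=2.0)
        tic = extract_tic(stack, np.ones((4, 4), bool))
        assert np.allclose(tic.intensities, 3.5)

    def test_complex_stack_uses_power(self):
        data = np.full((4, 3, 3), 2.0 + 0.0j)
        tic = extract_tic(FrameStack(data, 1.0), np.ones((3, 3), bool))
        assert np.allclose(tic.intensities, 4.0)

    def test_single_pixel_mask(self, rng):
        data = rng.normal(size=(6, 4, 4))
        mask = np.zeros((4, 4), bool)
        mask[1, 2] = True
        tic = extract_tic(FrameStack(data, 1.0), mask)
        assert np.array_equal(tic.intensities, data[:, 1, 2])

    def test_empty_mask_rejected(self):
        stack = FrameStack(np.ones((3, 2, 2)), 1.0)
        with pytest.raises(InvalidInputError):
            extract_tic(stack, np.zeros((2, 2), bool))

    def test_normalize_is_idempotent_and_scale_invariant(self, default_bolus):
        tic, _ = generate_tic(default_bolus)
        n1 = normalize_tic(tic)
        assert n1.peak == pytest.approx(1.0)
        assert np.array_equal(normalize_tic(n1).intensities, n1.intensities)
        scaled = TimeIntensityCurve(tic.times, 7.0 * tic.intensities)
        assert np.allclose(normalize_tic(scaled).intensities, n1.intensities)

    def test_normalize_zero_curve_rejected(self):
        tic = TimeIntensityCurve(np.arange(10.0), np.zeros(10))
        with pytest.raises(InvalidInputError):
            normalize_tic(tic)


class TestFit:
    def test_noiseless_recovery_exact(self):
        p = BolusParams(A=1.0, alpha=2.0, beta=5.0, t0=0.0)
        tic, _ = generate_tic(p)
        fit = fit_gamma_variate(tic)
        assert fit.converged
        assert fit.A == pytest.approx(1.0, rel=1e-4)
        assert fit.alpha == pytest.approx(2.0, rel=1e-4)
        assert fit.beta == pytest.approx(5.0, rel=1e-4)

    def test_noiseless_recovery_with_onset(self):
        p = BolusParams(A=0.5, alpha=1.5, beta=8.0, t0=12.0)
        tic, _ = generate_tic(p)
        fit = fit_gamma_variate(tic)
        assert fit.converged
        for got, want in [(fit.A, 0.5), (fit.alpha, 1.5), (fit.beta, 8.0),
                          (fit.t0, 12.0)]:
            assert got == pytest.approx(want, rel=1e-4, abs=1e-4)

    def test_noisy_recovery_median_error(self):
        errs = {"alpha": [], "beta": []}
        for seed in range(30):
            p = BolusParams(alpha=2.0, beta=5.0, t0=10.0, noise_sd=0.05,
                            seed=seed)
            tic, _ = generate_tic(p)
            fit = fit_gamma_variate(tic)
            assert fit.converged
            errs["alpha"].append(abs(fit.alpha - 2.0) / 2.0)
            errs["beta"].append(abs(fit.beta - 5.0) / 5.0)
        assert np.median(errs["alpha"]) < 0.10
        assert np.median(errs["beta"]) < 0.10

    def test_all_zero_curve_fails_gracefully(self):
        tic = TimeIntensityCurve(np.arange(20.0), np.zeros(20))
        fit = fit_gamma_variate(tic)
        assert not fit.converged
        assert fit.message

    def test_monotone_decreasing_curve_fails_gracefully(self):
        tic = TimeIntensityCurve(np.arange(20.0), np.linspace(5.0, 0.1, 20))
        fit = fit_gamma_variate(tic)
        assert not fit.converged

    def test_too_few_samples_rejected(self):
        tic = TimeIntensityCurve(np.arange(5.0), np.ones(5))
        with pytest.raises(InvalidInputError):
            fit_gamma_variate(tic)

    def test_scale_equivariance(self, default_bolus):
        p = BolusParams(alpha=2.0, beta=5.0, t0=10.0, noise_sd=0.05, seed=4)
        tic, _ = generate_tic(p)
        f1 = fit_gamma_variate(tic)
        f2 = fit_gamma_variate(
            TimeIntensityCurve(tic.times, 1000.0 * tic.intensities))
        assert f2.A / f1.A == pytest.approx(1000.0, rel=1e-6)
        assert f2.alpha == pytest.approx(f1.alpha, rel=1e-6)
        assert f2.beta == pytest.approx(f1.beta, rel=1e-6)
        assert f2.t0 == pytest.approx(f1.t0, rel=1e-6, abs=1e-9)

    def test_normalization_invariance_of_shape_parameters(self):
        p = BolusParams(alpha=2.0, beta=5.0, t0=10.0, noise_sd=0.03, seed=8)
        tic, _ = generate_tic(p)
        f_raw = fit_gamma_variate(tic)
        f_norm = fit_gamma_variate(normalize_tic(tic))
        p_raw = derive_parameters(f_raw, tic)
        p_norm = derive_parameters(f_norm, normalize_tic(tic))
        for attr in ("mtt", "time_of_arrival", "time_to_peak"):
            assert getattr(p_raw, attr) == pytest.approx(
                getattr(p_norm, attr), rel=1e-6)
        assert f_raw.alpha == pytest.approx(f_norm.alpha, rel=1e-6)
        assert f_raw.beta == pytest.approx(f_norm.beta, rel=1e-6)

    def test_first_pass_window_truncates_after_descent(self):
        p = BolusParams(alpha=2.0, beta=5.0, t0=10.0)
        tic, _ = generate_tic(p)
        short = first_pass_window(tic, descent_fraction=0.25)
        assert short.n_samples < tic.n_samples
        assert short.times[-1] > p.time_to_peak

    def test_estimator_interface(self):
        p = BolusParams(alpha=2.0, beta=5.0, t0=10.0, noise_sd=0.02, seed=1)
        tic, truth = generate_tic(p)
        model = GammaVariateModel().fit(tic.times, tic.intensities)
        assert model.converged_
        assert model.alpha_ == pytest.approx(2.0, rel=0.2)
        pred = model.predict(tic.times)
        assert np.corrcoef(pred, truth)[0, 1] > 0.99
        # sklearn params round-trip
        assert GammaVariateModel(**model.get_params()).get_params() == \
            model.get_params()


class TestDerivedParameters:
    def test_auc_hand_values(self):
        # integral of t e^-t over [0, inf) = Gamma(2) = 1
        assert auc(_fit_for(1.0, 1.0)) == pytest.approx(1.0, rel=1e-12)
        # alpha=2, beta=5: 5^3 * Gamma(3) = 250
        assert auc(_fit_for(2.0, 5.0)) == pytest.approx(250.0, rel=1e-12)

    def test_auc_linear_in_amplitude(self):
        assert auc(_fit_for(2.0, 5.0, A=2.0)) == pytest.approx(
            2.0 * auc(_fit_for(2.0, 5.0)), rel=1e-12)

    @pytest.mark.parametrize("alpha", [0.3, 1.0, 2.0, 4.0, 6.0])
    @pytest.mark.parametrize("beta", [0.5, 5.0, 60.0])
    def test_auc_matches_quadrature(self, alpha, beta):
        closed = auc(_fit_for(alpha, beta))
        numeric, _ = quad(lambda t: gamma_variate(np.array([t]), 1.0, alpha,
                                                  beta)[0],
                          0.0, 50.0 * beta + 50 * alpha * beta, limit=500)
        assert closed == pytest.approx(numeric, rel=5e-3)

    def test_mtt_hand_value(self):
        # median of the unit-scale gamma integral with alpha+1 = 2
        assert mean_transit_time(_fit_for(1.0, 1.0)) == pytest.approx(
            1.6783, abs=1e-3)

    def test_mtt_scales_with_beta(self):
        assert mean_transit_time(_fit_for(2.0, 10.0)) == pytest.approx(
            2.0 * mean_transit_time(_fit_for(2.0, 5.0)), rel=1e-10)

    def test_mtt_increasing_in_alpha(self):
        vals = [mean_transit_time(_fit_for(a, 5.0)) for a in (0.5, 1, 2, 4)]
        assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize("alpha,beta", [(0.5, 2.0), (1.0, 1.0),
                                            (2.0, 5.0), (4.0, 20.0)])
    def test_mtt_matches_grid_inversion_oracle(self, alpha, beta):
        # brute-force inversion of the cumulative trapezoidal integral
        t = np.linspace(0.0, 60.0 * beta * max(alpha, 1.0), 100_001)
        y = gamma_variate(t, 1.0, alpha, beta)
        oracle = half_auc_time(t, y)
        assert mean_transit_time(_fit_for(alpha, beta)) == pytest.approx(
            oracle, abs=1e-3 * beta)

    def test_parameter_example(self):
        p = BolusParams(A=1.0, alpha=2.0, beta=5.0, t0=0.0)
        tic, _ = generate_tic(p)
        fit = fit_gamma_variate(tic)
        params = derive_parameters(fit, tic)
        assert params.time_to_peak == pytest.approx(10.0, rel=1e-3)
        assert params.peak_enhancement == pytest.approx(100.0 * np.exp(-2.0),
                                                        rel=1e-3)
        assert params.wash_in_rate > 0
        assert params.wash_out_rate > 0
        assert params.time_of_arrival <= params.time_to_peak

    def test_wash_rates_match_grid_search(self):
        fit = _fit_for(2.0, 5.0)
        tic, _ = generate_tic(BolusParams(alpha=2.0, beta=5.0))
        params = derive_parameters(fit, tic)
        t = np.linspace(1e-6, tic.times[-1], 400_001)
        slope = np.gradient(gamma_variate(t, 1.0, 2.0, 5.0), t)
        assert params.wash_in_rate == pytest.approx(slope.max(), rel=1e-3)
        assert params.wash_out_rate == pytest.approx(-slope.min(), rel=1e-3)

    def test_non_converged_fit_rejected(self):
        bad = GammaVariateFit(A=float("nan"), alpha=float("nan"),
                              beta=float("nan"), t0=float("nan"), rss=0.0,
                              converged=False)
        tic = TimeIntensityCurve(np.arange(10.0), np.ones(10))
        with pytest.raises(InvalidInputError):
            derive_parameters(bad, tic)


class TestEllipsoidVolume:
    def test_sphere(self):
        assert ellipsoid_volume(2.0, 2.0, 2.0) == pytest.approx(4 * np.pi / 3)

    @given(st.floats(0.1, 50), st.floats(0.1, 50), st.floats(0.1, 50))
    @settings(max_examples=50, deadline=None)
    def test_linearity_in_each_axis(self, a, b, c):
        assert ellipsoid_volume(2 * a, b, c) == pytest.approx(
            2 * ellipsoid_volume(a, b, c), rel=1e-12)

    def test_rejects_nonpositive_axis(self):
        with pytest.raises(InvalidInputError):
            ellipsoid_volume(1.0, 0.0, 2.0)
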