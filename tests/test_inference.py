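"""Absorbance conversion and release-curve fitting."""

import math

import numpy as np
import pytest

from fiberbloom import (
    BeerLambertCalibration,
    FiberGeometry,
    FiberSample,
    ReleaseCurve,
    TransportParameters,
    absorbance_to_moles,
    bloomed_fraction,
    fit_diffusion_coefficient,
    fit_power_law,
    predict_curve,
    release_fraction,
)
from fiberbloom.synth import GeneratorConfig, generate_release_observations

CALIB = BeerLambertCalibration(molar_absorptivity=0.018, path_length_cm=1.0,
                               wavelength_nm=397.0)


class TestBeerLambert:
    def test_blank_reads_zero(self):
        assert absorbance_to_moles(0.0, CALIB, 0.003) == 0.0

    def test_identity_algebra(self):
        # A = eps * 1 M * 1 cm  ->  concentration 1 M in 3 mL
        assert absorbance_to_moles(0.018, CALIB, 0.003) == pytest.approx(3e-3)

    def test_linearity(self):
        one = absorbance_to_moles(0.1, CALIB, 0.003)
        two = absorbance_to_moles(0.2, CALIB, 0.003)
        assert two == pytest.approx(2 * one)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            absorbance_to_moles(-0.1, CALIB, 0.003)
        with pytest.raises(ValueError):
            BeerLambertCalibration(molar_absorptivity=-1.0)


class TestBloomedFraction:
    def sample(self, n_pieces=1):
        return FiberSample(
            geometry=FiberGeometry(radius_cm=0.03, length_cm=2.0),
            loading_wt_frac=0.01,
            density_g_cm3=0.943,
            molar_mass_g_mol=259.3,
            n_pieces=n_pieces,
        )

    def test_zero_moles(self):
        assert bloomed_fraction(0.0, self.sample()) == 0.0

    def test_hand_computed_half_release(self):
        # one 2 cm piece at R = 0.03 cm holds pi R^2 L rho * 1% = 5.33e-5 g
        # of additive = 2.06e-7 mol; half that in solution -> w = 0.5
        s = self.sample()
        assert s.additive_mass_g == pytest.approx(5.33e-5, rel=2e-3)
        assert bloomed_fraction(1.03e-7, s) == pytest.approx(0.5, rel=2e-3)

    def test_scales_inversely_with_pieces(self):
        w1 = bloomed_fraction(5e-8, self.sample(n_pieces=1))
        w4 = bloomed_fraction(5e-8, self.sample(n_pieces=4))
        assert w1 == pytest.approx(4 * w4)

    def test_overshoot_warns_not_raises(self):
        s = self.sample()
        with pytest.warns(UserWarning):
            w = bloomed_fraction(s.additive_moles * 1.2, s)
        assert w == pytest.approx(1.2)


class TestPowerLawFit:
    def test_exact_power_law_recovered_to_machine_precision(self):
        t = np.logspace(1, 5, 12)
        curve = ReleaseCurve(times_s=t, fractions=0.1 * (t / t[0]) ** 0.5 * 0.01)
        # keep w below the cutoff
        curve = ReleaseCurve(times_s=t, fractions=1e-3 * t**0.5)
        fit = fit_power_law(curve)
        assert fit.exponent == pytest.approx(0.5, abs=1e-12)
        assert fit.prefactor == pytest.approx(1e-3, rel=1e-10)
        assert fit.residual_rms < 1e-12

    def test_model_grid_exponent_near_0p447(self):
        """The diffusion-limited series on the standard tau grid bends the
        log-log slope from 0.5 down to ~0.447, bracketing the ~0.44 seen
        in fiber release experiments."""
        taus = 0.002 * 2.0 ** np.arange(8)
        w = np.array([release_fraction(t) for t in taus])
        curve = ReleaseCurve(times_s=taus, fractions=w)  # tau as time unit
        fit = fit_power_law(curve)
        assert fit.exponent == pytest.approx(0.44717, abs=5e-4)

    def test_exponent_regimes(self, geometry, transport):
        # early release only: slope -> 0.5
        t_small = np.linspace(1e3, 1e5, 10)
        fit_small = fit_power_law(predict_curve(transport, geometry, t_small))
        assert fit_small.exponent == pytest.approx(0.5, abs=0.01)
        # across the fitted range w in [0.1, 0.85]: slope in [0.40, 0.48]
        t_wide = np.array([1, 2, 4, 8, 16, 32, 64, 125], float) * 86400.0
        fit_wide = fit_power_law(predict_curve(transport, geometry, t_wide))
        assert 0.40 <= fit_wide.exponent <= 0.48

    def test_high_w_points_never_influence_fit(self, geometry, transport, day_times):
        curve = predict_curve(transport, geometry, day_times)
        extended = ReleaseCurve(
            times_s=np.r_[curve.times_s, 570 * 86400.0],
            fractions=np.r_[curve.fractions, 0.997],
        )
        a = fit_power_law(curve)
        b = fit_power_law(extended)
        assert b.exponent == pytest.approx(a.exponent, abs=1e-12)
        assert b.n_excluded == a.n_excluded + 1

    def test_time_unit_invariance(self, geometry, transport, day_times):
        curve_s = predict_curve(transport, geometry, day_times)
        curve_h = ReleaseCurve(times_s=curve_s.times_s / 3600.0,
                               fractions=curve_s.fractions)
        fs, fh = fit_power_law(curve_s), fit_power_law(curve_h)
        assert fh.exponent == pytest.approx(fs.exponent, abs=1e-9)
        assert fh.prefactor == pytest.approx(fs.prefactor * 3600.0**fs.exponent, rel=1e-6)

    def test_insufficient_points_raise(self):
        curve = ReleaseCurve(times_s=np.array([1.0, 2.0]),
                             fractions=np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            fit_power_law(curve)


class TestDiffusionFit:
    def test_noiseless_recovery_below_point1_percent(self, geometry, transport, day_times):
        curve = predict_curve(transport, geometry, day_times)
        fit = fit_diffusion_coefficient(curve, geometry, mode="series")
        D_true = transport.diffusion_coeff_cm2_s
        assert abs(fit.diffusion_coeff_cm2_s - D_true) / D_true < 1e-3
        assert fit.converged

    def test_sqrt_mode_on_early_data(self, geometry, transport):
        # keep tau below ~1e-3 where the sqrt term dominates the -tau correction
        t = np.linspace(1e3, 2e4, 12)
        curve = predict_curve(transport, geometry, t)
        fit = fit_diffusion_coefficient(curve, geometry, mode="sqrt_term")
        D_true = transport.diffusion_coeff_cm2_s
        # sqrt-term neglects the -tau correction: small positive bias allowed
        assert abs(fit.diffusion_coeff_cm2_s - D_true) / D_true < 0.05

    def test_fit_idempotence(self, geometry, transport, day_times):
        curve = predict_curve(transport, geometry, day_times)
        fit = fit_diffusion_coefficient(curve, geometry)
        refit_params = TransportParameters(
            diffusion_coeff_cm2_s=fit.diffusion_coeff_cm2_s,
            initial_conc_frac=transport.initial_conc_frac,
        )
        pred = predict_curve(refit_params, geometry, day_times)
        keep = curve.fractions < 0.85
        resid = np.abs(pred.fractions - curve.fractions)[keep]
        assert np.all(resid <= fit.residual_rms + 1e-9)

    def test_monte_carlo_bias_below_5_percent(self, geometry, transport, day_times):
        """Relative bias of D-hat under sigma_w = 0.02 observation noise."""
        D_true = transport.diffusion_coeff_cm2_s
        estimates = []
        for rep in range(100):
            cfg = GeneratorConfig(seed=10_000 + rep)
            obs = generate_release_observations(cfg, day_times)
            curve = ReleaseCurve(times_s=day_times,
                                 fractions=obs["fraction_w"].to_numpy())
            fit = fit_diffusion_coefficient(curve, geometry)
            estimates.append(fit.diffusion_coeff_cm2_s)
        median_bias = abs(np.median(estimates) - D_true) / D_true
        assert median_bias < 0.05

    def test_mode_validation(self, geometry, day_times, transport):
        curve = predict_curve(transport, geometry, day_times)
        with pytest.raises(ValueError):
            fit_diffusion_coefficient(curve, geometry, mode="cubic")


class TestPredictCurve:
    def test_time_zero_gives_zero(self, geometry, transport):
        curve = predict_curve(transport, geometry, np.array([0.0]))
        assert curve.fractions[0] == 0.0

    def test_reference_point(self, geometry, transport):
        t = 0.1 * geometry.radius_cm**2 / transport.diffusion_coeff_cm2_s
        curve = predict_curve(transport, geometry, np.array([t]))
        assert curve.fractions[0] == pytest.approx(0.605824, abs=1e-5)

    def test_doubling_D_halves_time_to_fixed_w(self, geometry, transport):
        t = np.array([5e5])
        fast = TransportParameters(
            diffusion_coeff_cm2_s=2 * transport.diffusion_coeff_cm2_s,
            initial_conc_frac=transport.initial_conc_frac,
        )
        w_fast_half_time = predict_curve(fast, geometry, t / 2).fractions[0]
        w_slow_full_time = predict_curve(transport, geometry, t).fractions[0]
        assert w_fast_half_time == pytest.approx(w_slow_full_time, abs=1e-10)

    def test_monotone_output(self, geometry, transport, day_times):
        curve = predict_curve(transport, geometry, day_times)
        assert np.all(np.diff(curve.fractions) >= 0)
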