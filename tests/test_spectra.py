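"""Generalized-Langevin force inference and its spectral conventions."""

import math

import numpy as np
import pytest

from endoforce.core import InvalidParameterError, K_B, Spectrum, Track
from endoforce.motor import force_periodogram, simulate_force
from endoforce.core import MotorModelParams
from endoforce.passive import drag_factors
from endoforce.spectra import (
    LangevinContext,
    average_spectra,
    band_average_ratio,
    fit_force_powerlaw,
    force_spectrum,
    force_spectrum_from_position,
    position_spectrum,
    thermal_force_spectrum,
)
from endoforce.synthetic import simulate_active_track, simulate_newtonian_track

GLYCEROL = 0.619


@pytest.fixture
def newtonian_ctx(glycerol_probe):
    k_par = drag_factors(glycerol_probe).k_parallel
    return LangevinContext(GLYCEROL, 1.0, k_par, 298.0)


class TestPositionSpectrum:
    def test_sinusoid_parseval(self):
        # variance of a sinusoid is a^2/2 = (1/2pi) * integral of S
        a, f0 = 1e-6, 2.0
        t = np.arange(20000) * 0.01
        x = a * np.sin(2 * math.pi * f0 * t)
        track = Track(t, np.column_stack([x, np.zeros_like(x)]))
        spec = position_spectrum(track, axis="x", method="welch",
                                 detrend=False)
        total = np.trapezoid(spec.values, spec.omegas) / (2 * math.pi)
        assert total == pytest.approx(a**2 / 2, rel=0.05)
        peak = spec.omegas[np.argmax(spec.values)]
        assert peak == pytest.approx(2 * math.pi * f0, rel=0.01)

    def test_brownian_track_inverse_square(self, glycerol_probe):
        # S_xx = 4D/omega^2 in the |Re FT of MSD| convention
        k_par = drag_factors(glycerol_probe).k_parallel
        d_coef = K_B * 298.0 / (k_par * GLYCEROL)
        specs = [
            position_spectrum(
                simulate_newtonian_track(glycerol_probe, GLYCEROL, 120.0,
                                         0.01, s), "parallel")
            for s in range(6)
        ]
        spec = average_spectra(specs)
        band = (spec.omegas >= 0.5) & (spec.omegas <= 20)
        ratio = spec.values[band] * spec.omegas[band] ** 2 / (4 * d_coef)
        assert np.mean(ratio) == pytest.approx(1.0, abs=0.1)

    def test_white_noise_parseval_bound(self, rng):
        x = 1e-8 * rng.standard_normal(8192)
        t = np.arange(x.size) * 0.01
        track = Track(t, np.column_stack([x, np.zeros_like(x)]))
        spec = position_spectrum(track, axis="x", method="welch",
                                 detrend="constant")
        total = np.trapezoid(spec.values, spec.omegas) / (2 * math.pi)
        var = float(np.var(x))
        assert total == pytest.approx(var, rel=0.1)
        assert total <= var * 1.05

    def test_rejects_unknown_axis(self, glycerol_probe):
        track = simulate_newtonian_track(glycerol_probe, GLYCEROL, 10.0, 0.01, 0)
        with pytest.raises(ValueError):
            position_spectrum(track, axis="diagonal")


class TestForceSpectrum:
    def test_newtonian_inversion_is_flat_thermal(self, glycerol_probe,
                                                 newtonian_ctx):
        # K^2*eta^2*omega^2 * 4D/omega^2 = 4*k_B*T*K*eta
        expected = 4 * K_B * 298.0 * newtonian_ctx.k_drag * GLYCEROL
        specs = [
            force_spectrum(
                simulate_newtonian_track(glycerol_probe, GLYCEROL, 120.0,
                                         0.01, s), newtonian_ctx, "parallel")
            for s in range(6)
        ]
        spec = average_spectra(specs)
        band = (spec.omegas >= 0.2) & (spec.omegas <= 20)
        assert np.mean(spec.values[band]) == pytest.approx(expected, rel=0.15)
        fit = fit_force_powerlaw(spec, band=(0.2, 20.0))
        assert abs(fit.exponent) < 0.15

    def test_zero_track_zero_spectrum(self, newtonian_ctx):
        t = np.arange(1000) * 0.01
        track = Track(t, np.zeros((1000, 2)))
        spec = force_spectrum(track, newtonian_ctx, "x")
        assert np.all(spec.values == 0.0)

    def test_known_force_round_trip(self, chain2, intact_medium):
        # drive a probe with a known force; the Langevin inversion must give
        # back that force's spectrum on the mid-band
        params = MotorModelParams.from_f_mean(22e-12, 1.5, dt=0.01,
                                              t_on_min=0.01)
        k_par = drag_factors(chain2).k_parallel
        ctx = LangevinContext(intact_medium.G0, intact_medium.alpha, k_par,
                              310.0)
        rec_specs, true_specs = [], []
        for seed in range(5):
            force = simulate_force(params, 200.0, seed)
            track = simulate_active_track(chain2, intact_medium, force)
            rec_specs.append(force_spectrum(track, ctx, "parallel"))
            true_specs.append(force_periodogram(force))
        rec = average_spectra(rec_specs)
        true = average_spectra(true_specs)
        band = (0.5, 10.0)
        mask_r = (rec.omegas >= band[0]) & (rec.omegas <= band[1])
        mask_t = (true.omegas >= band[0]) & (true.omegas <= band[1])
        rec_mean = np.exp(np.mean(np.log(rec.values[mask_r])))
        true_mean = np.exp(np.mean(np.log(true.values[mask_t])))
        assert rec_mean == pytest.approx(true_mean, rel=0.25)


class TestThermalSpectrum:
    def test_newtonian_closed_form(self, newtonian_ctx):
        omegas = np.logspace(-1, 2, 50)
        spec = thermal_force_spectrum(newtonian_ctx, omegas)
        expected = 4 * K_B * 298.0 * newtonian_ctx.k_drag * GLYCEROL
        np.testing.assert_allclose(spec.values, expected, rtol=1e-12)

    def test_powerlaw_equilibrium_exponent(self):
        # gamma_eq = 1 - alpha: alpha = 0.40 gives a -0.60 slope
        ctx = LangevinContext(8.6, 0.40, 1e-5, 310.0)
        omegas = np.logspace(-1, 2, 60)
        spec = thermal_force_spectrum(ctx, omegas)
        fit = fit_force_powerlaw(spec, band=(omegas[0], omegas[-1]),
                                 n_bins=None)
        assert fit.exponent == pytest.approx(-0.60, abs=1e-12)

    def test_doubling_temperature_doubles_spectrum(self):
        omegas = np.logspace(-1, 1, 20)
        lo = thermal_force_spectrum(LangevinContext(8.6, 0.4, 1e-5, 300.0),
                                    omegas)
        hi = thermal_force_spectrum(LangevinContext(8.6, 0.4, 1e-5, 600.0),
                                    omegas)
        np.testing.assert_allclose(hi.values, 2 * lo.values, rtol=1e-12)


class TestForcePowerLawFit:
    def test_exact_recovery(self):
        omegas = np.logspace(-1, 2, 100)
        spec = Spectrum(omegas, 1e-22 * omegas**-1.5, kind="force")
        fit = fit_force_powerlaw(spec, band=(0.1, 100.0))
        assert -fit.exponent == pytest.approx(1.5, abs=1e-10)
        assert fit.prefactor == pytest.approx(1e-22, rel=1e-9)

    def test_needs_enough_points(self):
        omegas = np.array([1.0, 2.0, 3.0, 4.0])
        spec = Spectrum(omegas, omegas**-1.0, kind="force")
        with pytest.raises(InvalidParameterError):
            fit_force_powerlaw(spec, band=(1.0, 4.0))

    def test_band_average_ratio_requires_common_grid(self):
        a = Spectrum(np.array([1.0, 2.0, 3.0, 4.0, 5.0]), np.ones(5))
        b = Spectrum(np.array([1.0, 2.0, 3.0, 4.0, 6.0]), np.ones(5))
        with pytest.raises(InvalidParameterError):
            band_average_ratio(a, b, (1.0, 5.0))
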