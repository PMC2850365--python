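"""Ground-truth recovery and determinism of the synthetic-data generators."""

import math

import numpy as np
import pytest
from scipy import stats

from endoforce.core import (
    ChainProbe,
    FieldProtocol,
    ForceSeries,
    InvalidParameterError,
    K_B,
    MotorModelParams,
    PowerLawMedium,
)
from endoforce.motor import simulate_force
from endoforce.passive import compute_msd, drag_factors, fit_msd_exponent
from endoforce.synthetic import (
    fractional_track,
    simulate_active_track,
    simulate_newtonian_track,
    simulate_oscillation_records,
    simulate_thermal_powerlaw_track,
)

GLYCEROL = 0.619  # Pa·s


class TestNewtonianTracks:
    def test_sphere_diffusion_coefficient(self):
        # 1 µm sphere in glycerol at 298 K: D = k_B*T/(3*pi*eta*d) ~ 7.05e-16
        probe = ChainProbe(1, d_endo=1e-6, temperature=298.0)
        d_expected = K_B * 298.0 / (3 * math.pi * GLYCEROL * 1e-6)
        assert d_expected == pytest.approx(7.05e-16, rel=0.01)
        msds = []
        for seed in range(6):
            track = simulate_newtonian_track(probe, GLYCEROL, 60.0, 0.01, seed)
            msd = compute_msd(track, axis="parallel")
            msds.append(msd.values)
        mean = np.mean(msds, axis=0)
        lags = compute_msd(track, axis="parallel").lags
        fit = np.polyfit(lags[:100], mean[:100], 1)
        assert fit[0] == pytest.approx(2 * d_expected, rel=0.15)

    def test_vanishing_mobility_limit(self):
        probe = ChainProbe(1, d_endo=1e-6, temperature=298.0)
        track = simulate_newtonian_track(probe, 1e6, 1.0, 0.01, seed=0)
        assert np.max(np.abs(track.positions)) < 1e-10

    def test_determinism(self, glycerol_probe):
        a = simulate_newtonian_track(glycerol_probe, GLYCEROL, 10.0, 0.01, 7)
        b = simulate_newtonian_track(glycerol_probe, GLYCEROL, 10.0, 0.01, 7)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_rejects_bad_parameters(self, glycerol_probe):
        with pytest.raises(InvalidParameterError):
            simulate_newtonian_track(glycerol_probe, -1.0, 10.0, 0.01, 0)
        with pytest.raises(InvalidParameterError):
            simulate_newtonian_track(glycerol_probe, 1.0, 0.5, 0.01, 0)

    def test_increments_gaussian_and_uncorrelated(self, glycerol_probe):
        track = simulate_newtonian_track(glycerol_probe, GLYCEROL, 60.0, 0.01, 3)
        incr = np.diff(track.positions[:, 0])
        n = incr.size
        assert stats.normaltest(incr).pvalue > 1e-3
        rho = np.corrcoef(incr[:-1], incr[1:])[0, 1]
        assert abs(rho) < 3.0 / math.sqrt(n)


class TestThermalPowerLawTracks:
    def test_msd_exponent_matches_alpha(self, chain2):
        # average the MSD across tracks before the log-log fit: a per-track
        # fit is downward-biased at long lags (few independent blocks)
        medium = PowerLawMedium(5.0, 0.5)
        curves = [
            compute_msd(simulate_thermal_powerlaw_track(chain2, medium, 60.0,
                                                        0.01, seed), "parallel")
            for seed in range(6)
        ]
        mean = curves[0]
        mean.values = np.mean([c.values for c in curves], axis=0)
        fit = fit_msd_exponent(mean, band=(0.05, 5.0))
        assert fit.exponent == pytest.approx(0.5, abs=0.05)

    def test_viscous_limit_matches_newtonian_statistics(self, glycerol_probe):
        # alpha -> 1 with G0 = eta approaches the Brownian generator
        medium = PowerLawMedium(GLYCEROL, 0.98)
        th_curves, nw_curves = [], []
        for seed in range(6):
            th = simulate_thermal_powerlaw_track(glycerol_probe, medium, 60.0,
                                                 0.01, seed)
            nw = simulate_newtonian_track(glycerol_probe, GLYCEROL, 60.0,
                                          0.01, 100 + seed)
            th_curves.append(compute_msd(th, "parallel"))
            nw_curves.append(compute_msd(nw, "parallel"))
        th_mean, nw_mean = th_curves[0], nw_curves[0]
        th_mean.values = np.mean([c.values for c in th_curves], axis=0)
        nw_mean.values = np.mean([c.values for c in nw_curves], axis=0)
        th_fit = fit_msd_exponent(th_mean)
        nw_fit = fit_msd_exponent(nw_mean)
        assert th_fit.exponent == pytest.approx(nw_fit.exponent, abs=0.1)
        assert th_fit.prefactor == pytest.approx(nw_fit.prefactor, rel=0.3)

    def test_sample_count_and_zero_mean(self, chain2):
        medium = PowerLawMedium(5.0, 0.5)
        track = simulate_thermal_powerlaw_track(chain2, medium, 60.0, 0.01, 1)
        assert len(track) == 6001
        assert np.all(np.isfinite(track.positions))
        incr = np.diff(track.positions[:, 0])
        assert abs(np.mean(incr)) < 3 * np.std(incr) / math.sqrt(incr.size)

    def test_rejects_alpha_out_of_range(self, chain2):
        with pytest.raises(InvalidParameterError):
            simulate_thermal_powerlaw_track(chain2, PowerLawMedium(5.0, 1.0),
                                            10.0, 0.01, 0)

    def test_determinism(self, chain2):
        medium = PowerLawMedium(5.0, 0.5)
        a = simulate_thermal_powerlaw_track(chain2, medium, 10.0, 0.01, 9)
        b = simulate_thermal_powerlaw_track(chain2, medium, 10.0, 0.01, 9)
        np.testing.assert_array_equal(a.positions, b.positions)


class TestActiveTracks:
    def test_zero_force_zero_track(self, chain2, intact_medium):
        n = 1000
        force = ForceSeries(np.arange(n) * 0.01, np.zeros(n))
        track = simulate_active_track(chain2, intact_medium, force)
        np.testing.assert_array_equal(track.positions, 0.0)

    def test_constant_force_newtonian_drift(self, chain2):
        # Stokes drag closed form: speed = F/(K*eta)
        eta = 0.5
        medium = PowerLawMedium(eta, 1.0)
        k_par = drag_factors(chain2).k_parallel
        f0 = 1e-12
        n = 2000
        force = ForceSeries(np.arange(n) * 0.01, np.full(n, f0))
        track = simulate_active_track(chain2, medium, force)
        speed = np.polyfit(track.times, track.positions[:, 0], 1)[0]
        assert speed == pytest.approx(f0 / (k_par * eta), rel=1e-9)
        assert np.max(np.abs(track.positions[:, 1])) == 0.0

    def test_motor_force_gives_superdiffusion(self, chain2, intact_medium):
        # paper condition: F_mean = 22 pN, x = 1.5 in the intact medium
        params = MotorModelParams.from_f_mean(22e-12, 1.5, dt=0.01,
                                              t_on_min=0.01)
        betas = []
        for seed in range(3):
            force = simulate_force(params, 120.0, seed)
            track = simulate_active_track(chain2, intact_medium, force)
            betas.append(fit_msd_exponent(compute_msd(track, "parallel"),
                                          band=(0.05, 5.0)).exponent)
        assert 1.1 <= np.mean(betas) <= 1.5

    def test_thermal_superposition_needs_seed(self, chain2, intact_medium):
        force = ForceSeries(np.arange(500) * 0.01, np.zeros(500))
        with pytest.raises(InvalidParameterError):
            simulate_active_track(chain2, intact_medium, force, thermal=True)


class TestOscillationRecords:
    def test_soft_medium_follows_field(self, chain2):
        medium = PowerLawMedium(1e-12, 0.40)
        records = simulate_oscillation_records(
            chain2, medium, FieldProtocol(0.2, [0.5, 1.0, 5.0]))
        for rec in records:
            assert rec.theta0 == pytest.approx(0.2, rel=1e-6)
            assert rec.delta == pytest.approx(0.0, abs=1e-6)

    def test_rigid_medium_freezes_chain(self, chain2):
        medium = PowerLawMedium(1e9, 0.40)
        records = simulate_oscillation_records(
            chain2, medium, FieldProtocol(0.2, [1.0]))
        assert records[0].theta0 < 1e-6

    def test_zero_moment_rejected(self, intact_medium):
        probe = ChainProbe(2, moment=0.0)
        with pytest.raises(InvalidParameterError):
            simulate_oscillation_records(probe, intact_medium,
                                         FieldProtocol(0.2, [1.0]))

    def test_determinism_with_noise(self, chain2, intact_medium):
        protocol = FieldProtocol(0.2, [0.5, 1.0, 5.0])
        a = simulate_oscillation_records(chain2, intact_medium, protocol,
                                         noise_sd=0.01, seed=4)
        b = simulate_oscillation_records(chain2, intact_medium, protocol,
                                         noise_sd=0.01, seed=4)
        assert a == b


class TestFractionalTracks:
    @pytest.mark.parametrize("beta", [0.4, 0.8, 1.3])
    def test_msd_exponent_recovered(self, beta):
        curves = [
            compute_msd(fractional_track(1e-14, beta, 60.0, 0.01, seed),
                        "parallel")
            for seed in range(6)
        ]
        mean = curves[0]
        mean.values = np.mean([c.values for c in curves], axis=0)
        fit = fit_msd_exponent(mean, band=(0.05, 5.0))
        assert fit.exponent == pytest.approx(beta, abs=0.1)

    def test_msd_prefactor_recovered(self):
        msds = []
        for seed in range(20):
            track = fractional_track(1e-14, 1.3, 30.0, 0.01, seed)
            x = track.positions[:, 0]
            d = x[100:] - x[:-100]  # lag 1 s
            msds.append(np.mean(d * d))
        assert np.mean(msds) == pytest.approx(1e-14, rel=0.15)

    def test_rejects_bad_exponent(self):
        with pytest.raises(InvalidParameterError):
            fractional_track(1e-14, 2.0, 10.0, 0.01, 0)
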