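"""Step-force motor model: a renewal process of square force pulses.

Motors pull the endosome along a microtubule in either direction.  The force
is a sequence of pulses of amplitude ±n·F0 (n motors, normally distributed
around n_mot, rounded and clipped at 1; sign equiprobable), with on-times
drawn from a truncated power law P(t_on) ∝ t_on^(−x) on [t_on_min, t_on_max]
and exponential dwell times (mean tau_off) between pulses.  The averaged FFT
periodogram of this process is a power law S_FF ∝ ω^(−γ) over roughly
2×10⁻²–2×10² Hz, with γ decreasing as x grows (γ ≈ 3 − x for 1 < x < 2).

Fitting an experimental spectrum never nests simulation inside an optimizer:
the slope is mapped to x through a precomputed x→(γ, A) calibration table
(shipped with the package), and F_mean follows from the amplitude since
A ∝ F_mean².
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Tuple

import numpy as np
from scipy import signal

from .core import (
    ForceSeries,
    InvalidParameterError,
    MU_0,
    MotorModelParams,
    PowerLawFit,
    Spectrum,
    fit_loglog,
)

#: Frequency band (Hz) where the simulated spectrum is power-law.
MODEL_BAND_HZ = (2e-2, 2e2)


def sample_durations(x: float, t_min: float, t_max: float, count: int,
                     seed) -> np.ndarray:
    """Draw on-times from the truncated power law P(t) ∝ t^(−x) on
    [t_min, t_max] by inverse-CDF; x = 1 uses the log-uniform limit."""
    if x <= 0:
        raise InvalidParameterError("x must be positive")
    if t_min >= t_max:
        raise InvalidParameterError("t_min must be < t_max")
    if count < 1:
        raise InvalidParameterError("count must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(count)
    if abs(x - 1.0) < 1e-12:
        return t_min * (t_max / t_min) ** u
    a = 1.0 - x
    return (t_min**a + u * (t_max**a - t_min**a)) ** (1.0 / a)


def duration_cdf(t, x: float, t_min: float, t_max: float) -> np.ndarray:
    """Analytic CDF of the truncated power law (oracle for the sampler)."""
    t = np.clip(np.asarray(t, dtype=float), t_min, t_max)
    if abs(x - 1.0) < 1e-12:
        return np.log(t / t_min) / math.log(t_max / t_min)
    a = 1.0 - x
    return (t**a - t_min**a) / (t_max**a - t_min**a)


def sample_dwells(tau_off: float, count: int, seed) -> np.ndarray:
    """Exponential dwell times between pulses (detachment is memoryless)."""
    if tau_off <= 0:
        raise InvalidParameterError("tau_off must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.exponential(tau_off, size=count)


def simulate_force(params: MotorModelParams, duration: float,
                   seed) -> ForceSeries:
    """One realization of the step-force process, sampled at params.dt."""
    if duration < 100 * params.dt:
        raise InvalidParameterError("duration must be >= 100·dt")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_samples = int(round(duration / params.dt))
    values = np.zeros(n_samples)
    # expected cycle length; draw event batches until the window is covered
    pos = 0
    while pos < n_samples:
        batch = max(64, int(1.5 * (n_samples - pos) * params.dt
                            / (0.05 + params.tau_off)))
        t_on = sample_durations(params.x, params.t_on_min, params.t_on_max,
                                batch, rng)
        t_off = sample_dwells(params.tau_off, batch, rng)
        n_motors = np.maximum(
            1, np.rint(rng.normal(params.n_mot, params.sigma_n, batch)))
        amps = np.where(rng.random(batch) < 0.5, -1.0, 1.0) * n_motors * params.f0
        for ton, toff, amp in zip(t_on, t_off, amps):
            end = pos + max(1, int(round(ton / params.dt)))
            values[pos:min(end, n_samples)] = amp
            pos = end + int(round(toff / params.dt))
            if pos >= n_samples:
                break
    times = np.arange(n_samples) * params.dt
    return ForceSeries(times=times, values=values)


def force_periodogram(series: ForceSeries) -> Spectrum:
    """One-sided periodogram of a force series (FT-of-autocorrelation
    convention: the per-Hz PSD read at ω = 2πf)."""
    freqs, psd = signal.periodogram(series.values, fs=1.0 / series.dt,
                                    window="boxcar", detrend=False)
    return Spectrum(omegas=2.0 * math.pi * freqs[1:],
                    values=psd[1:], kind="force",
                    meta={"n_realizations": 1})


def model_spectrum(params: MotorModelParams, duration: float = 200.0,
                   n_realizations: int = 20, seed=0) -> Spectrum:
    """Averaged one-sided force PSD of the step-force process."""
    if n_realizations < 1:
        raise InvalidParameterError("n_realizations must be >= 1")
    seeds = np.random.SeedSequence(seed).spawn(n_realizations)
    total = None
    omegas = None
    for s in seeds:
        series = simulate_force(params, duration, np.random.default_rng(s))
        spec = force_periodogram(series)
        if total is None:
            omegas, total = spec.omegas, spec.values.copy()
        else:
            total += spec.values
    return Spectrum(omegas=omegas, values=total / n_realizations, kind="force",
                    meta={"n_realizations": n_realizations,
                          "duration": duration, "f_mean": params.f_mean,
                          "x": params.x})


def fit_model_spectrum(spectrum: Spectrum,
                       band_hz: Tuple[float, float] = MODEL_BAND_HZ,
                       n_bins: int = 24) -> PowerLawFit:
    """Power-law fit of a simulated spectrum over the model band (Hz)."""
    band = (2.0 * math.pi * band_hz[0], 2.0 * math.pi * band_hz[1])
    return fit_loglog(spectrum.omegas, spectrum.values, band=band,
                      n_bins=n_bins)


@dataclass(frozen=True)
class MotorFit:
    """Motor-model parameters inferred from a force spectrum."""

    f_mean: float
    x: float
    gamma: float
    amplitude: float
    r_squared: float


def load_calibration() -> dict:
    """x→(γ, A) calibration table shipped with the package.

    Built once by brute-force simulation of the model over a grid of x at a
    reference F_mean (see scripts/build_motor_calibration.py); amplitudes
    scale as F_mean², so one reference row per x suffices.
    """
    path = resources.files("endoforce").joinpath("data/motor_calibration.json")
    return json.loads(path.read_text())


def fit_model(spectrum_target: Spectrum,
              band: Optional[Tuple[float, float]] = None,
              calibration: Optional[dict] = None) -> MotorFit:
    """Infer (F_mean, x) of the motor model from a measured force spectrum.

    Two stages: fit (A, γ) of the target in log-log; invert the calibration
    curve γ(x) (monotone decreasing) for x; set F_mean from the amplitude via
    A(x, F_mean) = A_ref(x)·(F_mean/F_ref)².
    """
    cal = calibration if calibration is not None else load_calibration()
    xs = np.asarray(cal["x"], dtype=float)
    gammas = np.asarray(cal["gamma"], dtype=float)
    log_a_ref = np.asarray(cal["log10_amplitude"], dtype=float)
    f_ref = float(cal["f_mean_ref"])
    if band is None:
        band = (2.0 * math.pi * MODEL_BAND_HZ[0],
                2.0 * math.pi * MODEL_BAND_HZ[1])
        lo = max(band[0], float(spectrum_target.omegas[0]))
        hi = min(band[1], float(spectrum_target.omegas[-1]))
        band = (lo, hi)
    fit = fit_loglog(spectrum_target.omegas, spectrum_target.values,
                     band=band, n_bins=24)
    gamma = -fit.exponent
    g_lo, g_hi = float(gammas.min()), float(gammas.max())
    if not g_lo <= gamma <= g_hi:
        raise InvalidParameterError(
            f"target exponent gamma = {gamma:.3f} outside calibrated range "
            f"[{g_lo:.3f}, {g_hi:.3f}]")
    # gamma decreases with x: interpolate on the reversed axis
    order = np.argsort(gammas)
    x_hat = float(np.interp(gamma, gammas[order], xs[order]))
    log_a_at_x = float(np.interp(x_hat, xs, log_a_ref))
    f_mean = f_ref * math.sqrt(fit.prefactor / 10.0**log_a_at_x)
    return MotorFit(f_mean=f_mean, x=x_hat, gamma=gamma,
                    amplitude=fit.prefactor, r_squared=fit.r_squared)


def dipole_contact_force(moment: float, diameter: float) -> float:
    """Cohesive force between two touching coaxial magnetic dipoles,
    F_d = 3µ0·m²/(2π·d⁴) — the force a motor must beat to detach an
    endosome from its chain (~63 pN at default endosome values)."""
    if moment <= 0 or diameter <= 0:
        raise InvalidParameterError("moment and diameter must be positive")
    return 3.0 * MU_0 * moment**2 / (2.0 * math.pi * diameter**4)
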