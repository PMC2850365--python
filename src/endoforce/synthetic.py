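"""Synthetic data with known ground truth.

These generators replace the microscopy videos of the original experiments:
Brownian chains in a Newtonian fluid (calibration), thermal motion in a
power-law medium (equilibrium control), actively driven tracks obtained by
filtering a motor force through the medium's creep response, and
oscillation records of the driven-chain experiment.

Stationary-increment Gaussian tracks with MSD ∝ τ^β are produced as
fractional Brownian motion (Hurst H = β/2) via Davies–Harte circulant
spectral embedding, which gives exact covariance control and is fully
seedable.  The target exponent holds at all lags; estimator bands quoted in
the tests are the ones where a finite-track fit is statistically reliable.
"""

from __future__ import annotations

import math
from typing import List, Optional

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import gamma as gamma_fn

from .core import (
    ChainProbe,
    FieldProtocol,
    ForceSeries,
    InvalidParameterError,
    K_B,
    OscillationRecord,
    PowerLawMedium,
    Track,
)
from .passive import drag_factors, fdt_msd_coefficient

_DEFAULT_AXIS = np.array([1.0, 0.0])


def _fgn(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """n samples of standard fractional Gaussian noise (unit lag-1 variance)
    by Davies–Harte circulant embedding."""
    if not 0.0 < hurst < 1.0:
        raise InvalidParameterError("Hurst exponent must be in (0, 1)")
    if hurst == 0.5:
        return rng.standard_normal(n)
    h2 = 2.0 * hurst
    # pad the embedding until its eigenvalues are non-negative (the minimal
    # circulant can fail for strongly persistent noise, H near 1)
    half = 1 << max(4, int(math.ceil(math.log2(2 * n))))
    while True:
        k = np.arange(half + 1, dtype=float)
        acov = 0.5 * ((k + 1) ** h2 - 2.0 * k**h2 + np.abs(k - 1) ** h2)
        row = np.concatenate([acov, acov[-2:0:-1]])
        eig = np.fft.fft(row).real
        if eig.min() > -1e-9 * eig.max() or half >= (1 << 26):
            break
        half *= 2
    eig = np.clip(eig, 0.0, None)
    m = row.size
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    # real part of the synthesis carries half the circulant variance,
    # hence eig/m rather than eig/(2m)
    w = np.fft.fft(np.sqrt(eig / m) * z)
    return w.real[:n]


def fractional_track(msd_prefactor: float, msd_exponent: float, duration: float,
                     dt: float, seed, axis: Optional[np.ndarray] = None) -> Track:
    """2-D track whose per-axis MSD is ``msd_prefactor``·τ^``msd_exponent``.

    Valid for exponents in (0, 2) (fractional Brownian motion); the two axes
    are independent.  ``msd_prefactor`` is in m²/s^exponent.
    """
    if msd_prefactor <= 0:
        raise InvalidParameterError("msd_prefactor must be positive")
    if not 0.0 < msd_exponent < 2.0:
        raise InvalidParameterError("msd_exponent must be in (0, 2)")
    if dt <= 0 or duration <= 0 or duration / dt < 2:
        raise InvalidParameterError("need duration/dt >= 2 with positive dt")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    scale = math.sqrt(msd_prefactor) * dt ** (msd_exponent / 2.0)
    hurst = msd_exponent / 2.0
    pos = np.zeros((n + 1, 2))
    for j in range(2):
        incr = scale * _fgn(n, hurst, rng)
        pos[1:, j] = np.cumsum(incr)
    times = np.arange(n + 1) * dt
    return Track(times=times, positions=pos,
                 axis=_DEFAULT_AXIS if axis is None else axis)


def simulate_newtonian_track(probe: ChainProbe, viscosity: float,
                             duration: float, dt: float, seed) -> Track:
    """Brownian track in a Newtonian fluid.

    Per-axis diffusion coefficients follow Stokes–Einstein with the probe's
    translational drag factors: D_axis = k_B·T/(K_axis·η).  Parallel motion
    is along the x axis.
    """
    if viscosity <= 0:
        raise InvalidParameterError("viscosity must be positive")
    if dt <= 0 or duration / dt < 100:
        raise InvalidParameterError("need duration/dt >= 100 with positive dt")
    rng = np.random.default_rng(seed)
    drags = drag_factors(probe)
    n = int(round(duration / dt))
    pos = np.zeros((n + 1, 2))
    for j, k_axis in enumerate((drags.k_parallel, drags.k_perpendicular)):
        d_coef = K_B * probe.temperature / (k_axis * viscosity)
        pos[1:, j] = np.cumsum(
            math.sqrt(2.0 * d_coef * dt) * rng.standard_normal(n))
    return Track(times=np.arange(n + 1) * dt, positions=pos, axis=_DEFAULT_AXIS)


def simulate_thermal_powerlaw_track(probe: ChainProbe, medium: PowerLawMedium,
                                    duration: float, dt: float, seed) -> Track:
    """Equilibrium thermal track in a power-law medium (0 < α < 1).

    Each axis is fractional Brownian motion with the FDT mean-square
    displacement 2·k_B·T/(K_axis·G0·Γ(1+α))·τ^α.
    """
    if not 0.0 < medium.alpha < 1.0:
        raise InvalidParameterError("thermal power-law track needs 0 < alpha < 1")
    if dt <= 0 or duration <= 0:
        raise InvalidParameterError("duration and dt must be positive")
    rng = np.random.default_rng(seed)
    drags = drag_factors(probe)
    n = int(round(duration / dt))
    pos = np.zeros((n + 1, 2))
    for j, k_axis in enumerate((drags.k_parallel, drags.k_perpendicular)):
        c = fdt_msd_coefficient(medium.G0, medium.alpha, k_axis,
                                probe.temperature)
        scale = math.sqrt(c) * dt ** (medium.alpha / 2.0)
        pos[1:, j] = np.cumsum(scale * _fgn(n, medium.alpha / 2.0, rng))
    return Track(times=np.arange(n + 1) * dt, positions=pos, axis=_DEFAULT_AXIS)


def _creep_response(force: np.ndarray, dt: float, k_drag: float,
                    medium: PowerLawMedium) -> np.ndarray:
    """Displacement response x(t) = ∫ F(s)·(t−s)^(α−1)/(K·G0·Γ(α)) ds for a
    piecewise-constant force, evaluated exactly per sample."""
    n = force.size
    alpha = medium.alpha
    m = np.arange(n + 1, dtype=float)
    weights = (m[1:] ** alpha - m[:-1] ** alpha) * dt**alpha / (
        k_drag * medium.G0 * gamma_fn(alpha + 1.0))
    x = np.empty(n + 1)
    x[0] = 0.0
    x[1:] = fftconvolve(force, weights)[:n]
    return x


def simulate_active_track(probe: ChainProbe, medium: PowerLawMedium,
                          force: ForceSeries, seed=None,
                          thermal: bool = False) -> Track:
    """Track of a probe driven by a force series through the medium.

    The force acts along the chain axis (transport along one microtubule);
    the displacement is the causal creep response x(ω) = F(ω)/(K_∥·G*(ω)).
    With ``thermal=True`` an independent equilibrium track is superposed on
    both axes (requires a seed and 0 < α < 1).
    """
    if force.dt <= 0:
        raise InvalidParameterError("force series needs positive dt")
    if medium.alpha <= 0.0:
        raise InvalidParameterError("creep response needs alpha > 0")
    drags = drag_factors(probe)
    x_par = _creep_response(force.values, force.dt, drags.k_parallel, medium)
    n = force.values.size
    pos = np.zeros((n + 1, 2))
    pos[:, 0] = x_par
    times = np.arange(n + 1) * force.dt
    if thermal:
        if seed is None:
            raise InvalidParameterError("thermal superposition requires a seed")
        th = simulate_thermal_powerlaw_track(
            probe, medium, duration=n * force.dt, dt=force.dt, seed=seed)
        pos += th.positions[: n + 1]
    return Track(times=times, positions=pos, axis=_DEFAULT_AXIS)


def simulate_oscillation_records(probe: ChainProbe, medium: PowerLawMedium,
                                 protocol: FieldProtocol, noise_sd: float = 0.0,
                                 seed=None) -> List[OscillationRecord]:
    """Oscillation records of a chain driven by a rotating field.

    Small-angle torque balance: the complex response ratio is
    (β0/θ0)·e^{iδ} = 1 + κ·V·G*(ω)/Γ0, inverted exactly by the active
    module.  Optional zero-mean Gaussian noise (sd in radians) is added to
    the chain amplitude and phase.
    """
    from .active import kappa, magnetic_prefactor  # local import avoids a cycle

    gamma0 = magnetic_prefactor(probe)
    kap = kappa(probe.n_endosomes)
    rng = np.random.default_rng(seed) if noise_sd > 0 else None
    records = []
    for f in protocol.frequencies:
        omega = 2.0 * math.pi * f
        ratio = 1.0 + kap * probe.volume * medium.complex_modulus(omega) / gamma0
        theta0 = protocol.beta0 / abs(ratio)
        delta = math.atan2(ratio.imag, ratio.real)
        if rng is not None:
            theta0 = abs(theta0 + noise_sd * rng.standard_normal())
            delta += noise_sd * rng.standard_normal()
        records.append(OscillationRecord(frequency=float(f),
                                         beta0=protocol.beta0,
                                         theta0=float(theta0),
                                         delta=float(delta)))
    return records
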