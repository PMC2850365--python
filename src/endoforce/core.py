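"""Shared domain types for the endosome-microrheology pipeline.

Everything is SI internally: meters, seconds, pascals, newtons, kelvin,
angular frequencies in rad/s.  Hertz appears only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Boltzmann constant (J/K).
K_B = 1.380649e-23
#: Vacuum permeability (T·m/A).
MU_0 = 4.0e-7 * math.pi


class InvalidParameterError(ValueError):
    """Raised when a physical parameter is outside its admissible range."""


@dataclass(frozen=True)
class ChainProbe:
    """A chain of N magnetically loaded endosomes used as a rheological probe.

    Parameters
    ----------
    n_endosomes : int
        Number of endosomes in the chain (N >= 1; torque-balance formulas
        require N >= 2).
    d_endo : float
        Endosome diameter in meters.
    moment : float
        Magnetic moment of a single endosome in A·m².
    temperature : float
        Bath temperature in kelvin.
    """

    n_endosomes: int
    d_endo: float = 0.6e-6
    moment: float = 3.7e-15
    temperature: float = 310.0

    def __post_init__(self) -> None:
        if self.n_endosomes < 1:
            raise InvalidParameterError("n_endosomes must be >= 1")
        if self.d_endo <= 0:
            raise InvalidParameterError("d_endo must be positive")
        if self.moment < 0:
            raise InvalidParameterError("moment must be non-negative")
        if self.temperature <= 0:
            raise InvalidParameterError("temperature must be positive")

    @property
    def volume(self) -> float:
        """Chain volume V = N·(π/6)·d³ in m³."""
        return self.n_endosomes * math.pi / 6.0 * self.d_endo**3


@dataclass(frozen=True)
class PowerLawMedium:
    """Viscoelastic medium with power-law modulus G*(ω) = G0·(iω)^α.

    With this representation |G| = G0·ω^α and the loss angle is constant,
    φ = α·π/2.  α = 1 is a Newtonian fluid of viscosity G0; α = 0 is an
    elastic solid of modulus G0.
    """

    G0: float
    alpha: float

    def __post_init__(self) -> None:
        if self.G0 <= 0:
            raise InvalidParameterError("G0 must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise InvalidParameterError("alpha must lie in [0, 1]")

    def complex_modulus(self, omega):
        """G*(ω) = G0·(iω)^α for ω > 0 (scalar or array)."""
        omega = np.asarray(omega, dtype=float)
        phi = self.alpha * math.pi / 2.0
        return self.G0 * omega**self.alpha * np.exp(1j * phi)

    def magnitude(self, omega):
        return self.G0 * np.asarray(omega, dtype=float) ** self.alpha

    def loss_modulus(self, omega):
        """G″(ω) = G0·ω^α·sin(απ/2)."""
        return self.magnitude(omega) * math.sin(self.alpha * math.pi / 2.0)

    def storage_modulus(self, omega):
        return self.magnitude(omega) * math.cos(self.alpha * math.pi / 2.0)

    @property
    def phase(self) -> float:
        return self.alpha * math.pi / 2.0


@dataclass
class Track:
    """Uniformly sampled 2-D trajectory of a probe's center.

    ``positions`` has shape (n, 2) in meters; ``axis`` is the unit vector of
    the chain direction recorded at the start of the track (used for the
    parallel/perpendicular decomposition).
    """

    times: np.ndarray
    positions: np.ndarray
    axis: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise InvalidParameterError("track needs >= 2 samples")
        if self.positions.shape != (self.times.size, 2):
            raise InvalidParameterError("positions must have shape (n, 2)")
        if not np.all(np.isfinite(self.positions)):
            raise InvalidParameterError("positions must be finite")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if np.ptp(steps) > 1e-9:
            raise InvalidParameterError("sampling must be uniform within 1e-9 s")
        if self.axis is not None:
            self.axis = np.asarray(self.axis, dtype=float)
            norm = float(np.hypot(*self.axis))
            if norm == 0:
                raise InvalidParameterError("axis must be a non-zero vector")
            self.axis = self.axis / norm

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def __len__(self) -> int:
        return self.times.size

    def component(self, axis: str = "parallel") -> np.ndarray:
        """1-D displacement along ``parallel``/``perpendicular``/``x``/``y``."""
        if axis == "x":
            return self.positions[:, 0]
        if axis == "y":
            return self.positions[:, 1]
        u = self.axis if self.axis is not None else np.array([1.0, 0.0])
        if axis == "parallel":
            return self.positions @ u
        if axis == "perpendicular":
            perp = np.array([-u[1], u[0]])
            return self.positions @ perp
        raise ValueError(f"unknown axis {axis!r}")


@dataclass(frozen=True)
class FieldProtocol:
    """Oscillating-field protocol: angular amplitude β0 and drive frequencies."""

    beta0: float
    frequencies: Sequence[float]

    def __post_init__(self) -> None:
        if not 0 < self.beta0 <= 0.5:
            raise InvalidParameterError("beta0 must be in (0, 0.5] rad (small angle)")
        if len(self.frequencies) == 0 or min(self.frequencies) <= 0:
            raise InvalidParameterError("frequencies must be positive")


@dataclass(frozen=True)
class OscillationRecord:
    """One frequency point of the active experiment.

    ``delta`` is the phase lag of the chain behind the field, in radians.
    """

    frequency: float
    beta0: float
    theta0: float
    delta: float

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise InvalidParameterError("frequency must be positive")
        if self.theta0 < 0:
            raise InvalidParameterError("theta0 must be non-negative")
        if abs(self.delta) > math.pi:
            raise InvalidParameterError("|delta| must be <= pi")


@dataclass
class MSDCurve:
    """Time-averaged mean-square displacement ⟨Δr²(τ)⟩ in m²."""

    lags: np.ndarray
    values: np.ndarray
    axis: str = "both"
    n_pairs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.lags) <= 0):
            raise InvalidParameterError("lags must be increasing")
        if np.any(self.values < 0):
            raise InvalidParameterError("MSD values must be non-negative")


@dataclass(frozen=True)
class DragFactors:
    """Translational drag geometry factors (meters): drag = K·η for a
    Newtonian fluid.  For a sphere of diameter a, K = 3πa on both axes."""

    k_parallel: float
    k_perpendicular: float
    source: str = "user"

    def __post_init__(self) -> None:
        if self.k_parallel <= 0 or self.k_perpendicular <= 0:
            raise InvalidParameterError("drag factors must be positive")

    def get(self, axis: str) -> float:
        if axis in ("parallel", "x"):
            return self.k_parallel
        if axis in ("perpendicular", "y"):
            return self.k_perpendicular
        raise ValueError(f"unknown axis {axis!r}")


@dataclass
class Spectrum:
    """One-sided power spectral density on an angular-frequency grid.

    Convention: S(ω) is twice the Fourier transform of the autocovariance
    (the |Re FT of the MSD| convention of microrheology), so the signal
    variance is (1/2π)·∫₀^∞ S(ω) dω.  Position spectra are in m²·s, force
    spectra in N²·s.  A Brownian track has S_xx = 4D/ω² and its thermal
    force spectrum is the flat 4·k_B·T·K·η.
    """

    omegas: np.ndarray
    values: np.ndarray
    kind: str = "position"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.omegas = np.asarray(self.omegas, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.omegas) <= 0):
            raise InvalidParameterError("omegas must be increasing")
        if np.any(self.values < 0):
            raise InvalidParameterError("spectral densities must be non-negative")


@dataclass(frozen=True)
class PowerLawFit:
    """Result of a log-log least-squares fit  value = prefactor·ω^exponent.

    ``prefactor`` is quoted at the abscissa value 1 (ω = 1 rad/s for spectra
    and moduli, τ = 1 s for MSD curves).  For decaying spectra the exponent
    is negative; S = A·ω^(−γ) corresponds to ``exponent = -gamma``.
    """

    prefactor: float
    exponent: float
    band: tuple
    r_squared: float
    n_points: int


@dataclass
class ForceSeries:
    """Uniformly sampled, signed force time series (newtons)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise InvalidParameterError("times and values must match")
        steps = np.diff(self.times)
        if np.any(steps <= 0) or np.ptp(steps) > 1e-12:
            raise InvalidParameterError("force series must be uniformly sampled")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class MotorModelParams:
    """Parameters of the step-force renewal process.

    Pulses of amplitude ±n·F0 (n ~ Normal(n_mot, sigma_n), rounded, >= 1,
    random sign) last t_on drawn from a truncated power law P(t) ∝ t^(−x);
    dwell times between pulses are exponential with mean tau_off.  The mean
    trajectory force is F_mean = n_mot·F0.
    """

    f0: float = 7e-12
    n_mot: float = 3.0
    sigma_n: Optional[float] = None
    x: float = 1.5
    tau_off: float = 0.030
    t_on_min: float = 1e-4
    t_on_max: float = 100.0
    dt: float = 1e-4

    def __post_init__(self) -> None:
        if min(self.f0, self.n_mot, self.x, self.tau_off, self.t_on_min,
               self.t_on_max, self.dt) <= 0:
            raise InvalidParameterError("motor-model parameters must be positive")
        if self.t_on_min >= self.t_on_max:
            raise InvalidParameterError("t_on_min must be < t_on_max")
        if self.dt > self.t_on_min:
            raise InvalidParameterError("dt must be <= t_on_min")
        if self.sigma_n is None:
            object.__setattr__(self, "sigma_n", 0.3 * self.n_mot)
        elif self.sigma_n < 0:
            raise InvalidParameterError("sigma_n must be non-negative")

    @property
    def f_mean(self) -> float:
        return self.n_mot * self.f0

    @classmethod
    def from_f_mean(cls, f_mean: float, x: float, f0: float = 7e-12,
                    **kwargs) -> "MotorModelParams":
        """Build parameters from the trajectory-average force F_mean = n_mot·F0."""
        return cls(f0=f0, n_mot=f_mean / f0, x=x, **kwargs)


def fit_loglog(x, y, band=None, n_bins: Optional[int] = None) -> PowerLawFit:
    """Least-squares power-law fit in log-log coordinates.

    Parameters
    ----------
    x, y : array-like
        Positive abscissa (rad/s or s) and values.
    band : (lo, hi), optional
        Restrict the fit to lo <= x <= hi.
    n_bins : int, optional
        If given, geometric-mean the data in log-spaced bins before fitting.
        On a uniform frequency grid this prevents the dense high-frequency
        end from dominating the regression.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if band is not None:
        mask = (x >= band[0]) & (x <= band[1])
    else:
        mask = np.ones_like(x, dtype=bool)
        band = (float(np.min(x)), float(np.max(x)))
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise InvalidParameterError("need >= 3 points in the fit band")
    if np.any(y <= 0) or np.any(x <= 0):
        raise InvalidParameterError("power-law fit requires positive data")
    lx, ly = np.log(x), np.log(y)
    n_raw = x.size
    if n_bins is not None and n_bins >= 3 and x.size > n_bins:
        edges = np.linspace(lx.min(), lx.max() * (1 + 1e-12), n_bins + 1)
        idx = np.clip(np.digitize(lx, edges) - 1, 0, n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
        keep = counts > 0
        lx = np.bincount(idx, weights=lx, minlength=n_bins)[keep] / counts[keep]
        ly = np.bincount(idx, weights=ly, minlength=n_bins)[keep] / counts[keep]
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(
        prefactor=float(np.exp(intercept)),
        exponent=float(slope),
        band=(float(band[0]), float(band[1])),
        r_squared=max(0.0, min(1.0, r2)),
        n_points=int(n_raw),
    )
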