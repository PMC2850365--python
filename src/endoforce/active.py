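"""Active microrheology: complex shear modulus from chain-oscillation records.

A chain of N magnetic endosomes aligned by a static field oscillates in
response to a small rotating field component β = β0·e^{iωt}.  In the
small-angle (linear) regime the chain angle is θ = θ0·e^{i(ωt−δ)} and the
torque balance gives

    G′(ω) = Γ0/(κV)·(β0/θ0·cos δ − 1),   G″(ω) = Γ0/(κV)·β0/θ0·sin δ,

with Γ0 = (3µ0·m²/4π)·N²/d³ the magnetic torque factor, κ = 2N²/(ln(N/2)
+ 2.4/N) the rotational geometry factor and V the chain volume.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    ChainProbe,
    InvalidParameterError,
    MU_0,
    OscillationRecord,
    PowerLawFit,
    fit_loglog,
)

#: Default fit band of the driven experiment, in Hz.
DEFAULT_ACTIVE_BAND_HZ = (0.2, 20.0)


class UnmeasurablePointError(ValueError):
    """A record cannot be inverted (vanishing chain amplitude)."""


def magnetic_prefactor(probe: ChainProbe) -> float:
    """Magnetic torque factor Γ0 = (3µ0·m²/4π)·N²/d_endo³, in N·m."""
    if probe.n_endosomes < 2:
        raise InvalidParameterError("torque balance requires a chain (N >= 2)")
    if probe.moment <= 0:
        raise InvalidParameterError("magnetic moment must be positive")
    return (3.0 * MU_0 * probe.moment**2 / (4.0 * math.pi)
            * probe.n_endosomes**2 / probe.d_endo**3)


def kappa(n_endosomes: int) -> float:
    """Rotational drag geometry factor κ = 2N²/(ln(N/2) + 2.4/N)."""
    if n_endosomes < 2:
        raise InvalidParameterError("kappa is calibrated for chains (N >= 2)")
    n = n_endosomes
    return 2.0 * n**2 / (math.log(n / 2.0) + 2.4 / n)


def modulus_from_record(record: OscillationRecord,
                        probe: ChainProbe) -> Tuple[float, float]:
    """Invert one oscillation record to (G′, G″) at ω = 2π·frequency.

    Noise can push G′ negative; such points are kept and flagged with a
    warning (|G| stays positive as long as the record is non-degenerate).
    """
    if record.theta0 <= 0:
        raise UnmeasurablePointError(
            f"theta0 = 0 at {record.frequency} Hz: unmeasurable point")
    scale = magnetic_prefactor(probe) / (kappa(probe.n_endosomes) * probe.volume)
    ratio = record.beta0 / record.theta0
    g_prime = scale * (ratio * math.cos(record.delta) - 1.0)
    g_dprime = scale * ratio * math.sin(record.delta)
    if g_prime < -1e-9 * scale * max(ratio, 1.0):  # beyond round-off
        warnings.warn(
            f"negative G' at {record.frequency} Hz (noisy record?)",
            stacklevel=2)
    return g_prime, g_dprime


@dataclass
class ModulusSpectrum:
    """Complex shear modulus sampled on an angular-frequency grid."""

    omegas: np.ndarray
    g_prime: np.ndarray
    g_dprime: np.ndarray

    def __post_init__(self) -> None:
        self.omegas = np.asarray(self.omegas, dtype=float)
        self.g_prime = np.asarray(self.g_prime, dtype=float)
        self.g_dprime = np.asarray(self.g_dprime, dtype=float)

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.g_prime, self.g_dprime)

    @property
    def phase(self) -> np.ndarray:
        return np.arctan2(self.g_dprime, self.g_prime)


def modulus_spectrum(records: Iterable[OscillationRecord],
                     probe: ChainProbe) -> ModulusSpectrum:
    """Invert a set of records into a modulus spectrum, sorted by frequency."""
    recs = sorted(records, key=lambda r: r.frequency)
    if not recs:
        raise InvalidParameterError("no records supplied")
    omegas, gp, gpp = [], [], []
    for rec in recs:
        g1, g2 = modulus_from_record(rec, probe)
        omegas.append(2.0 * math.pi * rec.frequency)
        gp.append(g1)
        gpp.append(g2)
    return ModulusSpectrum(np.array(omegas), np.array(gp), np.array(gpp))


def average_modulus(spectra: Sequence[ModulusSpectrum],
                    method: str = "geometric") -> ModulusSpectrum:
    """Average per-chain modulus spectra sharing one frequency grid.

    The default geometric mean acts on |G| (log-normal-like spread across
    probes) keeping the mean phase; ``arithmetic`` averages G′ and G″
    directly.
    """
    if not spectra:
        raise InvalidParameterError("no spectra to average")
    omegas = spectra[0].omegas
    for s in spectra[1:]:
        if not np.allclose(s.omegas, omegas):
            raise InvalidParameterError("spectra must share a frequency grid")
    if method == "arithmetic":
        gp = np.mean([s.g_prime for s in spectra], axis=0)
        gpp = np.mean([s.g_dprime for s in spectra], axis=0)
        return ModulusSpectrum(omegas, gp, gpp)
    if method != "geometric":
        raise ValueError(f"unknown averaging method {method!r}")
    mags = np.array([s.magnitude for s in spectra])
    if np.any(mags <= 0):
        raise InvalidParameterError("geometric mean needs positive |G|")
    mag = np.exp(np.mean(np.log(mags), axis=0))
    phase = np.mean([s.phase for s in spectra], axis=0)
    return ModulusSpectrum(omegas, mag * np.cos(phase), mag * np.sin(phase))


def fit_powerlaw(omegas, values, band: Optional[Tuple[float, float]] = None,
                 band_hz: Optional[Tuple[float, float]] = None) -> PowerLawFit:
    """Fit |G(ω)| = G0·ω^α by log-log least squares.

    ``band`` is in rad/s; ``band_hz`` is a convenience alias converted with
    ω = 2πf.  The prefactor is quoted at ω = 1 rad/s.
    """
    if band_hz is not None:
        if band is not None:
            raise ValueError("give band or band_hz, not both")
        band = (2.0 * math.pi * band_hz[0], 2.0 * math.pi * band_hz[1])
    return fit_loglog(omegas, values, band=band)


def check_phase_consistency(spectrum: ModulusSpectrum, fit: PowerLawFit,
                            tol: float = 0.1) -> dict:
    """Check the power-law identity φ = α·π/2 against the measured phase.

    Returns the mean measured phase, the value expected from the fitted
    exponent, per-frequency residuals, and a boolean verdict at ``tol`` rad.
    """
    expected = fit.exponent * math.pi / 2.0
    phase = spectrum.phase
    residuals = phase - expected
    mean_phase = float(np.mean(phase))
    return {
        "mean_phase": mean_phase,
        "expected_phase": expected,
        "residuals": residuals,
        "consistent": abs(mean_phase - expected) <= tol,
        "tolerance": tol,
    }


def fit_records(records_per_probe: Sequence[Sequence[OscillationRecord]],
                probes: Sequence[ChainProbe],
                band_hz: Tuple[float, float] = DEFAULT_ACTIVE_BAND_HZ,
                average: str = "geometric") -> Tuple[PowerLawFit, ModulusSpectrum]:
    """Full active pipeline: invert, average across probes, fit |G| = G0·ω^α."""
    spectra: List[ModulusSpectrum] = [
        modulus_spectrum(recs, probe)
        for recs, probe in zip(records_per_probe, probes)
    ]
    mean_spec = average_modulus(spectra, method=average)
    fit = fit_powerlaw(mean_spec.omegas, mean_spec.magnitude, band_hz=band_hz)
    return fit, mean_spec
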