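"""Passive microrheology: MSD estimation, anomalous-exponent fits, and the
equilibrium (fluctuation–dissipation) prediction.

The probe's spontaneous per-axis mean-square displacement in an equilibrium
power-law medium G*(ω) = G0·(iω)^α follows the closed form

    ⟨Δx²(τ)⟩_eq = 2·k_B·T / (K · G0 · Γ(1+α)) · τ^α,

the inverse generalized Stokes–Einstein relation for a pure power law.  The
constant convention is pinned by the Newtonian limit α = 1, G0 = η, where it
must reduce to 2Dτ with D = k_B·T/(K·η).
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import gamma as gamma_fn

from .core import (
    K_B,
    ChainProbe,
    DragFactors,
    InvalidParameterError,
    MSDCurve,
    PowerLawFit,
    Track,
    fit_loglog,
)

#: Default lag band (seconds) for anomalous-exponent fits.
DEFAULT_MSD_BAND = (0.05, 5.0)


def drag_factors(probe: ChainProbe, override: Optional[DragFactors] = None) -> DragFactors:
    """Translational drag factors K_∥, K_⊥ (meters) for a probe.

    N = 1 uses the Stokes sphere value 3π·d on both axes.  For chains the
    default is the short-cylinder (Tirado–García de la Torre) law for a rod
    of length L = N·d and diameter d, whose end corrections stay accurate at
    the low aspect ratios of 2–8-endosome chains:

        K_∥ = 2πL / (ln p + ν_∥),   ν_∥ = −0.207 + 0.980/p − 0.133/p²,
        K_⊥ = 4πL / (ln p + ν_⊥),   ν_⊥ =  0.839 + 0.185/p + 0.233/p²,

    with p = L/d.  If a denominator turns non-positive (degenerate aspect
    ratio), the equal-volume-sphere value is used with a warning.  A
    user-supplied ``override`` is returned verbatim.
    """
    if override is not None:
        return override
    d = probe.d_endo
    n = probe.n_endosomes
    if n == 1:
        k = 3.0 * math.pi * d
        return DragFactors(k, k, source="sphere")
    length = n * d
    p = length / d
    log_p = math.log(p)
    k_par_den = log_p - 0.207 + 0.980 / p - 0.133 / p**2
    k_perp_den = log_p + 0.839 + 0.185 / p + 0.233 / p**2
    if k_par_den <= 0 or k_perp_den <= 0:
        d_eq = d * n ** (1.0 / 3.0)
        warnings.warn(
            "cylinder drag law invalid for this aspect ratio; "
            "falling back to equal-volume sphere",
            stacklevel=2,
        )
        k = 3.0 * math.pi * d_eq
        return DragFactors(k, k, source="sphere")
    return DragFactors(
        2.0 * math.pi * length / k_par_den,
        4.0 * math.pi * length / k_perp_den,
        source="chain-formula",
    )


def compute_msd(track: Track, axis: str = "both",
                max_lag_fraction: float = 0.25) -> MSDCurve:
    """Time-averaged MSD using all overlapping pairs.

    ⟨Δr²(τ)⟩ = ⟨|r(t'+τ) − r(t')|²⟩_t' per requested axis; ``both`` sums the
    two in-plane components.  Lags run from dt up to
    ``max_lag_fraction``·duration.
    """
    n = len(track)
    if n < 10:
        raise InvalidParameterError("need >= 10 samples to estimate an MSD")
    max_lag = max(1, int(max_lag_fraction * (n - 1)))
    if axis == "both":
        comps = [track.component("parallel"), track.component("perpendicular")]
    else:
        comps = [track.component(axis)]
    lags = np.arange(1, max_lag + 1)
    values = np.zeros(max_lag)
    for comp in comps:
        for i, k in enumerate(lags):
            d = comp[k:] - comp[:-k]
            values[i] += float(np.mean(d * d))
    return MSDCurve(
        lags=lags * track.dt,
        values=values,
        axis=axis,
        n_pairs=(n - lags).astype(int),
    )


def fit_msd_exponent(msd: MSDCurve,
                     band: Tuple[float, float] = DEFAULT_MSD_BAND) -> PowerLawFit:
    """Log-log fit ⟨Δr²(τ)⟩ = C·τ^β over a lag band (seconds)."""
    return fit_loglog(msd.lags, msd.values, band=band)


def fdt_msd_prediction(modulus_prefactor: float, modulus_exponent: float,
                       k_drag: float, temperature: float,
                       lags: Sequence[float], axis: str = "parallel") -> MSDCurve:
    """Equilibrium per-axis MSD predicted from the modulus via the FDT.

    For G*(ω) = G0·(iω)^α with 0 < α <= 1 the equilibrium MSD is
    2·k_B·T/(K·G0·Γ(1+α))·τ^α; at α = 1 this is the Stokes–Einstein 2Dτ.
    """
    alpha = modulus_exponent
    if not 0.0 < alpha <= 1.0:
        raise InvalidParameterError("modulus exponent must be in (0, 1]")
    if modulus_prefactor <= 0 or k_drag <= 0 or temperature <= 0:
        raise InvalidParameterError("G0, K and T must be positive")
    lags = np.asarray(lags, dtype=float)
    prefactor = 2.0 * K_B * temperature / (
        k_drag * modulus_prefactor * gamma_fn(1.0 + alpha))
    return MSDCurve(lags=lags, values=prefactor * lags**alpha, axis=axis)


def fdt_msd_coefficient(modulus_prefactor: float, modulus_exponent: float,
                        k_drag: float, temperature: float) -> float:
    """Prefactor C of the equilibrium per-axis MSD C·τ^α (m²/s^α)."""
    curve = fdt_msd_prediction(modulus_prefactor, modulus_exponent, k_drag,
                               temperature, [1.0])
    return float(curve.values[0])


def effective_temperature(msd_measured: MSDCurve,
                          msd_eq: MSDCurve) -> Tuple[np.ndarray, np.ndarray]:
    """Pointwise ratio measured/equilibrium MSD on the common lag support.

    The ratio is the effective temperature in units of the bath temperature:
    1 at equilibrium, ≫ 1 under active driving (growing as τ^(β−α) when the
    measured exponent β exceeds the modulus exponent α).
    """
    lags, ia, ib = np.intersect1d(
        np.round(msd_measured.lags, 12), np.round(msd_eq.lags, 12),
        return_indices=True)
    if lags.size == 0:
        raise InvalidParameterError("no common lag support")
    eq = msd_eq.values[ib]
    if np.any(eq <= 0):
        raise InvalidParameterError("equilibrium MSD must be positive")
    return lags, msd_measured.values[ia] / eq
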