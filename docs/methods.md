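# Methods

This note records the models implemented, the conventions that pin their
constants, the synthetic-data generators and what they do and do not
emulate, and the numerical choices that were genuinely open.

## Probe and media models

A probe is a chain of N endosomes of diameter d (default 0.6 µm) each
carrying a magnetic moment m (default 3.7×10⁻¹⁵ A·m²); its volume is
V = N(π/6)d³.  The surrounding medium is a power-law viscoelastic fluid

    G*(ω) = G₀·(iω)^α ,  0 ≤ α ≤ 1,

so |G| = G₀ω^α and the loss angle is constant, φ = απ/2.  α = 1 is a
Newtonian fluid of viscosity G₀, α = 0 an elastic solid.  G₀ is always
quoted at ω = 1 rad/s; a per-Hz convention would rescale G₀ by (2π)^α but
never α, and the same holds for the force-spectrum amplitude A (factor
(2π)^γ).  Angular frequency is used everywhere internally; Hz appears only
in file headers and CLI flags.

### Torque balance (active arm)

In the small-angle linear regime the complex response of a chain to a
rotating field component β = β₀e^{iωt} is

    (β₀/θ₀)·e^{iδ} = 1 + κV·G*(ω)/Γ₀ ,

with Γ₀ = (3µ₀m²/4π)·N²/d³ and κ = 2N²/(ln(N/2) + 2.4/N).  The inversion
to (G′, G″) is exact; the synthetic record generator is its literal
inverse, which gives the zero-noise round-trip test machine precision.
Negative fitted G′ points (possible under noise) are kept and flagged, not
discarded: |G| stays positive and the log-log fit is unaffected.

Per-chain moduli are computed first and geometric-mean averaged across
probes before fitting (|G| spreads log-normally across probes); an
arithmetic option exists.  Default drive band 0.2–20 Hz.

### Drag factors (passive arm)

Translational drag enters as a geometry factor K (meters): drag = K·η in a
Newtonian fluid.  N = 1 uses the Stokes sphere K = 3πd.  Chains use the
short-cylinder law with Tirado–García de la Torre end corrections for a rod
of length L = Nd, diameter d, aspect ratio p = L/d:

    K_∥ = 2πL/(ln p − 0.207 + 0.980/p − 0.133/p²)
    K_⊥ = 4πL/(ln p + 0.839 + 0.185/p + 0.233/p²)

chosen over the classical slender-body constants because the latter
produce K_⊥ < K_∥ at p = 2–3, the aspect ratios that dominate real chains.
The experimental calibration law for endosome chains is not available to
us, so absolute prefactors of MSDs and force spectra for N ≥ 2 inherit
this model uncertainty; every exponent (α, β, γ) is independent of K.
A user-supplied override is accepted everywhere.

### Equilibrium (FDT) prediction

For a pure power-law medium the inverse generalized Stokes–Einstein
relation has the closed form

    ⟨Δx²(τ)⟩_eq = 2·k_B·T/(K·G₀·Γ(1+α))·τ^α   (per axis),

pinned by the Newtonian limit (α = 1, G₀ = η must give 2Dτ with
D = k_BT/(Kη)).  The effective temperature is the pointwise ratio of the
measured to the equilibrium MSD; for measured exponent β it grows as
τ^(β−α).

### Generalized-Langevin force inference

With inertia neglected (micron probes) the Langevin equation with memory
friction ζ(ω) = K·G*(ω)/(iω) gives

    S_FF(ω) = K²·|G(ω)|²·S_xx(ω),

valid in and out of equilibrium; the thermal reference is
S_FF^eq(ω) = 4·k_B·T·K·G″(ω)/ω ∝ ω^(α−1), so the equilibrium spectrum
exponent is γ_eq = 1 − α.

**Spectral convention.**  All spectra are one-sided densities in the
Fourier-transform-of-autocorrelation convention: variance =
(1/2π)∫₀^∞ S dω, numerically equal to the per-Hz one-sided PSD read at
ω = 2πf.  Two closed forms pin this uniquely: a Brownian track has
S_xx = 4D/ω², and the Newtonian force spectrum is the flat 4·k_B·T·K·η.
Both are verified in the glycerol-style oracle (chains of 1-µm beads in a
η = 0.619 Pa·s fluid at 298 K), where the band-averaged ratio of inferred
to thermal spectrum falls in [0.9, 1.1].  One-sided versus two-sided
choices shift amplitudes by 2; comparisons of absolute spectrum amplitudes
across conventions are only meaningful to such factors, which is why the
motor-model amplitude check carries a factor-3 tolerance while all
exponent checks are tight.

### Step-force motor model

The motor force is a renewal process: pulses of amplitude ±n·F₀ with n
drawn from Normal(n_mot, σ_n), rounded to an integer and clipped at 1,
sign equiprobable per pulse; on-times from a truncated power law
P(t_on) ∝ t_on^(−x) on [0.1 ms, 100 s] (inverse-CDF sampling; x = 1 via
the log-uniform limit); exponential dwells with τ_off = 30 ms.  Defaults:
F₀ = 7 pN (single-motor stall force), dt = 0.1 ms, σ_n = 0.3·n_mot (the
literature does not constrain the motor-number spread; amplitude
statistics are dominated by n_mot and the fitted F_mean shifts by < 10 %
over σ_n ∈ [0, 0.5·n_mot]).  The trajectory-mean force is
F_mean = n_mot·F₀.

The averaged one-sided periodogram of this process is a power law over
2×10⁻²–2×10² Hz with γ decreasing in x (γ ≈ 3 − x for 1 < x < 2).
Fitting an experimental spectrum is a two-stage inverse: γ → x through a
precomputed calibration table (x grid 1.0–2.4, 32 realizations of 200 s
each at a 22 pN reference; `scripts/build_motor_calibration.py`), then
F_mean from the amplitude via A ∝ F_mean².  No stochastic simulation runs
inside an optimizer loop, so fits are deterministic and fast.  The
calibration is reliable for γ roughly in [0.6, 1.9]; outside it the fit
raises with the usable range.

## Synthetic data

* **Newtonian tracks**: independent Gaussian increments per axis with
  D_axis = k_BT/(K_axis·η).
* **Thermal power-law tracks** and generic anomalous tracks: fractional
  Brownian motion (Hurst H = β/2) via Davies–Harte circulant embedding —
  exact covariance control at all lags, seeded, with the embedding padded
  (and doubled if needed) until its eigenvalues are non-negative.  The
  target MSD prefactor for thermal tracks is the FDT coefficient above.
* **Driven tracks**: the causal creep response of the medium to a force
  series, computed exactly for piecewise-constant forces by convolving
  with the integrated kernel t^(α−1)/(K·G₀·Γ(α)); a constant force on a
  Newtonian medium reproduces Stokes drift to round-off.  The force acts
  along the chain axis (transport along one microtubule).
* **Oscillation records**: exact torque-balance response plus optional
  Gaussian angular noise.

Condition presets (intact / microtubules-only / actin-only) carry the
literature triplets (G₀, α) = (8.6, 0.40)/(3.5, 0.56)/(5.7, 0.49) Pa,
β = 1.3/1.2/0.8, and effective temperatures at 1 s of 1000/300/10 bath
units; the intact and microtubule-disrupted magnitudes are reported
values, the intermediate condition is set between them.  Default sampling
is 100 Hz for 60 s (tracking rates of 60–100 fps are both in use; the rate
is a flag, not an assertion).  Temperatures default to 310 K in cells and
298 K for the Newtonian calibration fluid.

What the generators deliberately do not emulate: localization noise
(available as an optional additive term but off by default), rotation of
the chain axis during a track, spatial heterogeneity of the medium,
probe–probe interactions, 3-D motion, and the segmented run/pause
structure of real trafficking (tracks are globally fractional-Gaussian).
Passing tests therefore validate the estimators and inversions under the
stated statistical model, not the biology of any particular cell.

## Estimator choices

* **MSD**: time-averaged over all overlapping pairs, lags up to 1/4 of the
  track.  Exponent fits use unweighted log-log least squares over
  0.05–5 s.  Per-track exponent fits are biased low at long lags (few
  independent blocks); the pipeline averages MSD curves across tracks
  before fitting.
* **Position spectra**: the default estimator pre-whitens by first
  differences and re-colors with |1 − e^{−iωdt}|² = 4 sin²(ωdt/2).
  Increments of the tracks here are nearly white, so leakage bias is
  negligible, whereas a direct periodogram of an ω^(−1.8…−2.4) spectrum
  overestimates its lowest bins and steepens fitted slopes by ~0.05–0.08.
  Constant drift enters only the discarded DC bin.  A tapered Welch
  estimator remains available (`method="welch"`; one full-length segment
  by default so a 60-s track still covers 0.2 rad/s — variance is reduced
  by averaging across tracks, not segments).
* **Power-law fits of dense spectra** are log-binned (24 bins) before
  regression so each decade carries equal weight; fits on sparse
  log-spaced grids (moduli, analytic spectra) are unbinned.  Prefactors
  are quoted at abscissa 1 (rad/s or s).
* **Force-spectrum band**: 0.2–20 rad/s by default, matching the overlap
  of the active (0.2–20 Hz) and passive (0.05–5 s) windows; the modulus
  entering the inversion is the fitted power law, not raw per-frequency
  points, so moderate extrapolation across bands is explicit and smooth.

## Problem sizes

Simulated studies use 30–32 tracks of 60 s at 100 Hz per condition, 6–8
tracks per chain length for the Newtonian oracle, and 20 realizations of
200 s at 10 kHz for motor-model spectra — sizes at which every recovered
exponent is stable to ±0.05 across seeds while a full analysis runs in
minutes on one core.

## Known limitations

* Absolute force scales (F_mean from a measured spectrum) inherit the
  chain drag-factor model and the spectral amplitude convention; they are
  order-of-magnitude robust while exponents are tight.
* The torque balance is linear (small angles); large-angle rheology and
  creep/step protocols are out of scope.
* The Langevin inversion assumes the active and passive measurements probe
  the same location and the same G; the pipeline applies one modulus fit
  to all tracks of a condition.
* `fit_model` identifies (F_mean, x) only through (A, γ); distinct
  microscopic processes with the same power-law spectrum are
  indistinguishable by construction.
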