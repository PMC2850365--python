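"""End-to-end workflow: active fit -> passive fit -> FDT comparison ->
force spectrum -> motor-model fit, plus the synthetic demo dataset.

Condition presets carry the literature values used as synthetic ground truth
for the three cytoskeleton conditions (intact, microtubules only after actin
disruption, actin only after microtubule disruption).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from . import active, motor, passive, spectra, synthetic
from .core import (
    ChainProbe,
    FieldProtocol,
    InvalidParameterError,
    MSDCurve,
    OscillationRecord,
    PowerLawMedium,
    Track,
)
from .io import fit_to_dict, write_json, write_msd, write_probe, write_records, write_spectrum, write_track
from .spectra import LangevinContext


@dataclass(frozen=True)
class ConditionPreset:
    """Literature truth for one cytoskeleton condition: modulus power law
    (G0 Pa, alpha), MSD exponent beta, force-spectrum exponent gamma, and the
    effective-temperature magnitude at 1 s used by the synthetic generator."""

    label: str
    G0: float
    alpha: float
    beta: float
    gamma: float
    t_eff_at_1s: float


CONDITION_PRESETS = {
    "intact": ConditionPreset("intact", G0=8.6, alpha=0.40, beta=1.3,
                              gamma=1.5, t_eff_at_1s=1000.0),
    "microtubules_only": ConditionPreset("microtubules_only", G0=3.5,
                                         alpha=0.56, beta=1.2, gamma=1.1,
                                         t_eff_at_1s=300.0),
    "actin_only": ConditionPreset("actin_only", G0=5.7, alpha=0.49, beta=0.8,
                                  gamma=0.8, t_eff_at_1s=10.0),
}

DEMO_FREQUENCIES_HZ = (0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0)


@dataclass
class AnalysisConfig:
    """Bands, estimator settings and bookkeeping for one pipeline run."""

    probe: ChainProbe = field(default_factory=lambda: ChainProbe(2))
    active_band_hz: tuple = active.DEFAULT_ACTIVE_BAND_HZ
    passive_band_s: tuple = passive.DEFAULT_MSD_BAND
    spectrum_band_rad_s: tuple = spectra.DEFAULT_SPECTRUM_BAND
    axis: str = "parallel"
    average: str = "geometric"
    seed: int = 0
    condition: Optional[str] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["probe"] = asdict(self.probe)
        return d


def _average_msd(curves: Sequence[MSDCurve]) -> MSDCurve:
    n = min(c.lags.size for c in curves)
    lags = curves[0].lags[:n]
    for c in curves[1:]:
        if not np.allclose(c.lags[:n], lags):
            raise InvalidParameterError("tracks must share a lag grid")
    values = np.mean([c.values[:n] for c in curves], axis=0)
    return MSDCurve(lags=lags, values=values, axis=curves[0].axis)


def run_pipeline(config: AnalysisConfig,
                 tracks: Optional[Sequence[Track]] = None,
                 records: Optional[Sequence[Sequence[OscillationRecord]]] = None,
                 probes: Optional[Sequence[ChainProbe]] = None,
                 out_dir: Optional[Path] = None) -> dict:
    """Run every stage the inputs allow and return one report dict.

    ``records`` is a list of per-probe record sets (``probes`` parallel to
    it; defaults to config.probe for all).  Stage failures are recorded and
    downstream stages are skipped with an explicit status.
    """
    if tracks is None and records is None:
        raise InvalidParameterError("need tracks and/or records")
    report: dict = {"config": config.to_dict(), "stages": {}, "warnings": []}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    modulus_fit = None
    if records:
        probe_list = list(probes) if probes is not None else [config.probe] * len(records)
        try:
            modulus_fit, mean_spec = active.fit_records(
                records, probe_list, band_hz=config.active_band_hz,
                average=config.average)
            phase = active.check_phase_consistency(mean_spec, modulus_fit)
            report["stages"]["active"] = {
                "status": "ok",
                "fit": fit_to_dict(modulus_fit),
                "G0_Pa": modulus_fit.prefactor,
                "alpha": modulus_fit.exponent,
                "mean_phase_rad": phase["mean_phase"],
                "phase_consistent": bool(phase["consistent"]),
            }
        except Exception as exc:
            report["stages"]["active"] = {"status": f"failed: {exc}"}
    else:
        report["stages"]["active"] = {"status": "skipped: no records"}

    msd_fit = None
    mean_msd = None
    if tracks:
        try:
            curves = [passive.compute_msd(t, axis=config.axis) for t in tracks]
            mean_msd = _average_msd(curves)
            msd_fit = passive.fit_msd_exponent(mean_msd, band=config.passive_band_s)
            report["stages"]["passive"] = {
                "status": "ok",
                "fit": fit_to_dict(msd_fit),
                "beta": msd_fit.exponent,
                "n_tracks": len(tracks),
            }
            if out_dir is not None:
                write_msd(mean_msd, out_dir / "msd_mean.csv")
        except Exception as exc:
            report["stages"]["passive"] = {"status": f"failed: {exc}"}
    else:
        report["stages"]["passive"] = {"status": "skipped: no tracks"}

    drags = passive.drag_factors(config.probe)
    k_drag = drags.get(config.axis) if config.axis != "both" else drags.k_parallel

    if modulus_fit is not None and mean_msd is not None and msd_fit is not None:
        try:
            eq = passive.fdt_msd_prediction(
                modulus_fit.prefactor, modulus_fit.exponent, k_drag,
                config.probe.temperature, mean_msd.lags, axis=config.axis)
            if config.axis == "both":
                eq.values = 2.0 * eq.values
            lags, ratio = passive.effective_temperature(mean_msd, eq)
            at_1s = float(np.interp(1.0, lags, ratio))
            report["stages"]["fdt"] = {
                "status": "ok",
                "t_eff_over_t_at_1s": at_1s,
                "beta_minus_alpha": msd_fit.exponent - modulus_fit.exponent,
                "fdt_violated": bool(at_1s > 3.0),
            }
        except Exception as exc:
            report["stages"]["fdt"] = {"status": f"failed: {exc}"}
    else:
        report["stages"]["fdt"] = {"status": "skipped: needs active + passive"}

    force_fit = None
    force_spec = None
    if modulus_fit is not None and tracks:
        try:
            ctx = LangevinContext(modulus_fit.prefactor, modulus_fit.exponent,
                                  k_drag, config.probe.temperature)
            pos_specs = [spectra.position_spectrum(t, axis=config.axis)
                         for t in tracks]
            force_spec = spectra.force_spectrum_from_position(
                spectra.average_spectra(pos_specs), ctx)
            force_fit = spectra.fit_force_powerlaw(
                force_spec, band=config.spectrum_band_rad_s)
            thermal = spectra.thermal_force_spectrum(ctx, force_spec.omegas)
            ratio = spectra.band_average_ratio(force_spec, thermal,
                                               config.spectrum_band_rad_s)
            report["stages"]["force_spectrum"] = {
                "status": "ok",
                "fit": fit_to_dict(force_fit),
                "gamma": -force_fit.exponent,
                "amplitude_N2s": force_fit.prefactor,
                "thermal_ratio": ratio,
            }
            if out_dir is not None:
                write_spectrum(force_spec, out_dir / "force_spectrum.csv")
        except Exception as exc:
            report["stages"]["force_spectrum"] = {"status": f"failed: {exc}"}
    else:
        report["stages"]["force_spectrum"] = {
            "status": "skipped: needs modulus fit + tracks"}

    if force_fit is not None and force_spec is not None:
        try:
            mfit = motor.fit_model(force_spec,
                                   band=config.spectrum_band_rad_s)
            report["stages"]["motor"] = {
                "status": "ok",
                "f_mean_N": mfit.f_mean,
                "f_mean_pN": mfit.f_mean * 1e12,
                "x": mfit.x,
                "n_motors": mfit.f_mean / 7e-12,
            }
        except Exception as exc:
            report["stages"]["motor"] = {"status": f"failed: {exc}"}
    else:
        report["stages"]["motor"] = {"status": "skipped: needs force spectrum"}

    if out_dir is not None:
        write_json(report, out_dir / "report.json", seed=config.seed,
                   config=config.to_dict())
    return report


def make_demo_dataset(out_dir, seed: int = 0) -> dict:
    """Write synthetic tracks + oscillation records for the three cell
    conditions, plus a Newtonian (glycerol-like) calibration set, with a
    ground-truth sidecar.  Returns the ground-truth dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root_seq = np.random.SeedSequence(seed)
    truth: dict = {"seed": seed, "conditions": {}}

    protocol = FieldProtocol(beta0=0.2, frequencies=DEMO_FREQUENCIES_HZ)
    for preset, cond_seq in zip(CONDITION_PRESETS.values(), root_seq.spawn(3)):
        cdir = out_dir / preset.label
        cdir.mkdir(exist_ok=True)
        medium = PowerLawMedium(preset.G0, preset.alpha)
        probes = [ChainProbe(n) for n in (2, 3, 4, 5, 6)]
        rec_seeds, track_seeds = cond_seq.spawn(2)
        for i, (probe, rs) in enumerate(zip(probes, rec_seeds.spawn(len(probes)))):
            recs = synthetic.simulate_oscillation_records(
                probe, medium, protocol, noise_sd=0.005,
                seed=np.random.default_rng(rs))
            write_records(recs, cdir / f"records_probe{i}.tsv")
            write_probe(probe, cdir / f"probe{i}.json")
        ref_probe = probes[0]
        k_par = passive.drag_factors(ref_probe).k_parallel
        c_eq = passive.fdt_msd_coefficient(preset.G0, preset.alpha, k_par,
                                           ref_probe.temperature)
        c_meas = preset.t_eff_at_1s * c_eq
        for i, ts in enumerate(track_seeds.spawn(10)):
            track = synthetic.fractional_track(
                c_meas, preset.beta, duration=60.0, dt=0.01,
                seed=np.random.default_rng(ts))
            write_track(track, cdir / f"track{i:02d}.tsv")
        truth["conditions"][preset.label] = {
            **asdict(preset), "msd_prefactor_m2": c_meas,
            "n_tracks": 10, "n_probes": len(probes),
        }

    gdir = out_dir / "glycerol"
    gdir.mkdir(exist_ok=True)
    eta = 0.619
    gseq = root_seq.spawn(4)[3]
    for n, ns in zip((1, 2, 3, 4, 5), gseq.spawn(5)):
        probe = ChainProbe(n, d_endo=1e-6, moment=1e-14, temperature=298.0)
        track = synthetic.simulate_newtonian_track(
            probe, eta, duration=60.0, dt=0.01,
            seed=np.random.default_rng(ns))
        write_track(track, gdir / f"track_n{n}.tsv")
        write_probe(probe, gdir / f"probe_n{n}.json")
    truth["glycerol"] = {"viscosity_Pa_s": eta, "temperature_K": 298.0,
                         "bead_diameter_m": 1e-6, "n_values": [1, 2, 3, 4, 5]}

    write_json(truth, out_dir / "ground_truth.json", seed=seed)
    return truth


def simulate_condition_tracks(preset: ConditionPreset, n_tracks: int,
                              duration: float, dt: float, seed,
                              probe: Optional[ChainProbe] = None) -> List[Track]:
    """Seeded batch of measured-MSD tracks for one condition preset."""
    probe = probe or ChainProbe(2)
    k_par = passive.drag_factors(probe).k_parallel
    c_eq = passive.fdt_msd_coefficient(preset.G0, preset.alpha, k_par,
                                       probe.temperature)
    c_meas = preset.t_eff_at_1s * c_eq
    seqs = np.random.SeedSequence(seed).spawn(n_tracks)
    return [synthetic.fractional_track(c_meas, preset.beta, duration, dt,
                                       seed=np.random.default_rng(s))
            for s in seqs]
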