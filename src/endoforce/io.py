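"""File formats: tracks and oscillation records as delimited text, fits and
reports as JSON.  All files are SI (m, s, Pa, N); frequencies in file headers
are Hz and converted at this boundary."""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .core import (
    ChainProbe,
    InvalidParameterError,
    OscillationRecord,
    PowerLawFit,
    Spectrum,
    Track,
    MSDCurve,
)

PathLike = Union[str, Path]

TRACK_COLUMNS = ["time_s", "x_m", "y_m"]
RECORD_COLUMNS = ["freq_hz", "beta0_rad", "theta0_rad", "delta_rad"]


class FileFormatError(ValueError):
    """Malformed input file; the message names the offending row."""


def write_track(track: Track, path: PathLike) -> None:
    """Write one track as TSV (time_s, x_m, y_m[, axis_x, axis_y])."""
    df = pd.DataFrame({
        "time_s": track.times,
        "x_m": track.positions[:, 0],
        "y_m": track.positions[:, 1],
    })
    if track.axis is not None:
        df["axis_x"] = track.axis[0]
        df["axis_y"] = track.axis[1]
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_track(path: PathLike) -> Track:
    """Read one TSV/CSV track; '#' lines are comments."""
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FileFormatError(f"{path}: cannot parse ({exc})") from exc
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing columns {missing}")
    for col in TRACK_COLUMNS:
        bad = np.flatnonzero(~np.isfinite(df[col].to_numpy(dtype=float)))
        if bad.size:
            raise FileFormatError(
                f"{path}: non-finite {col} at data row {int(bad[0]) + 1}")
    times = df["time_s"].to_numpy(dtype=float)
    rev = np.flatnonzero(np.diff(times) <= 0)
    if rev.size:
        raise FileFormatError(
            f"{path}: time not increasing at data row {int(rev[0]) + 2}")
    axis = None
    if "axis_x" in df.columns and "axis_y" in df.columns:
        axis = np.array([df["axis_x"].iloc[0], df["axis_y"].iloc[0]], float)
    try:
        return Track(times=times,
                     positions=df[["x_m", "y_m"]].to_numpy(dtype=float),
                     axis=axis)
    except InvalidParameterError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc


def read_tracks(path: PathLike) -> List[Track]:
    """Read a track file, or every *.tsv track in a directory (sorted)."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("track*.tsv")) + sorted(path.glob("track*.csv"))
        if not files:  # fall back to any delimited file in the directory
            files = sorted(path.glob("*.tsv")) + sorted(path.glob("*.csv"))
        if not files:
            raise FileFormatError(f"{path}: no track files found")
        return [read_track(f) for f in files]
    return [read_track(path)]


def write_records(records: Sequence[OscillationRecord], path: PathLike) -> None:
    pd.DataFrame({
        "freq_hz": [r.frequency for r in records],
        "beta0_rad": [r.beta0 for r in records],
        "theta0_rad": [r.theta0 for r in records],
        "delta_rad": [r.delta for r in records],
    }).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_records(path: PathLike) -> List[OscillationRecord]:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(OscillationRecord(
                frequency=float(row["freq_hz"]), beta0=float(row["beta0_rad"]),
                theta0=float(row["theta0_rad"]), delta=float(row["delta_rad"])))
        except (InvalidParameterError, ValueError) as exc:
            raise FileFormatError(f"{path}: bad record at data row {i + 1}: "
                                  f"{exc}") from exc
    return records


def write_probe(probe: ChainProbe, path: PathLike) -> None:
    Path(path).write_text(json.dumps(asdict(probe), indent=1) + "\n")


def read_probe(path: PathLike) -> ChainProbe:
    return ChainProbe(**json.loads(Path(path).read_text()))


def write_spectrum(spectrum: Spectrum, path: PathLike) -> None:
    col = "s_ff_N2s" if spectrum.kind == "force" else "s_xx_m2s"
    pd.DataFrame({"omega_rad_s": spectrum.omegas, col: spectrum.values}).to_csv(
        path, index=False, float_format="%.12g")


def read_spectrum(path: PathLike, kind: str = "force") -> Spectrum:
    df = pd.read_csv(path, comment="#")
    if "omega_rad_s" not in df.columns or df.shape[1] < 2:
        raise FileFormatError(f"{path}: expected omega_rad_s + value column")
    value_col = [c for c in df.columns if c != "omega_rad_s"][0]
    return Spectrum(omegas=df["omega_rad_s"].to_numpy(float),
                    values=df[value_col].to_numpy(float), kind=kind)


def write_msd(msd: MSDCurve, path: PathLike) -> None:
    pd.DataFrame({"lag_s": msd.lags, "msd_m2": msd.values,
                  "axis": msd.axis}).to_csv(path, index=False,
                                            float_format="%.12g")


def fit_to_dict(fit: PowerLawFit) -> dict:
    return {"prefactor": fit.prefactor, "exponent": fit.exponent,
            "band": list(fit.band), "r_squared": fit.r_squared,
            "n_points": fit.n_points}


def write_json(payload: dict, path: PathLike, seed: Optional[int] = None,
               config: Optional[dict] = None) -> None:
    """Write a JSON artifact stamped with the seed and a config hash."""
    out = dict(payload)
    if seed is not None:
        out["seed"] = seed
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
        out["config_sha256"] = digest
    Path(path).write_text(json.dumps(out, indent=1, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_config(path: PathLike) -> dict:
    """YAML/JSON key-value config."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise FileFormatError(f"{path}: config must be a mapping")
    return data


def parse_band(spec: str) -> tuple:
    """Parse 'lo:hi' into a float pair."""
    try:
        lo, hi = spec.split(":")
        lo, hi = float(lo), float(hi)
    except ValueError as exc:
        raise ValueError(f"band must be 'lo:hi', got {spec!r}") from exc
    if not 0 < lo < hi or not math.isfinite(hi):
        raise ValueError(f"band must satisfy 0 < lo < hi, got {spec!r}")
    return lo, hi
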