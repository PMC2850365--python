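"""Build the x -> (gamma, amplitude) calibration table of the motor model.

Run once to regenerate src/endoforce/data/motor_calibration.json: for each
duration exponent x on a grid, the averaged spectrum of the step-force
process is simulated at a reference F_mean and its power law (A, gamma)
fitted over the model band.  Amplitudes scale as F_mean^2, so a single
reference row per x is enough for the inverse fit.

Usage: python scripts/build_motor_calibration.py [--fast]
"""

import argparse
import json
from pathlib import Path

import numpy as np

from endoforce.core import MotorModelParams
from endoforce.motor import fit_model_spectrum, model_spectrum

F_MEAN_REF = 22e-12
X_GRID = np.round(np.arange(1.0, 2.45, 0.1), 2)
SEED = 20260927


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fast", action="store_true",
                        help="fewer realizations (smoke run, not shipped)")
    parser.add_argument("--out", default=None)
    args = parser.parse_args()
    n_real = 8 if args.fast else 32
    duration = 100.0 if args.fast else 200.0

    rows = {"x": [], "gamma": [], "log10_amplitude": []}
    for i, x in enumerate(X_GRID):
        params = MotorModelParams.from_f_mean(F_MEAN_REF, float(x))
        spec = model_spectrum(params, duration=duration,
                              n_realizations=n_real, seed=SEED + i)
        fit = fit_model_spectrum(spec)
        rows["x"].append(float(x))
        rows["gamma"].append(round(-fit.exponent, 4))
        rows["log10_amplitude"].append(round(float(np.log10(fit.prefactor)), 4))
        print(f"x={x:.1f}  gamma={-fit.exponent:.3f}  "
              f"A={fit.prefactor:.3e}  r2={fit.r_squared:.4f}")

    table = {
        "f_mean_ref": F_MEAN_REF,
        "duration_s": duration,
        "n_realizations": n_real,
        "seed": SEED,
        "band_hz": [2e-2, 2e2],
        **rows,
    }
    out = Path(args.out) if args.out else (
        Path(__file__).resolve().parents[1]
        / "src/endoforce/data/motor_calibration.json")
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(table, indent=1) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
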