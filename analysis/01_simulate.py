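#!/usr/bin/env python
"""Render the synthetic study inputs: calibration strip and test squares.

Writes the raw reflectance strip cube (ENVI), mean white/black reference
spectra (CSV), a four-square multilayer test set, and the exact deposited
ground truth (JSON) under results/sim/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from inkdose.envi import write_envi_cube, write_reference_csv
from inkdose.pipeline import desk_optics, simulate_calibration
from inkdose.synthetic import (
    DepositionModel,
    PrintPattern,
    SpectralModel,
    deposit_mass_field,
    render_cube,
)

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    sim = simulate_calibration(SEED)
    write_envi_cube(OUT / "strip", sim["raw_cube"])
    wl = sim["raw_cube"].wavelengths
    write_reference_csv(OUT / "white.csv", wl, sim["refs"].white.mean(axis=0))
    write_reference_csv(OUT / "black.csv", wl, sim["refs"].black.mean(axis=0))

    truth = {
        "seed": SEED,
        "strip": sim["field"].ground_truth,
        "reference_masses_mg": sim["reference_masses"].tolist(),
        "quantifiable": sim["quantifiable"].tolist(),
        "squares": {},
    }
    optics, smodel, dep = desk_optics(), SpectralModel(), DepositionModel()
    for n_layers in (1, 2, 3, 5):
        field = deposit_mass_field(
            PrintPattern(kind="multilayer_square", n_layers=n_layers),
            dep, seed=SEED + n_layers,
        )
        raw, refs, cube_truth = render_cube(field, optics, smodel,
                                            seed=SEED + 100 + n_layers)
        write_envi_cube(OUT / f"square_{n_layers}layer", raw)
        truth["squares"][str(n_layers)] = {
            "mass_mg": field.ground_truth["mass_mg"],
            "n_drops": field.ground_truth["n_drops"],
        }
        print(f"square {n_layers} layers: deposited "
              f"{field.ground_truth['mass_mg']:.4f} mg, cube {raw.data.shape}")

    (OUT / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    print(f"strip cube {sim['raw_cube'].data.shape}, "
          f"{len(sim['spots'])} spots -> {OUT}")


if __name__ == "__main__":
    main()
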