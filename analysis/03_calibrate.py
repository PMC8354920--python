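#!/usr/bin/env python
"""Build the Raman-stratified SIMPLS calibration from the simulated strip.

Converts the strip to absorbance, preprocesses (1200–1600 nm window, SNV,
order-2/window-35 Savitzky-Golay first derivative), allocates per-pixel
responses from Raman band maps under reference-mass closure, fits SIMPLS
with 5 components, and cross-validates the component count.  Writes the
model bundle and the RMSECV table under results/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np

from inkdose import spectra_core as sc
from inkdose.calibration import assemble_training, cross_validate, stratify_response
from inkdose.config import model_bundle
from inkdose.pipeline import build_calibration, simulate_calibration
from inkdose.preprocess import preprocess_cube

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    sim = simulate_calibration(SEED)
    run = build_calibration(sim, n_components=5)
    print(f"retained {run.diagnostics['n_spots_retained']} spots; "
          f"{run.training_rows} training pixels")
    for exc in run.excluded_spots:
        print(f"  excluded spot {exc['spot']} ({exc['n_drops']} drops): "
              f"{exc['reason']}")

    # assemble the same training matrix once more for the RMSECV scan
    acube = sc.compute_absorbance(sim["raw_cube"], sim["refs"])
    pcube = preprocess_cube(acube, run.cfg)
    cubes, responses, counts = [], [], []
    for j, spot in enumerate(sim["spots"]):
        if spot["n_drops"] < 50 or not sim["quantifiable"][j]:
            continue
        responses.append(stratify_response(
            sim["raman_maps"][j], float(sim["reference_masses"][j]),
            None, clip_negative=False,
        ))
        cubes.append(pcube)
        counts.append(spot["n_drops"])
    X, y, _ = assemble_training(cubes, responses, counts)
    table = cross_validate(X, y, list(range(1, 9)), n_folds=5, seed=SEED)
    table.to_csv(OUT / "rmsecv.csv", index=False)
    best = table.loc[table["rmsecv"].idxmin()]
    print(table.to_string(index=False))
    print(f"RMSECV minimum at {int(best['n_components'])} components "
          f"({best['rmsecv']:.3e} mg/px); model fitted with "
          f"{run.model.n_components}")

    bundle = model_bundle(run.model)
    (OUT / "model.json").write_text(json.dumps(bundle, indent=1))
    print(f"-> {OUT / 'model.json'}, {OUT / 'rmsecv.csv'}")


if __name__ == "__main__":
    main()
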