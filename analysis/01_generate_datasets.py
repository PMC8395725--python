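#!/usr/bin/env python
"""Generate the synthetic measurement bundle for the downstream analyses.

Produces, under results/data/: a uniaxial compression record, an osmotic
mixing-pressure series at the reference interaction parameters, a
three-bead swelling-kinetics family sharing one collective diffusion
coefficient, and a divalent-salt volume-transition scan — each with its
ground truth echoed to JSON.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from gelswell.presets import (
    DEFAULT_SALT_GRID,
    REFERENCE_CHI,
    divalent_bath,
    divalent_chi_ramp,
    pa_gel_params,
)
from gelswell.synthetic import (
    NoiseSpec,
    gen_mixing_series,
    gen_stress_strain,
    gen_swelling_curves,
    gen_transition_dataset,
)

SEED = 2021
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    rec, gt = gen_stress_strain(10e3, noise=NoiseSpec(level=0.01, seed=SEED))
    pd.DataFrame({"lam": rec.lam, "sigma_kPa": rec.sigma / 1e3}).to_csv(
        OUT / "compression.csv", index=False
    )
    (OUT / "ground_truth_compression.json").write_text(gt.to_json(indent=2))

    phi, pi, gt = gen_mixing_series(
        REFERENCE_CHI, np.linspace(0.01, 0.1, 25),
        noise=NoiseSpec(level=0.02, seed=SEED + 1),
    )
    pd.DataFrame({"phi": phi, "pi_mix_kPa": pi / 1e3}).to_csv(
        OUT / "osmotic.csv", index=False
    )
    (OUT / "ground_truth_osmotic.json").write_text(gt.to_json(indent=2))

    curves, gt = gen_swelling_curves(
        dc=3e-11, r_ratio=0.25, radii=[2.5e-4, 3.75e-4, 5.0e-4],
        noise=NoiseSpec(level=0.01, seed=SEED + 2),
    )
    rows = [
        {"bead_id": c.bead_id, "t_s": t, "d_mm": d * 1e3}
        for c in curves
        for t, d in zip(c.t, c.d)
    ]
    pd.DataFrame(rows).to_csv(OUT / "kinetics.csv", index=False)
    pd.DataFrame(
        {"bead_id": [c.bead_id for c in curves],
         "a_mm": [c.radius * 1e3 for c in curves],
         "d0_mm": [c.d0 * 1e3 for c in curves],
         "d_inf_mm": [c.d_inf * 1e3 for c in curves]}
    ).to_csv(OUT / "beads.csv", index=False)
    (OUT / "ground_truth_kinetics.json").write_text(gt.to_json(indent=2))

    data, gt = gen_transition_dataset(
        divalent_chi_ramp, pa_gel_params(), divalent_bath, DEFAULT_SALT_GRID,
        noise=NoiseSpec(level=0.0, seed=SEED + 3),
    )
    pd.DataFrame({"c_salt_mM": data["c_salt"], "phi": data["phi"]}).to_csv(
        OUT / "transition.csv", index=False
    )
    (OUT / "ground_truth_transition.json").write_text(gt.to_json(indent=2))

    print(f"wrote 4 datasets + ground truths to {OUT}")
    print("conditions: G=10 kPa; chi=(0.448, 0.21); Dc=3e-11 m^2/s, R=0.25;")
    print("            divalent chi ramp over", DEFAULT_SALT_GRID[[0, -1]], "mM")


if __name__ == "__main__":
    main()
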