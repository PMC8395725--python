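#!/usr/bin/env python
"""Shear modulus from compression data and its phi^(1/3) concentration law.

Fits sigma = G (Lambda - Lambda^-2) to the generated compression record,
then checks the rubber-elasticity power law G = G0 phi^(1/3) on a modulus
series sampled from the elastic model.  Writes results/modulus.json.
"""

import json
from pathlib import Path

import numpy as np

from gelswell.elasticity import ModulusSeries, fit_power_law, fit_shear_modulus
from gelswell.io import json_dump, load_compression

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rec = load_compression(ROOT / "data" / "compression.csv")[0]
    fit = fit_shear_modulus(rec)
    truth = json.loads((ROOT / "data" / "ground_truth_compression.json").read_text())
    g_true = truth["params"]["G"]
    print(f"shear modulus: {fit.g/1e3:.3f} +- {fit.stderr/1e3:.3f} kPa "
          f"(truth {g_true/1e3:.1f} kPa, {fit.n_used} points)")

    phi = np.geomspace(1e-3, 0.1, 15)
    series = ModulusSeries(phi=phi, g=fit.g / 0.1 ** (1 / 3) * phi ** (1 / 3))
    pl = fit_power_law(series)
    print(f"power law: G = {pl.g0/1e3:.3f} kPa * phi^{pl.exponent:.4f} "
          f"(exponent deviation from 1/3: {pl.exponent_deviation:.2e})")

    json_dump(
        {
            "G_kPa": fit.g / 1e3,
            "stderr_kPa": fit.stderr / 1e3,
            "G_true_kPa": g_true / 1e3,
            "power_law_exponent": pl.exponent,
        },
        ROOT / "modulus.json",
    )


if __name__ == "__main__":
    main()
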