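#!/usr/bin/env python
"""Interaction parameters from the osmotic mixing-pressure series.

Least-squares fit of the Flory-Huggins mixing law to the (phi, Pi_mix)
records, i.e. the workflow that follows Pi_mix = Pi_tot + G once the
swelling pressure and modulus series are in hand.  Writes
results/chi.json.
"""

import json
from pathlib import Path

from gelswell.io import json_dump, load_osmotic
from gelswell.thermo import SolventSpec, fit_chi

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    df = load_osmotic(ROOT / "data" / "osmotic.csv")
    fit = fit_chi(df["phi"].to_numpy(), df["pi_mix"].to_numpy(), SolventSpec())
    truth = json.loads((ROOT / "data" / "ground_truth_osmotic.json").read_text())
    print(
        f"chi0 = {fit.params.chi0:.4f} +- {fit.stderr_chi0:.4f} "
        f"(truth {truth['params']['chi0']})"
    )
    print(
        f"chi1 = {fit.params.chi1:.3f} +- {fit.stderr_chi1:.3f} "
        f"(truth {truth['params']['chi1']})"
    )
    json_dump(
        {
            "chi0": fit.params.chi0,
            "chi1": fit.params.chi1,
            "stderr_chi0": fit.stderr_chi0,
            "stderr_chi1": fit.stderr_chi1,
            "residual_norm_kPa": fit.residual_norm / 1e3,
            "n_points": fit.n_points,
        },
        ROOT / "chi.json",
    )


if __name__ == "__main__":
    main()
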