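#!/usr/bin/env python
"""Ion-induced volume transition along the divalent-salt ramp.

Traces the globally stable swelling branch phi(c_salt) as the interaction
parameters drift with divalent-salt concentration, and locates the
discontinuous swollen -> collapsed jump.  Writes results/transition.json.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gelswell.io import json_dump
from gelswell.presets import divalent_bath, divalent_chi_ramp, pa_gel_params
from gelswell.thermo import transition_scan

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    grid = np.linspace(0.0, 1.0, 41)
    scan = transition_scan(pa_gel_params(), divalent_chi_ramp, divalent_bath, grid)
    print(f"swollen branch: phi = {scan.phi_stable[0]:.4f} at 0 mM divalent salt")
    print(f"collapsed branch: phi = {scan.phi_stable[-1]:.4f} at {grid[-1]:.1f} mM")
    if scan.has_transition:
        i = np.searchsorted(grid, scan.transition_salt)
        print(f"volume transition at {scan.transition_salt:.3f} mM "
              f"(phi jumps {scan.phi_stable[i-1]:.4f} -> {scan.phi_stable[i]:.4f})")
    else:
        print("no transition detected on this ramp")
    pd.DataFrame({"c_salt_mM": grid, "phi": scan.phi_stable}).to_csv(
        ROOT / "transition_branch.csv", index=False
    )
    json_dump(
        {
            "transition_salt_mM": scan.transition_salt,
            "phi_swollen": float(scan.phi_stable[0]),
            "phi_collapsed": float(scan.phi_stable[-1]),
        },
        ROOT / "transition.json",
    )


if __name__ == "__main__":
    main()
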