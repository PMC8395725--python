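"""Reference parameter sets for a polyacrylate-like model gel.

These presets define the synthetic study conditions used throughout the
analysis scripts and tests: a weakly charged anionic network swollen in
40 mM NaCl at 25 C, whose interaction parameters drift with added
divalent salt — the second-order parameter weakly, the third-order one
strongly — carrying the system across the multi-root region of the
swelling-pressure equation and producing the discontinuous volume
transition at sub-mM divalent concentrations.

The numbers are model choices on laboratory scales, not measurements:
chi0 = 0.448 and chi1 = 0.21 at zero divalent salt (the 40 mM NaCl fit
values), shear-modulus prefactor 10 kPa, effective ionization 0.02
(counter-ion condensation leaves only a small effective fixed charge),
acrylate-like monomer molar volume 6e-5 m^3/mol.
"""

from __future__ import annotations

import numpy as np

from .thermo import (
    ElasticParams,
    FloryHugginsParams,
    GelThermoParams,
    IonicBath,
    SolventSpec,
)

__all__ = [
    "REFERENCE_CHI",
    "pa_gel_params",
    "divalent_chi_ramp",
    "monovalent_chi_flat",
    "divalent_bath",
    "DEFAULT_SALT_GRID",
]

#: Interaction parameters of the reference gel in 40 mM NaCl.
REFERENCE_CHI = FloryHugginsParams(chi0=0.448, chi1=0.21)


def pa_gel_params(
    chi: FloryHugginsParams = REFERENCE_CHI,
    g0: float = 10e3,
    fixed_charge_per_monomer: float = 0.02,
    monomer_molar_volume: float = 6.0e-5,
    solvent: SolventSpec | None = None,
) -> GelThermoParams:
    """Reference polyacrylate-like gel parameter set."""
    return GelThermoParams(
        fh=chi,
        elastic=ElasticParams(g0=g0),
        solvent=solvent or SolventSpec(),
        fixed_charge_per_monomer=fixed_charge_per_monomer,
        monomer_molar_volume=monomer_molar_volume,
    )


def divalent_chi_ramp(c_divalent: float) -> FloryHugginsParams:
    """Interaction parameters vs divalent-salt concentration (mol/m^3).

    Saturating ramps emulating the observed trend: chi0 rises weakly
    (0.448 -> 0.508), chi1 strongly (0.21 -> 0.66), with half-saturation
    at 0.3 mol/m^3.  This carries the gel across the multi-root region,
    so the stable swelling branch jumps near 0.7 mol/m^3 divalent salt.
    """
    s = c_divalent / (c_divalent + 0.3)
    return FloryHugginsParams(chi0=0.448 + 0.06 * s, chi1=0.21 + 0.45 * s)


def monovalent_chi_flat(c_salt: float) -> FloryHugginsParams:
    """Monovalent-style condition: interaction parameters do not drift."""
    return REFERENCE_CHI


def divalent_bath(c_divalent: float, c_monovalent: float = 40.0) -> IonicBath:
    """40 mM NaCl background plus the given CaCl2-like divalent salt (mol/m^3)."""
    if c_divalent == 0.0:
        return IonicBath.monovalent(c_monovalent)
    return IonicBath.with_divalent(c_monovalent, c_divalent)


#: Divalent-salt grid (mol/m^3 = mM) spanning the synthetic transition.
DEFAULT_SALT_GRID = np.linspace(0.0, 1.0, 21)
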