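"""Synthetic measurement generators with known ground truth.

Every record type the analysis consumes — uniaxial compression series,
osmotic deswelling series, bead swelling-kinetics curves, volume-transition
scans — can be generated from the forward models with chosen parameters
and controlled Gaussian noise, so each fitting stage is testable as a
closed loop: generator -> fitter -> ground truth.

Noise defaults emulate plausible instrument scales (1% relative on
diameters, 2% on pressures, 0.5% on deformation ratios); they are
configurable and echoed in the :class:`GroundTruth` bundle serialized
alongside every dataset.  Identical seeds reproduce identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Callable, Sequence

import numpy as np

from .elasticity import StressStrainRecord
from .kinetics import SwellingCurve, pure_diffusion_modes, model_diameter
from .sphere_modes import SphereModeRelation
from .thermo import (
    FloryHugginsParams,
    GelThermoParams,
    IonicBath,
    SolventSpec,
    mixing_pressure,
    stable_phi,
    transition_scan,
)

__all__ = [
    "NoiseSpec",
    "GroundTruth",
    "gen_stress_strain",
    "gen_mixing_series",
    "gen_osmotic_series",
    "gen_swelling_curves",
    "gen_transition_dataset",
    "DEFAULT_LAMBDA_GRID",
]

#: Default compression grid: the instrument window 0.7 <= Lambda <= 1, 30 points.
DEFAULT_LAMBDA_GRID = np.linspace(0.7, 1.0, 30)


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian measurement noise: relative to each value or absolute."""

    kind: str = "gaussian-relative"
    level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian-relative", "gaussian-absolute"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.level < 0:
            raise ValueError(f"noise level must be >= 0, got {self.level}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.level == 0.0:
            return values.copy()
        eps = rng.standard_normal(values.shape)
        if self.kind == "gaussian-relative":
            return values * (1.0 + self.level * eps)
        return values + self.level * eps


@dataclass(frozen=True)
class GroundTruth:
    """Full echo of every parameter used by a generator."""

    generator: str
    params: dict

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {"generator": self.generator, "params": self.params},
            default=_jsonable,
            **kwargs,
        )


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    return str(obj)


# --------------------------------------------------------------------------


def gen_stress_strain(
    g: float,
    lam_grid: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[StressStrainRecord, GroundTruth]:
    """Uniaxial compression record sigma = G (Lam - Lam^-2) + noise."""
    lam = DEFAULT_LAMBDA_GRID.copy() if lam_grid is None else np.asarray(lam_grid, float)
    if np.any(lam <= 0) or np.any(lam > 1):
        raise ValueError("lam_grid must lie in (0, 1]")
    rng = noise.rng()
    sigma = g * (lam - lam**-2)
    sigma = noise.apply(sigma, rng)
    rec = StressStrainRecord(lam=lam, sigma=sigma)
    gt = GroundTruth("stress_strain", {"G": g, "lam_grid": lam, "noise": asdict(noise)})
    return rec, gt


def gen_mixing_series(
    fh: FloryHugginsParams,
    phi_grid: np.ndarray,
    solvent: SolventSpec | None = None,
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Osmotic mixing-pressure series Pi_mix(phi) straight from the mixing law.

    Returns (phi, pi_mix, ground_truth); the noiseless series is exactly
    invertible by the chi fit.
    """
    solvent = solvent or SolventSpec()
    phi = np.asarray(phi_grid, dtype=float)
    rng = noise.rng()
    pi = mixing_pressure(phi, fh, solvent)
    pi = noise.apply(pi, rng)
    gt = GroundTruth(
        "mixing_series",
        {"chi0": fh.chi0, "chi1": fh.chi1, "solvent": asdict(solvent),
         "phi_grid": phi, "noise": asdict(noise)},
    )
    return phi, pi, gt


def gen_osmotic_series(
    params: GelThermoParams,
    pressure_grid: Sequence[float],
    bath: IonicBath | None = None,
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[dict, GroundTruth]:
    """Osmotic-deswelling series: equilibrate the gel against each external
    pressure and record (phi, Pi_tot, G, Pi_mix).

    Emulates the osmotic-stress protocol: the gel's swelling pressure equals
    the imposed external osmotic pressure at equilibrium.  ``Pi_mix`` is the
    true mixing pressure at the equilibrium phi; the measured-workflow
    estimate ``Pi_tot + G`` can be formed from the other columns.  Noise
    (if any) applies to phi and to the pressures/moduli.
    """
    pressures = np.asarray(pressure_grid, dtype=float)
    if np.any(pressures < 0):
        raise ValueError("external pressures must be >= 0")
    rng = noise.rng()
    phis = np.empty_like(pressures)
    for k, p in enumerate(pressures):
        try:
            phis[k] = stable_phi(params, bath, float(p))
        except Exception as exc:
            raise RuntimeError(
                f"no equilibrium at external pressure {p} Pa"
            ) from exc
    g = params.elastic.shear_modulus(phis)
    pi_mix = mixing_pressure(phis, params.fh, params.solvent)
    data = {
        "phi": noise.apply(phis, rng),
        "pi_tot": noise.apply(pressures, rng),
        "G": noise.apply(g, rng),
        "pi_mix": noise.apply(pi_mix, rng),
    }
    gt = GroundTruth(
        "osmotic_series",
        {
            "chi0": params.fh.chi0,
            "chi1": params.fh.chi1,
            "g0": params.elastic.g0,
            "fixed_charge_per_monomer": params.fixed_charge_per_monomer,
            "monomer_molar_volume": params.monomer_molar_volume,
            "pressure_grid": pressures,
            "phi_equilibrium": phis,
            "noise": asdict(noise),
        },
    )
    return data, gt


def gen_swelling_curves(
    dc: float,
    r_ratio: float,
    radii: Sequence[float],
    d_ratio: float = 1.6,
    t_grid: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(kind="gaussian-relative", level=0.01),
    n_modes: int = 50,
    n_t: int = 600,
    t_max_factor: float = 4.0,
    d_inf_known: bool = True,
) -> tuple[list[SwellingCurve], GroundTruth]:
    """Family of bead swelling curves sharing one D_c and one G/M_os.

    Per bead of radius a: tau_1 = a^2 / (beta_1^2 D_c) with (beta_1, B_1)
    from the spherical mode relation at modulus ratio ``r_ratio``; the
    pure-diffusion case (r_ratio = 0) uses the first ``n_modes`` modes,
    otherwise the single slowest mode.  ``d_ratio`` = d_inf/d0 > 1 swells,
    < 1 shrinks.  Default sampling emulates video time-lapse microscopy:
    each bead followed on its own clock, ``n_t`` frames to
    ``t_max_factor`` times its tau_1; ``d_inf_known`` records the
    separately equilibrated final diameter on the curve (the usual
    protocol), otherwise the fit must estimate the plateau.
    """
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("all radii must be > 0")
    rel = SphereModeRelation()
    beta1 = rel.beta1(r_ratio) if r_ratio > 0 else np.pi
    b1 = rel.b1(r_ratio)
    taus = radii**2 / (beta1**2 * dc)
    rng = noise.rng()
    curves = []
    for a, tau1 in zip(radii, taus):
        t = (
            t_grid.copy()
            if t_grid is not None
            else np.linspace(0.0, t_max_factor * tau1, n_t)
        )
        d0 = 2.0 * a
        d_inf = d_ratio * d0
        if r_ratio == 0:
            modes = pure_diffusion_modes(tau1, n_modes)
        else:
            modes = [(b1, tau1)]
        d = model_diameter(t, d0, d_inf, modes)
        d = noise.apply(d, rng)
        curves.append(
            SwellingCurve(
                t=t, d=d, d0=d0, d_inf=d_inf if d_inf_known else None,
                bead_id=f"a={a:g}", radius=float(a),
            )
        )
    gt = GroundTruth(
        "swelling_curves",
        {
            "Dc": dc,
            "R": r_ratio,
            "B1": b1,
            "beta1": beta1,
            "radii": radii,
            "tau1": taus,
            "d_ratio": d_ratio,
            "n_modes": 1 if r_ratio else n_modes,
            "noise": asdict(noise),
        },
    )
    return curves, gt


def gen_transition_dataset(
    chi_of_salt: Callable[[float], FloryHugginsParams],
    params_base: GelThermoParams,
    bath_of_salt: Callable[[float], IonicBath | None],
    salt_grid: Sequence[float],
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[dict, GroundTruth]:
    """Equilibrium phi(c_salt) records along a salt ramp.

    The stable branch comes from the transition scan; when ``chi_of_salt``
    carries the third-order parameter across the multi-root region the
    noiseless series shows the discontinuous swollen -> collapsed jump.
    """
    scan = transition_scan(params_base, chi_of_salt, bath_of_salt, salt_grid)
    rng = noise.rng()
    data = {
        "c_salt": scan.salt_grid.copy(),
        "phi": noise.apply(scan.phi_stable, rng),
    }
    gt = GroundTruth(
        "transition_dataset",
        {
            "salt_grid": scan.salt_grid,
            "phi_stable": scan.phi_stable,
            "transition_salt": scan.transition_salt,
            "chi_table": {
                f"{c:g}": asdict(chi_of_salt(float(c))) for c in scan.salt_grid
            },
            "noise": asdict(noise),
        },
    )
    return data, gt
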