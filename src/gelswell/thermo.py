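"""Swelling-pressure thermodynamics of polyelectrolyte gels.

The swelling pressure of a charged gel in an ionic bath decomposes into
three additive contributions,

    Pi_tot(phi) = Pi_mix(phi) + Pi_el(phi) + Pi_ion(phi),

where ``phi`` is the polymer volume fraction.  ``Pi_mix`` is the
Flory-Huggins mixing pressure with second- and third-order interaction
parameters (chi0, chi1), ``Pi_el = -G`` is the rubber-elastic pressure
(equal to minus the shear modulus), and ``Pi_ion`` is the ideal-Donnan
osmotic pressure of the mobile ions partitioned between gel and bath.

At free swelling ``Pi_tot = 0``; under osmotic deswelling ``Pi_tot``
equals the externally applied osmotic pressure.  When the third-order
interaction parameter grows with added multivalent salt, ``Pi_tot`` can
develop multiple roots and the equilibrium volume fraction jumps
discontinuously: the ion-induced volume phase transition.

All quantities are SI internally: Pa, mol/m^3, K, m^3/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "GAS_CONSTANT",
    "SolventSpec",
    "FloryHugginsParams",
    "ElasticParams",
    "IonSpecies",
    "IonicBath",
    "GelThermoParams",
    "PressureBreakdown",
    "ChiFitResult",
    "EquilibriumRoot",
    "TransitionScanResult",
    "mixing_pressure",
    "elastic_pressure",
    "donnan_ratio",
    "donnan_partition",
    "ionic_pressure",
    "swelling_pressure",
    "mixing_from_total",
    "equilibrium_phi",
    "stable_phi",
    "transition_scan",
    "fit_chi",
    "WATER_MOLAR_VOLUME",
]

#: Molar gas constant R, J/(mol K) (CODATA, exact).
GAS_CONSTANT = 8.314462618

#: Molar volume of liquid water near 25 C, m^3/mol.  Configurable through
#: :class:`SolventSpec`; this default is a documented convention.
WATER_MOLAR_VOLUME = 1.8e-5


# --------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class SolventSpec:
    """Solvent constants entering the mixing and ionic pressures.

    Parameters
    ----------
    molar_volume
        Molar volume V1 of the solvent, m^3/mol.
    temperature
        Absolute temperature T, K.
    gas_constant
        Molar gas constant R, J/(mol K).  Exposed only so the physical
        constant is visible, not meant to be changed.
    """

    molar_volume: float = WATER_MOLAR_VOLUME
    temperature: float = 298.15
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        if not self.molar_volume > 0:
            raise ValueError(f"molar_volume must be > 0, got {self.molar_volume}")
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")

    @property
    def rt(self) -> float:
        """R*T, J/mol."""
        return self.gas_constant * self.temperature


@dataclass(frozen=True)
class FloryHugginsParams:
    """Second- and third-order polymer-solvent interaction parameters."""

    chi0: float
    chi1: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.chi0) and np.isfinite(self.chi1)):
            raise ValueError(f"chi parameters must be finite, got ({self.chi0}, {self.chi1})")


@dataclass(frozen=True)
class ElasticParams:
    """Rubber-elasticity prefactor G0 of the modulus law G = G0 * phi^(1/3).

    G0 = A*R*T*nu where A is the junction-topology factor and nu the molar
    concentration of elastic chains.  Either supply ``g0`` directly (the
    normal route) or supply ``a_factor``, ``nu`` and ``temperature`` and let
    the prefactor be derived.
    """

    g0: float
    a_factor: float | None = None
    nu: float | None = None
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if not self.g0 > 0:
            raise ValueError(f"g0 must be > 0, got {self.g0}")
        if self.a_factor is not None and self.nu is not None:
            derived = self.a_factor * GAS_CONSTANT * self.temperature * self.nu
            if abs(derived - self.g0) > 1e-12 * max(abs(derived), abs(self.g0)):
                raise ValueError(
                    f"inconsistent elastic prefactor: g0={self.g0} but "
                    f"A*R*T*nu={derived}"
                )

    @classmethod
    def from_chain_density(
        cls, nu: float, a_factor: float = 1.0, temperature: float = 298.15
    ) -> "ElasticParams":
        g0 = a_factor * GAS_CONSTANT * temperature * nu
        return cls(g0=g0, a_factor=a_factor, nu=nu, temperature=temperature)

    def shear_modulus(self, phi):
        """G(phi) = G0 * phi^(1/3), Pa."""
        phi = np.asarray(phi, dtype=float)
        return self.g0 * np.cbrt(phi)


@dataclass(frozen=True)
class IonSpecies:
    """One mobile ion species in the bath."""

    label: str
    valence: int
    bath_concentration: float  # mol/m^3

    def __post_init__(self) -> None:
        if self.valence == 0:
            raise ValueError(f"ion {self.label!r}: valence must be nonzero")
        if self.bath_concentration < 0:
            raise ValueError(
                f"ion {self.label!r}: bath_concentration must be >= 0, "
                f"got {self.bath_concentration}"
            )


@dataclass(frozen=True)
class IonicBath:
    """Electroneutral collection of mobile ion species.

    Convenience constructors build the common bath compositions used in
    the experiments being modelled (NaCl, NaCl + CaCl2).
    """

    species: tuple[IonSpecies, ...]

    def __init__(self, species: Sequence[IonSpecies]):
        object.__setattr__(self, "species", tuple(species))
        self._check_electroneutral()

    def _check_electroneutral(self, rtol: float = 1e-9) -> None:
        charge = sum(s.valence * s.bath_concentration for s in self.species)
        scale = sum(abs(s.valence) * s.bath_concentration for s in self.species)
        if scale > 0 and abs(charge) > rtol * scale:
            raise ValueError(
                f"bath is not electroneutral: net charge {charge} mol/m^3"
            )

    @property
    def valences(self) -> np.ndarray:
        return np.array([s.valence for s in self.species], dtype=float)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([s.bath_concentration for s in self.species], dtype=float)

    @property
    def total_concentration(self) -> float:
        return float(self.concentrations.sum())

    @classmethod
    def monovalent(cls, c_salt: float, label: str = "Na") -> "IonicBath":
        """1:1 salt (e.g. NaCl) at concentration ``c_salt`` mol/m^3."""
        return cls(
            [
                IonSpecies(f"{label}+", +1, c_salt),
                IonSpecies("Cl-", -1, c_salt),
            ]
        )

    @classmethod
    def with_divalent(
        cls, c_mono: float, c_di: float, label: str = "Ca"
    ) -> "IonicBath":
        """Mixed bath: 1:1 salt at ``c_mono`` plus 2:1 salt at ``c_di`` mol/m^3."""
        return cls(
            [
                IonSpecies("Na+", +1, c_mono),
                IonSpecies(f"{label}2+", +2, c_di),
                IonSpecies("Cl-", -1, c_mono + 2.0 * c_di),
            ]
        )


@dataclass(frozen=True)
class GelThermoParams:
    """Everything needed to evaluate Pi_tot(phi).

    ``fixed_charge_per_monomer`` is the degree of ionization f of the
    network (fraction of monomers bearing a fixed negative charge);
    ``monomer_molar_volume`` converts polymer volume fraction to the molar
    concentration of fixed charges:

        c_fixed = phi * f / v_monomer   (mol/m^3).
    """

    fh: FloryHugginsParams
    elastic: ElasticParams
    solvent: SolventSpec = field(default_factory=SolventSpec)
    fixed_charge_per_monomer: float = 0.0
    monomer_molar_volume: float = 6.0e-5

    def __post_init__(self) -> None:
        if not 0.0 <= self.fixed_charge_per_monomer <= 1.0:
            raise ValueError(
                "fixed_charge_per_monomer must lie in [0, 1], got "
                f"{self.fixed_charge_per_monomer}"
            )
        if not self.monomer_molar_volume > 0:
            raise ValueError(
                f"monomer_molar_volume must be > 0, got {self.monomer_molar_volume}"
            )

    def fixed_charge_concentration(self, phi):
        """Molar concentration of fixed network charges at ``phi``, mol/m^3."""
        phi = np.asarray(phi, dtype=float)
        return phi * self.fixed_charge_per_monomer / self.monomer_molar_volume

    def with_chi(self, fh: FloryHugginsParams) -> "GelThermoParams":
        return replace(self, fh=fh)


@dataclass(frozen=True)
class PressureBreakdown:
    """Swelling-pressure decomposition at one state point (all Pa)."""

    pi_mix: float
    pi_el: float
    pi_ion: float

    @property
    def pi_tot(self) -> float:
        return self.pi_mix + self.pi_el + self.pi_ion


# --------------------------------------------------------------------------
# pressure components


def _check_phi(phi, lower_open: bool) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    if np.any(phi >= 1.0):
        bad = phi[phi >= 1.0] if phi.ndim else phi
        raise ValueError(f"polymer volume fraction must be < 1, got {bad}")
    if lower_open:
        if np.any(phi <= 0.0):
            bad = phi[phi <= 0.0] if phi.ndim else phi
            raise ValueError(f"polymer volume fraction must be > 0, got {bad}")
    elif np.any(phi < 0.0):
        bad = phi[phi < 0.0] if phi.ndim else phi
        raise ValueError(f"polymer volume fraction must be >= 0, got {bad}")
    return phi


def mixing_pressure(phi, fh: FloryHugginsParams, solvent: SolventSpec | None = None):
    """Flory-Huggins osmotic mixing pressure, Pa.

    Pi_mix = -(R T / V1) [ln(1 - phi) + phi + chi0 phi^2 + chi1 phi^3]

    Accepts scalars or arrays of ``phi`` in [0, 1).
    """
    solvent = solvent or SolventSpec()
    phi = _check_phi(phi, lower_open=False)
    # log1p keeps the small-phi cancellation (ln(1-phi)+phi = O(phi^2)) accurate
    bracket = np.log1p(-phi) + phi + fh.chi0 * phi**2 + fh.chi1 * phi**3
    out = -(solvent.rt / solvent.molar_volume) * bracket
    return out if out.ndim else float(out)


def elastic_pressure(phi, elastic: ElasticParams):
    """Rubber-elastic pressure Pi_el = -G0 phi^(1/3) = -G(phi), Pa."""
    phi = _check_phi(phi, lower_open=True)
    out = -elastic.shear_modulus(phi)
    return out if np.ndim(out) else float(out)


# --------------------------------------------------------------------------
# Donnan partitioning

_LOG_LAMBDA_SPAN = (np.log(1e-6), np.log(1e6))


def donnan_ratio(c_fixed, bath: IonicBath, n_iter: int = 100):
    """Donnan ratio lambda solving gel electroneutrality.

    Internal concentrations obey the ideal Donnan condition
    ``c_j_gel = c_j_bath * lambda**(-z_j)``; lambda > 0 is fixed by
    electroneutrality of the gel interior including the fixed *negative*
    network charges at concentration ``c_fixed`` (mol/m^3, >= 0):

        sum_j z_j c_j_bath lambda**(-z_j) - c_fixed = 0.

    The residual is strictly decreasing in lambda, so a bracketed bisection
    on log(lambda) over [1e-6, 1e6] converges unconditionally; ``n_iter``
    halvings leave the bracket far below 1e-12 relative width.  Vectorized
    over ``c_fixed`` so million-point sweeps of Pi_tot(phi) stay cheap.
    """
    c_fixed = np.asarray(c_fixed, dtype=float)
    scalar = c_fixed.ndim == 0
    c_fixed = np.atleast_1d(c_fixed)
    if np.any(c_fixed < 0):
        raise ValueError("fixed-charge concentration must be >= 0")
    z = bath.valences
    c = bath.concentrations
    if np.all(c == 0.0):
        if np.any(c_fixed > 0):
            raise ValueError(
                "no Donnan equilibrium: bath has no mobile ions to balance "
                "the fixed network charge"
            )
        lam = np.ones_like(c_fixed)
        return float(lam[0]) if scalar else lam

    def residual(log_lam: np.ndarray) -> np.ndarray:
        # sum_j z_j c_j exp(-z_j log lam) - c_fixed
        return (c[:, None] * z[:, None] * np.exp(-np.outer(z, log_lam))).sum(axis=0) - c_fixed

    lo = np.full(c_fixed.shape, _LOG_LAMBDA_SPAN[0])
    hi = np.full(c_fixed.shape, _LOG_LAMBDA_SPAN[1])
    if np.any(residual(lo) < 0) or np.any(residual(hi) > 0):
        raise RuntimeError("Donnan ratio fell outside the bracket [1e-6, 1e6]")
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        r = residual(mid)
        take_hi = r > 0  # residual decreasing: root above mid
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    lam = np.exp(0.5 * (lo + hi))
    # exact at zero fixed charge
    lam = np.where(c_fixed == 0.0, 1.0, lam)
    return float(lam[0]) if scalar else lam


def donnan_partition(
    phi: float, params: GelThermoParams, bath: IonicBath
) -> np.ndarray:
    """Internal mobile-ion concentrations (mol/m^3) at volume fraction phi.

    Ideal Donnan partitioning: each species' internal concentration is
    ``c_bath * lambda**(-z)`` with one common ratio lambda chosen so the gel
    interior, fixed charges included, is electroneutral.
    """
    phi = _check_phi(phi, lower_open=False)
    c_fixed = params.fixed_charge_concentration(phi)
    lam = donnan_ratio(c_fixed, bath)
    return bath.concentrations * np.power(lam, -bath.valences)


def ionic_pressure(phi, params: GelThermoParams, bath: IonicBath | None):
    """Ideal-Donnan ionic swelling pressure Pi_ion = RT sum_j (c_j_gel - c_j_bath).

    Always >= 0 for a gel with fixed charges in an ideal bath; tends to zero
    as added salt swamps the fixed-charge concentration.  ``bath=None`` means
    no mobile ions: valid only for a neutral gel, returning 0.
    """
    phi = np.asarray(phi, dtype=float)
    scalar = phi.ndim == 0
    if bath is None:
        if params.fixed_charge_per_monomer > 0 and np.any(phi > 0):
            raise ValueError(
                "charged gel requires an ionic bath (no Donnan equilibrium "
                "without counter-ions)"
            )
        out = np.zeros_like(np.atleast_1d(phi))
        return float(out[0]) if scalar else out
    phi1 = np.atleast_1d(_check_phi(phi, lower_open=False))
    c_fixed = params.fixed_charge_concentration(phi1)
    lam = donnan_ratio(c_fixed, bath)
    z = bath.valences
    c = bath.concentrations
    excess = (c[:, None] * (np.power(np.asarray(lam)[None, :], -z[:, None]) - 1.0)).sum(axis=0)
    out = params.solvent.rt * excess
    # ideal-Donnan excess is nonnegative; clip roundoff
    out = np.where(out < 0, np.where(out > -1e-9, 0.0, out), out)
    return float(out[0]) if scalar else out


# --------------------------------------------------------------------------
# total pressure and equilibrium


def swelling_pressure(
    phi: float, params: GelThermoParams, bath: IonicBath | None = None
) -> PressureBreakdown:
    """Full decomposition (Pi_mix, Pi_el, Pi_ion, Pi_tot) at one state point."""
    pi_mix = mixing_pressure(phi, params.fh, params.solvent)
    pi_el = elastic_pressure(phi, params.elastic)
    pi_ion = ionic_pressure(phi, params, bath)
    return PressureBreakdown(pi_mix=pi_mix, pi_el=pi_el, pi_ion=pi_ion)


def total_pressure_profile(
    phi, params: GelThermoParams, bath: IonicBath | None = None
) -> np.ndarray:
    """Vectorized Pi_tot over an array of volume fractions (Pa)."""
    phi = np.asarray(phi, dtype=float)
    return (
        mixing_pressure(phi, params.fh, params.solvent)
        + elastic_pressure(phi, params.elastic)
        + ionic_pressure(phi, params, bath)
    )


def mixing_from_total(pi_tot, shear_modulus):
    """Recover Pi_mix from measured Pi_tot and G via Pi_mix = Pi_tot + G.

    This is the osmotic-deswelling workflow: Pi_tot from the osmotic-stress
    series, G from compression on the same gels, ionic term neglected in the
    presence of added salt.
    """
    shear_modulus = np.asarray(shear_modulus, dtype=float)
    if np.any(shear_modulus < 0):
        raise ValueError("shear modulus must be >= 0")
    out = np.asarray(pi_tot, dtype=float) + shear_modulus
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class EquilibriumRoot:
    """One solution of Pi_tot(phi) = Pi_external."""

    phi: float
    residual: float  # Pa
    stable: bool  # dPi_tot/dphi > 0
    globally_stable: bool = False


class NoEquilibriumError(RuntimeError):
    """Pi_tot(phi) = Pi_external has no root in the search window."""


def _free_energy_difference(
    phi_a: float,
    phi_b: float,
    params: GelThermoParams,
    bath: IonicBath | None,
    external_pressure: float,
) -> float:
    """Osmotic free energy of state b minus state a, per unit dry volume (J/m^3).

    dF/dV = -(Pi_tot - Pi_ext) along the swelling path; with V = V_dry/phi,
    F(b) - F(a) = int_a^b (Pi_tot(phi) - Pi_ext) / phi^2 dphi.
    """

    def integrand(phi):
        return (total_pressure_profile(phi, params, bath) - external_pressure) / phi**2

    val, _ = integrate.quad(integrand, phi_a, phi_b, epsrel=1e-8, limit=200)
    return val


def equilibrium_phi(
    params: GelThermoParams,
    bath: IonicBath | None = None,
    external_pressure: float = 0.0,
    phi_window: tuple[float, float] = (1e-5, 0.5),
    n_grid: int = 2048,
) -> list[EquilibriumRoot]:
    """All equilibrium volume fractions with stability labels.

    Roots of ``Pi_tot(phi) = external_pressure`` are bracketed by sign
    changes on a log-spaced grid over ``phi_window`` and polished with
    Brent's method to |residual| < 1e-6 Pa.  A root is locally stable when
    dPi_tot/dphi > 0 there (restoring response).  When several stable roots
    coexist (volume-transition region) the globally stable one is selected
    by comparing the osmotic free energy integral between roots.
    """
    if external_pressure < 0:
        raise ValueError("external_pressure must be >= 0")
    lo, hi = phi_window
    grid = np.geomspace(lo, hi, n_grid)
    resid = total_pressure_profile(grid, params, bath) - external_pressure

    roots: list[float] = []
    sign = np.sign(resid)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        f = lambda p: float(total_pressure_profile(p, params, bath)) - external_pressure
        r = optimize.brentq(f, grid[i], grid[i + 1], xtol=1e-16, rtol=8.9e-16)
        roots.append(float(r))
    # grid points that are exact roots
    for i in np.nonzero(resid == 0.0)[0]:
        roots.append(float(grid[i]))
    roots = sorted(set(roots))
    if not roots:
        raise NoEquilibriumError(
            f"no root of Pi_tot(phi) = {external_pressure} Pa in "
            f"phi in [{lo}, {hi}]"
        )

    out: list[EquilibriumRoot] = []
    for r in roots:
        h = max(1e-9, 1e-6 * r)
        dpi = (
            float(total_pressure_profile(min(r + h, 0.999), params, bath))
            - float(total_pressure_profile(max(r - h, 1e-12), params, bath))
        ) / (min(r + h, 0.999) - max(r - h, 1e-12))
        res = float(total_pressure_profile(r, params, bath)) - external_pressure
        out.append(EquilibriumRoot(phi=r, residual=res, stable=dpi > 0))

    stable = [er for er in out if er.stable]
    if len(stable) == 1:
        best = stable[0]
    elif len(stable) > 1:
        # compare osmotic free energies pairwise against the first stable root
        ref = stable[0]
        best, best_df = ref, 0.0
        for er in stable[1:]:
            df = _free_energy_difference(
                ref.phi, er.phi, params, bath, external_pressure
            )
            if df < best_df:
                best, best_df = er, df
    else:  # pathological: only unstable roots found
        best = out[0]
    return [
        replace(er, globally_stable=(er is best)) for er in out
    ]


def stable_phi(
    params: GelThermoParams,
    bath: IonicBath | None = None,
    external_pressure: float = 0.0,
    **kwargs,
) -> float:
    """Globally stable equilibrium volume fraction (convenience wrapper)."""
    roots = equilibrium_phi(params, bath, external_pressure, **kwargs)
    return next(er.phi for er in roots if er.globally_stable)


# --------------------------------------------------------------------------
# volume-transition scan


@dataclass(frozen=True)
class TransitionScanResult:
    """Stable swelling branch phi(c_salt) and the detected jump, if any."""

    salt_grid: np.ndarray
    phi_stable: np.ndarray
    transition_salt: float | None  # smallest c_salt where the branch jumps
    jump_factor: float

    @property
    def has_transition(self) -> bool:
        return self.transition_salt is not None


def transition_scan(
    params_base: GelThermoParams,
    chi_of_salt: Callable[[float], FloryHugginsParams],
    bath_of_salt: Callable[[float], IonicBath | None],
    salt_grid: Sequence[float],
    jump_factor: float = 3.0,
    external_pressure: float = 0.0,
    **eq_kwargs,
) -> TransitionScanResult:
    """Trace the stable swelling branch along a salt-concentration grid.

    ``chi_of_salt`` maps salt concentration to interaction parameters (the
    empirical route by which divalent ions drive the transition: chi1 grows
    with c_salt); ``bath_of_salt`` supplies the matching ionic bath.  The
    transition concentration is the smallest grid value at which the stable
    equilibrium phi jumps by more than ``jump_factor`` between adjacent
    points; ``transition_salt=None`` reports "no transition".
    """
    salt_grid = np.asarray(salt_grid, dtype=float)
    if salt_grid.ndim != 1 or len(salt_grid) < 2 or np.any(np.diff(salt_grid) <= 0):
        raise ValueError("salt_grid must be strictly increasing with >= 2 points")
    phis = np.empty_like(salt_grid)
    for k, c in enumerate(salt_grid):
        p = params_base.with_chi(chi_of_salt(float(c)))
        phis[k] = stable_phi(p, bath_of_salt(float(c)), external_pressure, **eq_kwargs)
    ratios = phis[1:] / phis[:-1]
    jumps = np.nonzero((ratios > jump_factor) | (ratios < 1.0 / jump_factor))[0]
    c_star = float(salt_grid[jumps[0] + 1]) if len(jumps) else None
    return TransitionScanResult(
        salt_grid=salt_grid,
        phi_stable=phis,
        transition_salt=c_star,
        jump_factor=jump_factor,
    )


# --------------------------------------------------------------------------
# interaction-parameter fit


@dataclass(frozen=True)
class ChiFitResult:
    """Least-squares fit of the mixing-pressure law to (phi, Pi_mix) data."""

    params: FloryHugginsParams
    stderr_chi0: float
    stderr_chi1: float
    residual_norm: float  # Pa
    n_points: int


def fit_chi(
    phi,
    pi_mix,
    solvent: SolventSpec | None = None,
    fix_chi0: float | None = None,
) -> ChiFitResult:
    """Fit (chi0, chi1) to an osmotic mixing-pressure series.

    The mixing law is linear in the interaction parameters once the known
    ``ln(1-phi) + phi`` term is moved to the left-hand side, so the
    least-squares problem is solved exactly by linear algebra; standard
    errors come from the Jacobian (design matrix) at the optimum.  With
    ``fix_chi0`` given, only chi1 is free (constrained fit for divalent-salt
    series where the second-order parameter barely moves).
    """
    solvent = solvent or SolventSpec()
    phi = np.asarray(phi, dtype=float)
    pi_mix = np.asarray(pi_mix, dtype=float)
    if phi.shape != pi_mix.shape or phi.ndim != 1:
        raise ValueError("phi and pi_mix must be 1-D arrays of equal length")
    if len(phi) < 3:
        raise ValueError(f"need >= 3 records to fit (chi0, chi1), got {len(phi)}")
    if np.any(phi <= 0) or np.any(phi >= 1):
        raise ValueError("all phi must lie strictly inside (0, 1)")

    pref = solvent.rt / solvent.molar_volume
    # Pi_mix = -pref*(ln(1-phi)+phi) - pref*chi0*phi^2 - pref*chi1*phi^3
    y = pi_mix + pref * (np.log1p(-phi) + phi)
    if fix_chi0 is None:
        X = np.column_stack([-pref * phi**2, -pref * phi**3])
        names = ("chi0", "chi1")
    else:
        y = y + pref * fix_chi0 * phi**2
        X = (-pref * phi**3)[:, None]
        names = ("chi1",)

    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "degenerate design: phi values do not separate the chi terms "
            "(e.g. all phi identical)"
        )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    dof = max(len(phi) - X.shape[1], 1)
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))

    if fix_chi0 is None:
        fh = FloryHugginsParams(chi0=float(coef[0]), chi1=float(coef[1]))
        se0, se1 = float(se[0]), float(se[1])
    else:
        fh = FloryHugginsParams(chi0=float(fix_chi0), chi1=float(coef[0]))
        se0, se1 = 0.0, float(se[0])
    return ChiFitResult(
        params=fh,
        stderr_chi0=se0,
        stderr_chi1=se1,
        residual_norm=float(np.sqrt(rss)),
        n_points=len(phi),
    )
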