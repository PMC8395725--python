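"""Shear modulus from uniaxial compression and its concentration dependence.

For an incompressible neo-Hookean (Gaussian) network the nominal stress in
uniaxial compression is

    sigma = G (Lambda - Lambda^-2),    Lambda = L / L0,

so G is the through-origin least-squares slope of sigma against
(Lambda - Lambda^-2).  Across swelling states rubber elasticity predicts
the power law G = G0 * phi^(1/3); the most swollen gels deviate upward
(finite chain extensibility), which is flagged, not modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "StressStrainRecord",
    "ModulusSeries",
    "ShearModulusFit",
    "PowerLawFit",
    "fit_shear_modulus",
    "fit_power_law",
    "flag_power_law_deviations",
    "DEFAULT_LAMBDA_WINDOW",
]

#: Measurement window of the compression protocol (deformation ratios).
DEFAULT_LAMBDA_WINDOW = (0.7, 1.0)


@dataclass(frozen=True)
class StressStrainRecord:
    """One uniaxial compression record: deformation ratios and nominal stresses."""

    lam: np.ndarray
    sigma: np.ndarray  # Pa
    sample_id: str | None = None
    lam_window: tuple[float, float] = DEFAULT_LAMBDA_WINDOW

    def __post_init__(self) -> None:
        lam = np.asarray(self.lam, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if lam.shape != sigma.shape or lam.ndim != 1:
            raise ValueError("lam and sigma must be 1-D arrays of equal length")
        if np.any(lam <= 0):
            raise ValueError("all deformation ratios must be > 0")
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "sigma", sigma)


@dataclass(frozen=True)
class ModulusSeries:
    """Shear moduli across swelling states (one bath or several)."""

    phi: np.ndarray
    g: np.ndarray  # Pa
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float)
        g = np.asarray(self.g, dtype=float)
        if phi.shape != g.shape or phi.ndim != 1:
            raise ValueError("phi and g must be 1-D arrays of equal length")
        if np.any(g <= 0):
            raise ValueError("all moduli must be > 0")
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "g", g)


@dataclass(frozen=True)
class ShearModulusFit:
    g: float  # Pa
    stderr: float  # Pa
    intercept: float = 0.0  # Pa, nonzero only with with_intercept=True
    n_used: int = 0
    n_excluded: int = 0


def fit_shear_modulus(
    rec: StressStrainRecord,
    with_intercept: bool = False,
    apply_window: bool = True,
) -> ShearModulusFit:
    """Shear modulus as the least-squares slope of sigma vs (Lam - Lam^-2).

    The regression passes through the origin (sigma vanishes at Lam = 1
    physically); ``with_intercept=True`` adds a diagnostic offset term for
    instrument zero errors.  Points outside the record's deformation window
    are excluded with a warning.
    """
    lam, sigma = rec.lam, rec.sigma
    n_excl = 0
    if apply_window:
        lo, hi = rec.lam_window
        keep = (lam > lo) & (lam <= hi)
        n_excl = int((~keep).sum())
        if n_excl:
            warnings.warn(
                f"excluding {n_excl} point(s) outside the deformation window "
                f"({lo}, {hi}]",
                stacklevel=2,
            )
        lam, sigma = lam[keep], sigma[keep]
    x = lam - lam**-2
    if len(np.unique(lam)) < 2 or np.all(x == 0):
        raise ValueError(
            "degenerate design: need >= 2 distinct deformation ratios with "
            "Lambda != 1"
        )
    if with_intercept:
        X = np.column_stack([x, np.ones_like(x)])
        coef, _, _, _ = np.linalg.lstsq(X, sigma, rcond=None)
        resid = sigma - X @ coef
        dof = max(len(x) - 2, 1)
        cov = (resid @ resid / dof) * np.linalg.inv(X.T @ X)
        return ShearModulusFit(
            g=float(coef[0]),
            stderr=float(np.sqrt(cov[0, 0])),
            intercept=float(coef[1]),
            n_used=len(x),
            n_excluded=n_excl,
        )
    sxx = float(x @ x)
    g = float(x @ sigma) / sxx
    resid = sigma - g * x
    dof = max(len(x) - 1, 1)
    stderr = float(np.sqrt((resid @ resid) / dof / sxx))
    return ShearModulusFit(g=g, stderr=stderr, n_used=len(x), n_excluded=n_excl)


@dataclass(frozen=True)
class PowerLawFit:
    """G = g0 * phi^exponent fitted on log-log axes."""

    g0: float  # Pa
    exponent: float
    stderr_g0: float
    stderr_exponent: float
    fixed_exponent: bool
    residual_log: np.ndarray = field(repr=False, default=None)

    @property
    def exponent_deviation(self) -> float:
        """Fitted exponent minus the rubber-elasticity value 1/3."""
        return self.exponent - 1.0 / 3.0


def fit_power_law(
    series: ModulusSeries, fixed_exponent: float | None = None
) -> PowerLawFit:
    """Fit the modulus-concentration power law G = G0 phi^m.

    Ordinary least squares of log G on log phi.  With ``fixed_exponent``
    (typically 1/3) only the prefactor is fitted.  The fit ignores bath
    labels: when divalent ions do not alter the effective cross-link
    density all baths share one curve.
    """
    phi, g = series.phi, series.g
    if len(phi) < 3:
        raise ValueError(f"need >= 3 points, got {len(phi)}")
    if np.any(phi <= 0):
        raise ValueError("all phi must be > 0 for a log-log fit")
    lx, ly = np.log(phi), np.log(g)
    if fixed_exponent is not None:
        c = ly - fixed_exponent * lx
        mean = float(np.mean(c))
        se = float(np.std(c, ddof=1) / np.sqrt(len(c))) if len(c) > 1 else 0.0
        resid = c - mean
        return PowerLawFit(
            g0=float(np.exp(mean)),
            exponent=float(fixed_exponent),
            stderr_g0=float(np.exp(mean) * se),
            stderr_exponent=0.0,
            fixed_exponent=True,
            residual_log=resid,
        )
    X = np.column_stack([lx, np.ones_like(lx)])
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError("degenerate design: all phi identical")
    coef, _, _, _ = np.linalg.lstsq(X, ly, rcond=None)
    resid = ly - X @ coef
    dof = max(len(lx) - 2, 1)
    cov = (resid @ resid / dof) * np.linalg.inv(X.T @ X)
    g0 = float(np.exp(coef[1]))
    return PowerLawFit(
        g0=g0,
        exponent=float(coef[0]),
        stderr_g0=float(g0 * np.sqrt(cov[1, 1])),
        stderr_exponent=float(np.sqrt(cov[0, 0])),
        fixed_exponent=False,
        residual_log=resid,
    )


def flag_power_law_deviations(
    series: ModulusSeries, fit: PowerLawFit, n_sigma: float = 3.0
) -> np.ndarray:
    """Indices where log G deviates from the fitted law by > n_sigma residual SDs.

    Intended to surface the low-phi stiffening of highly swollen gels,
    where finite chain extensibility breaks the Gaussian 1/3 power law.
    """
    resid = np.log(series.g) - (np.log(fit.g0) + fit.exponent * np.log(series.phi))
    scale = float(np.std(fit.residual_log, ddof=1)) if len(fit.residual_log) > 1 else 0.0
    if scale == 0.0:
        return np.nonzero(np.abs(resid) > 0)[0]
    return np.nonzero(np.abs(resid) > n_sigma * scale)[0]
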