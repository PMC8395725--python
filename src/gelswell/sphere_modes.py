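"""First-mode relation for spherical gel swelling with shear correction.

Collective swelling of a spherical gel relaxes through the eigenmodes of
the network-displacement diffusion equation.  With a stress-free surface
the shear modulus enters only through the boundary condition, giving the
eigenvalue problem (R = G / M_os, the shear-to-longitudinal modulus ratio)

    beta_n * j0(beta_n) = 4 R * j1(beta_n),

with j_n the spherical Bessel functions.  Expanding the initially uniform
dilation in these modes gives the diameter-relaxation amplitudes

    B_n = 2 j1(beta_n) j2(beta_n) / ( beta_n [ j1(beta_n)^2 - j0(beta_n) j2(beta_n) ] ).

In the pure-diffusion limit R -> 0 this reduces to the textbook result
beta_n = n*pi, B_n = 6/(n^2 pi^2).  The first mode exists for
R in [0, 3/4); as R -> 3/4, beta_1 -> 0 and B_1 -> 1.  B_1(R) is strictly
increasing, so it is invertible: a measured first-mode amplitude determines
R and hence beta_1, which converts the fitted relaxation time into the
collective diffusion coefficient D_c = a^2 / (beta_1^2 tau_1).
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from scipy.special import spherical_jn

__all__ = ["SphereModeRelation", "PURE_DIFFUSION_B1", "R_MAX"]

#: B_1 in the pure-diffusion limit (R = 0): 6/pi^2.
PURE_DIFFUSION_B1 = 6.0 / np.pi**2

#: Upper end of the modulus-ratio domain; the first mode disappears at 3/4.
R_MAX = 0.75


def _char(beta: float, r: float) -> float:
    """Characteristic function whose roots are the eigenvalues."""
    return beta * spherical_jn(0, beta) - 4.0 * r * spherical_jn(1, beta)


def _amplitude(beta: float) -> float:
    j0 = spherical_jn(0, beta)
    j1 = spherical_jn(1, beta)
    j2 = spherical_jn(2, beta)
    return 2.0 * j1 * j2 / (beta * (j1 * j1 - j0 * j2))


class SphereModeRelation:
    """Eigenvalues beta_n(R) and amplitudes B_n(R) for a spherical gel.

    The single point of contact between measured first-mode amplitudes and
    the modulus ratio: ``beta1``/``b1`` evaluate the forward relation,
    ``invert_b1`` recovers R from a fitted B_1 by monotone bracketing.
    """

    def __init__(self, r_cap: float = R_MAX - 1e-9):
        self.r_cap = float(r_cap)

    # -- forward ----------------------------------------------------------

    def beta_n(self, r: float, n: int) -> float:
        """n-th eigenvalue (n >= 1); root of the characteristic equation
        in ((n-1)*pi, n*pi)."""
        if not 0.0 <= r < R_MAX:
            raise ValueError(f"modulus ratio R must lie in [0, {R_MAX}), got {r}")
        if n < 1:
            raise ValueError("mode index n must be >= 1")
        if r == 0.0:
            return n * np.pi
        lo = (n - 1) * np.pi + 1e-12
        hi = n * np.pi - 1e-12
        # the root sits strictly inside; endpoints have opposite signs
        flo, fhi = _char(lo, r), _char(hi, r)
        if flo * fhi > 0:  # pragma: no cover - guarded by theory
            raise RuntimeError(f"eigenvalue bracket failed for R={r}, n={n}")
        return float(optimize.brentq(_char, lo, hi, args=(r,), xtol=1e-15, rtol=8.9e-16))

    def beta1(self, r: float) -> float:
        return self.beta_n(r, 1)

    def b_n(self, r: float, n: int) -> float:
        """Amplitude of mode n at modulus ratio R."""
        if r == 0.0:
            return 6.0 / (n * np.pi) ** 2
        return float(_amplitude(self.beta_n(r, n)))

    def b1(self, r: float) -> float:
        return self.b_n(r, 1)

    def spectrum(self, r: float, n_modes: int) -> tuple[np.ndarray, np.ndarray]:
        """(beta_n, B_n) for the first ``n_modes`` modes."""
        betas = np.array([self.beta_n(r, n) for n in range(1, n_modes + 1)])
        if r == 0.0:
            amps = 6.0 / betas**2
        else:
            amps = np.array([_amplitude(b) for b in betas])
        return betas, amps

    # -- inverse ----------------------------------------------------------

    @property
    def b1_range(self) -> tuple[float, float]:
        """Attainable interval of B_1 over R in [0, r_cap]."""
        return (PURE_DIFFUSION_B1, self.b1(self.r_cap))

    def invert_b1(self, b1: float, tol: float = 0.0) -> tuple[float, float]:
        """(beta1, R) from a measured first-mode amplitude.

        B_1(R) is strictly increasing on [0, 3/4), so the inverse is found
        by bracketed root finding.  ``tol`` admits measurement noise: values
        within ``tol`` below the pure-diffusion amplitude 6/pi^2 (or above
        the cap) are clamped to the nearest attainable point; beyond that an
        out-of-range error reports the valid interval.
        """
        lo, hi = self.b1_range
        if not lo - tol <= b1 <= hi + tol:
            raise ValueError(
                f"B1={b1} outside the attainable range [{lo:.6f}, {hi:.6f}] "
                f"of the spherical mode relation (R in [0, {self.r_cap}])"
            )
        b1c = min(max(b1, lo), hi)
        if b1c <= lo:
            return np.pi, 0.0
        if b1c >= hi:
            return self.beta1(self.r_cap), self.r_cap
        r = optimize.brentq(
            lambda rr: self.b1(rr) - b1c, 0.0, self.r_cap, xtol=1e-14, rtol=8.9e-16
        )
        return self.beta1(float(r)), float(r)
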