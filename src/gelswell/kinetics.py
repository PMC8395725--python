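"""Swelling/shrinking kinetics of spherical gel beads.

The bead diameter relaxes toward equilibrium as a sum of exponential
modes,

    d(t) = d_inf + (d0 - d_inf) * sum_n B_n exp(-t / tau_n),

and at long times (t > tau_1) the slowest mode dominates.  Fitting the
linearized form

    Y = ln[(d_inf - d_t) / (d_inf - d0)] = ln B_1 - t / tau_1

gives the first-mode amplitude B_1 and relaxation time tau_1.  B_1 fixes
the modulus ratio R = G/M_os through the spherical mode relation, whose
eigenvalue beta_1(R) converts tau_1 into the collective diffusion
coefficient

    D_c = a^2 / (beta_1^2 tau_1),

with a the bead radius.  D_c is a material property: beads of different
sizes made of the same gel share one D_c (tau_1 scales as a^2), which is
what the master-curve collapse in reduced variables (t/tau_1, d_t/d0)
expresses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from .sphere_modes import PURE_DIFFUSION_B1, SphereModeRelation

__all__ = [
    "SwellingCurve",
    "KineticsFit",
    "MasterCurveResult",
    "model_diameter",
    "pure_diffusion_modes",
    "linearize",
    "fit_first_mode",
    "beta_from_B1",
    "collective_diffusion",
    "analyze_curve",
    "analyze_family",
    "master_curve",
]

_RELATION = SphereModeRelation()


@dataclass(frozen=True)
class SwellingCurve:
    """One bead's diameter-vs-time record (sphere geometry)."""

    t: np.ndarray  # s, strictly increasing
    d: np.ndarray  # m
    d0: float  # m, initial diameter
    d_inf: float | None = None  # m; None = not observed, estimate it
    bead_id: str | None = None
    radius: float | None = None  # m, bead radius a (for D_c)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        d = np.asarray(self.d, dtype=float)
        if t.shape != d.shape or t.ndim != 1:
            raise ValueError("t and d must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(d <= 0):
            raise ValueError("diameters must be > 0")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "d", d)


@dataclass(frozen=True)
class KineticsFit:
    """First-mode fit of one swelling curve and derived transport quantities."""

    B1: float
    tau1: float  # s
    d_inf: float  # m (supplied or jointly estimated)
    beta1: float | None = None
    R: float | None = None  # G/M_os
    Dc: float | None = None  # m^2/s
    fit_window: tuple[float, float] = (0.0, np.inf)
    n_points_used: int = 0
    bead_id: str | None = None

    def __post_init__(self) -> None:
        if not self.tau1 > 0:
            raise ValueError(f"tau1 must be > 0, got {self.tau1}")
        if not self.B1 > 0:
            raise ValueError(f"B1 must be > 0, got {self.B1}")


def model_diameter(
    t, d0: float, d_inf: float, modes: Sequence[tuple[float, float]]
):
    """Multi-mode relaxation d(t) = d_inf + (d0 - d_inf) sum_i B_i exp(-t/tau_i).

    ``modes`` is a sequence of (B_i, tau_i) pairs; a single mode reproduces
    the long-time law.  Works for swelling (d0 < d_inf) and shrinking alike.
    """
    t = np.asarray(t, dtype=float)
    modes = list(modes)
    b = np.array([m[0] for m in modes], dtype=float)
    tau = np.array([m[1] for m in modes], dtype=float)
    if np.any(tau <= 0):
        raise ValueError("all relaxation times must be > 0")
    if b.sum() > 1.0 + 1e-9:
        raise ValueError(f"mode amplitudes sum to {b.sum()} > 1")
    decay = (b[:, None] * np.exp(-np.outer(1.0 / tau, t))).sum(axis=0)
    out = d_inf + (d0 - d_inf) * decay
    return out if out.ndim else float(out)


def pure_diffusion_modes(tau1: float, n_modes: int = 50) -> list[tuple[float, float]]:
    """Sphere mode set in the no-shear limit: B_n = 6/(n pi)^2, tau_n = tau1/n^2."""
    n = np.arange(1, n_modes + 1)
    return list(zip(6.0 / (n * np.pi) ** 2, tau1 / n.astype(float) ** 2))


def linearize(
    curve: SwellingCurve, d_inf: float | None = None
) -> tuple[np.ndarray, np.ndarray, int]:
    """Log-transform a curve: Y = ln[(d_inf - d_t)/(d_inf - d0)].

    Points where ``d_inf - d_t`` has the opposite sign to ``d_inf - d0``
    (noise beyond the plateau) cannot be log-transformed; they are dropped
    and counted.  Returns (t, Y, n_dropped).
    """
    d_inf = curve.d_inf if d_inf is None else d_inf
    if d_inf is None:
        raise ValueError("d_inf is required (supply it or estimate it first)")
    denom = d_inf - curve.d0
    if denom == 0:
        raise ValueError("degenerate curve: d_inf equals d0")
    ratio = (d_inf - curve.d) / denom
    keep = ratio > 0
    n_dropped = int((~keep).sum())
    y = np.log(ratio[keep])
    return curve.t[keep], y, n_dropped


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and intercept of an ordinary least-squares line."""
    A = np.column_stack([t, np.ones_like(t)])
    (slope, intercept), _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    return float(slope), float(intercept)


def fit_first_mode(
    curve: SwellingCurve,
    window_policy: str = "iterative",
    max_iter: int = 10,
    min_points: int = 5,
    refine: bool = True,
) -> KineticsFit:
    """Extract (B_1, tau_1) from one swelling curve.

    The linearized long-time fit supplies initial estimates.  With
    ``window_policy="iterative"`` an OLS line over all usable points seeds
    tau_1, the window is re-cut to tau_1_hat < t < 4 tau_1_hat (below: early
    multi-mode curvature; above: log-space points carry no signal against
    plateau noise) and the cycle repeats to a fixed point.
    ``window_policy="all"`` uses every usable point — appropriate when the
    record is known to be single-mode.  When ``d_inf`` is not supplied, or
    ``refine`` is set, a joint nonlinear refinement of (d_inf, B_1, tau_1)
    against the diameters on t >= window start follows, initialized from
    the linear fit; diameter-space noise is homoscedastic, so late plateau
    points then properly pin d_inf.
    """
    d_inf = curve.d_inf
    d_inf_known = d_inf is not None
    if not d_inf_known:
        # plateau guess: mean of the last 10% of samples
        k = max(3, len(curve.d) // 10)
        d_inf = float(np.mean(curve.d[-k:]))
        if d_inf == curve.d0:
            raise ValueError("cannot estimate d_inf: curve shows no relaxation")

    t_all, y_all, _ = linearize(curve, d_inf)
    if len(t_all) < min_points:
        raise ValueError(
            f"only {len(t_all)} usable points after log transform; need >= {min_points}"
        )

    sel = np.ones(len(t_all), dtype=bool)
    slope, intercept = _ols_line(t_all, y_all)
    if window_policy == "iterative":
        for _ in range(max_iter):
            if slope >= 0:
                break
            tau_hat = -1.0 / slope
            new_sel = (t_all > tau_hat) & (t_all < 4.0 * tau_hat)
            if new_sel.sum() < min_points or np.array_equal(new_sel, sel):
                break
            sel = new_sel
            slope, intercept = _ols_line(t_all[sel], y_all[sel])
    elif window_policy != "all":
        raise ValueError(f"unknown window_policy {window_policy!r}")

    if slope >= 0:
        if not refine:
            raise ValueError(
                "non-relaxing data: linearized fit has non-negative slope "
                f"({slope:.3g} 1/s)"
            )
        # noisy seed; hand a coarse guess to the nonlinear refinement
        tau1 = float(curve.t[-1] - curve.t[0]) / 3.0
        b1 = PURE_DIFFUSION_B1
        sel = np.ones(len(t_all), dtype=bool)
    else:
        tau1 = -1.0 / slope
        b1 = float(np.exp(intercept))
    window = (float(t_all[sel][0]), float(t_all[sel][-1]))
    n_used = int(sel.sum())

    if refine or not d_inf_known:
        t_lo = window[0] if window_policy == "iterative" else -np.inf
        mask = curve.t >= t_lo
        tt, dd = curve.t[mask], curve.d[mask]

        if d_inf_known:
            # plateau measured independently: refine only (B1, tau1)
            di = d_inf

            def resid2(p):
                b, tau = p
                return dd - (di + (curve.d0 - di) * b * np.exp(-tt / tau))

            lsq = optimize.least_squares(
                resid2,
                x0=[min(b1, 1.0), tau1],
                bounds=([1e-12, 1e-12], [2.0, np.inf]),
                method="trf",
                xtol=1e-13, ftol=1e-13, gtol=1e-13,
            )
            b1, tau1 = (float(v) for v in lsq.x)
        else:

            def resid3(p):
                di, b, tau = p
                return dd - (di + (curve.d0 - di) * b * np.exp(-tt / tau))

            lsq = optimize.least_squares(
                resid3,
                x0=[d_inf, min(b1, 1.0), tau1],
                bounds=([0.0, 1e-12, 1e-12], [np.inf, 2.0, np.inf]),
                method="trf",
                xtol=1e-13, ftol=1e-13, gtol=1e-13,
            )
            d_inf, b1, tau1 = (float(v) for v in lsq.x)
        n_used = int(mask.sum())
        window = (float(tt[0]), float(tt[-1]))

    return KineticsFit(
        B1=b1,
        tau1=tau1,
        d_inf=float(d_inf),
        fit_window=window,
        n_points_used=n_used,
        bead_id=curve.bead_id,
    )


def beta_from_B1(b1: float, tol: float = 0.02) -> tuple[float, float]:
    """Map a first-mode amplitude to (beta_1, R = G/M_os).

    Inverts the strictly increasing spherical relation B_1(R); at the
    pure-diffusion end B_1 = 6/pi^2 maps to (pi, 0).  ``tol`` absorbs
    fit noise just outside the attainable interval (clamped); values
    further out raise with the valid range.
    """
    if not 0.0 < b1 <= 1.0 + tol:
        raise ValueError(f"B1 must lie in (0, 1], got {b1}")
    return _RELATION.invert_b1(b1, tol=tol)


def collective_diffusion(a: float, beta1: float, tau1: float) -> float:
    """Collective diffusion coefficient D_c = a^2 / (beta_1^2 tau_1), m^2/s."""
    if not (a > 0 and beta1 > 0 and tau1 > 0):
        raise ValueError("radius, beta1 and tau1 must all be > 0")
    return a * a / (beta1 * beta1 * tau1)


def analyze_curve(curve: SwellingCurve, **fit_kwargs) -> KineticsFit:
    """Full per-bead pipeline: first-mode fit -> (beta_1, R) -> D_c."""
    fit = fit_first_mode(curve, **fit_kwargs)
    beta1, r = beta_from_B1(fit.B1)
    dc = (
        collective_diffusion(curve.radius, beta1, fit.tau1)
        if curve.radius is not None
        else None
    )
    return replace(fit, beta1=beta1, R=r, Dc=dc)


def analyze_family(
    curves: Sequence[SwellingCurve], pool_b1: bool = True, **fit_kwargs
) -> list[KineticsFit]:
    """Analyze a bead-size family made of one gel.

    Each curve gets its own first-mode fit (so the size-independence of
    B_1 remains checkable), but with ``pool_b1`` the modulus ratio — a
    material property shared by all beads of one gel — is taken from the
    family-mean B_1 before converting the individual tau_1 into D_c.
    """
    fits = [fit_first_mode(c, **fit_kwargs) for c in curves]
    if pool_b1:
        b1_pool = float(np.mean([f.B1 for f in fits]))
        beta1, r = beta_from_B1(b1_pool)
        betas = [(beta1, r)] * len(fits)
    else:
        betas = [beta_from_B1(f.B1) for f in fits]
    out = []
    for c, f, (beta1, r) in zip(curves, fits, betas):
        dc = (
            collective_diffusion(c.radius, beta1, f.tau1)
            if c.radius is not None
            else None
        )
        out.append(replace(f, beta1=beta1, R=r, Dc=dc))
    return out


# --------------------------------------------------------------------------
# master curve


@dataclass(frozen=True)
class MasterCurveResult:
    """Curves rescaled to (t/tau_1, d_t/d0) and their collapse score."""

    reduced_time: list[np.ndarray]
    reduced_diameter: list[np.ndarray]
    bin_centers: np.ndarray | None
    spread_per_bin: np.ndarray | None
    collapse_score: float | None  # RMS cross-curve spread of d_t/d0


def master_curve(
    curves: Sequence[SwellingCurve],
    fits: Sequence[KineticsFit],
    n_bins: int = 20,
) -> MasterCurveResult:
    """Rescale curves by their fitted tau_1 and score the collapse.

    Each curve becomes (t/tau_1, d_t/d0).  The score interpolates every
    curve at ``n_bins`` log-spaced reduced-time points spanning the common
    overlap and takes the root-mean-square cross-curve spread of the
    reduced diameter (per-bin unbiased variance, averaged, rooted).  A
    single curve yields rescaled data with no score.
    """
    if len(curves) != len(fits):
        raise ValueError("need one fit per curve")
    red_t = [c.t / f.tau1 for c, f in zip(curves, fits)]
    red_d = [c.d / c.d0 for c in curves]
    if len(curves) < 2:
        return MasterCurveResult(red_t, red_d, None, None, None)

    lo = max(rt[rt > 0].min() for rt in red_t)
    hi = min(rt.max() for rt in red_t)
    if not hi > lo:
        raise ValueError("curves have no overlapping reduced-time range")
    centers = np.geomspace(lo, hi, n_bins)
    samples = np.stack([np.interp(centers, rt, rd) for rt, rd in zip(red_t, red_d)])
    var = samples.var(axis=0, ddof=1)
    score = float(np.sqrt(var.mean()))
    return MasterCurveResult(red_t, red_d, centers, np.sqrt(var), score)
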