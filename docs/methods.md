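# Methods

## Swelling-pressure model

The gel free energy is taken as additive in mixing, elastic, and ionic
terms, so the swelling pressure decomposes exactly as
Π_tot = Π_mix + Π_el + Π_ion.  Assumptions, term by term:

* **Mixing** (Flory–Huggins with a concentration-dependent interaction):
  Π_mix = −(RT/V₁)[ln(1−φ) + φ + χ₀φ² + χ₁φ³].  The third-order
  parameter χ₁ is what added divalent salt mainly moves; χ₀ moves weakly.
  `log1p` keeps the small-φ cancellation ln(1−φ)+φ = O(φ²) accurate, so
  the pressure is clean down to φ ~ 1e−6.
* **Elasticity** (Gaussian phantom/affine network): Π_el = −G₀φ^(1/3),
  identically −G(φ).  The prefactor is G₀ = A·R·T·ν; the topology factor
  A defaults to 1 and users normally supply G₀ directly, since A is rarely
  known.  Finite-extensibility stiffening of highly swollen networks is
  *detected* (power-law residual flags) but not modelled.
* **Ionic** (ideal Donnan, activity coefficients 1): internal
  concentrations c_j = c_j^bath·λ^(−z_j) with one ratio λ fixed by gel
  electroneutrality including the fixed charges
  c_f = φ·f/v_monomer.  λ is solved by monotone bisection in log λ on
  [1e−6, 1e6] (the residual is strictly decreasing in λ), 100 halvings →
  far below 1e−12 relative error; the solver is vectorized over φ so
  million-point pressure profiles stay cheap.  Counter-ion condensation
  is *not* modelled; instead the effective ionization f (default 0.02 for
  the reference gel) absorbs it as a lumped parameter.

With added salt the Donnan term is numerically small, which is why the
fitting workflow for interaction parameters uses Π_mix = Π_tot + G and
ignores Π_ion by default; the term is still computed and can be included
explicitly.

### Default constants

| symbol | meaning | default | note |
|---|---|---|---|
| T | temperature | 298.15 K | measurement temperature 25 °C |
| V₁ | solvent molar volume | 1.8e−5 m³/mol | water; configurable |
| v_monomer | monomer molar volume | 6e−5 m³/mol | acrylate-like; an assumption, configurable |
| f | effective ionization | 0.02 | lumped (condensation-reduced); configurable |
| G₀ | modulus prefactor | 10 kPa | laboratory scale for weakly cross-linked gels |

## Equilibrium swelling and the volume transition

Roots of Π_tot(φ) = Π_ext are bracketed on a 2048-point log-spaced grid
over φ ∈ [1e−5, 0.5] (window and grid overridable) and polished by
Brent's method; accepted roots satisfy |Π_tot − Π_ext| < 1e−6 Pa.  Local
stability is dΠ_tot/dφ > 0.  When two stable roots coexist, the globally
stable one minimizes the osmotic free energy; the difference between
states is the quadrature ∫(Π_tot − Π_ext)/φ² dφ (adaptive, relative
tolerance 1e−8).  Because global stability is evaluated pointwise, an
up-scan and a down-scan of the same conditions return the same branch —
the transition is treated as the reversible equilibrium jump, and
metastable-branch hysteresis is deliberately not reported as the stable
curve.

`transition_scan` walks a user-supplied χ(c_salt) map along a salt grid
and reports the smallest concentration where the stable φ jumps by more
than a factor 3 (configurable) between adjacent grid points.

The reference synthetic ramp (`presets.divalent_chi_ramp`) saturates at
χ₀: 0.448→0.508 and χ₁: 0.21→0.66 with half-saturation at 0.3 mol/m³,
on top of a 40 mol/m³ 1:1 background bath plus the divalent salt.  These
numbers were chosen once so that the multi-root region is crossed inside
the φ window at sub-mM divalent concentrations (the coarse default grid
detects the jump at ~0.65 mM, a laboratory-plausible scale); the swollen
branch sits at φ ≈ 0.017 and the collapsed branch at φ ≈ 0.4.

## Interaction-parameter fit

Equation Π_mix(φ; χ₀, χ₁) is linear in the interaction parameters once
the known ln(1−φ)+φ term is moved to the data side, so the least-squares
problem is solved exactly by linear algebra — same optimum and covariance
as an iterative nonlinear fit, with none of its convergence questions.
Standard errors come from the design matrix and residual variance; a
rank check rejects degenerate designs (e.g. all φ equal).  A constrained
variant fixes χ₀ and fits χ₁ alone, for divalent-salt series where the
second-order parameter barely moves.

## Shear modulus

G is the through-origin least-squares slope of nominal stress against
(Λ − Λ⁻²); the origin constraint reflects σ(Λ=1) = 0, with an optional
intercept as an instrument-offset diagnostic.  Points outside the
deformation window (0.7, 1] are excluded with a warning (the measurement
protocol's range; configurable).  The concentration law G = G₀φ^m is fit
on log–log axes, optionally with m fixed at 1/3.

## Swelling kinetics

Sphere relaxation modes: the displacement field obeys a diffusion
equation with collective diffusivity D_c = M_os/f_friction; the shear
modulus enters only through the stress-free surface condition, giving
eigenvalues β_n from β j₀(β) = 4R j₁(β), R = G/M_os ∈ [0, 3/4), and
amplitudes B_n = 2j₁j₂ / (β[j₁² − j₀j₂]).  This reproduces β_n = nπ,
B_n = 6/(nπ)² at R = 0 and is exposed behind a single
`SphereModeRelation` interface; B₁(R) is strictly increasing, so a fitted
B₁ inverts to (β₁, R) by bracketed root finding (round-trip accurate to
1e−8).  The first mode ceases to exist at R = 3/4 (β₁ → 0, B₁ → 1), which
bounds the attainable B₁ range; fitted values slightly outside (within a
2% tolerance) are clamped, beyond that an error reports the valid
interval.

Per-curve fitting: the linearized form Y = ln[(d_∞−d_t)/(d_∞−d₀)] is fit
by OLS in an iteratively re-cut window τ̂ < t < 4τ̂ (below: multi-mode
curvature; above: log-space points are plateau noise), then a nonlinear
refinement in diameter space follows — three parameters (d_∞, B₁, τ₁)
when the plateau was not measured, two when it was.  Diameter-space noise
is homoscedastic, so plateau points properly pin d_∞ there.  For records
known to be single-mode the `window_policy="all"` fit over the full
record is the maximum-likelihood choice.  Sign conventions make the same
formulas handle shrinking (d₀ > d_∞).

Family analysis: B₁ (equivalently G/M_os) is a material property, so
`analyze_family` pools the family-mean B₁ before converting each bead's
τ₁ into D_c = a²/(β₁²τ₁).  Per-bead B₁ values are still reported, so the
size-independence claim remains a checkable output, not an assumption.
Master curves rescale each record to (t/τ₁, d_t/d₀); the collapse score
interpolates every curve at 20 log-spaced reduced times spanning the
common overlap and takes the RMS cross-curve spread (per-bin unbiased
variance, averaged, rooted).

## Synthetic data

Generators emulate: uniaxial compression (σ = G(Λ−Λ⁻²), Λ ∈ [0.7, 1],
30 points), osmotic-stress deswelling (equilibrium φ per imposed
pressure), bead video time-lapse (per-bead clocks, 600 frames to 4τ₁,
diameter ratio d_∞/d₀ = 1.6, separately measured d₀ and d_∞ — note the
first frame already sits below d₀ by the instantly-relaxed fast modes),
and transition scans.  Noise is Gaussian, relative or absolute, with
defaults 1% on diameters, 2% on pressures, 0.5% on deformation ratios —
plausible instrument scales, echoed with every dataset in a GroundTruth
JSON.  Identical seeds give identical datasets.

What the generators do *not* emulate: instrument drift, outliers,
non-spherical beads, gel-to-gel parameter scatter, multi-mode content at
R > 0 (the shear-corrected family is generated single-mode, per the
long-time description being fitted), and any coupling between the
thermodynamic and kinetic blocks.  Passing closed-loop tests therefore
demonstrates estimator correctness and precision at the stated noise
level, not robustness to real-world artifacts.

## Ion-exchange front simulation

A deliberately minimal mechanistic reconstruction of divalent-ion-driven
collapse: explicit finite-volume radial diffusion of free Ca²⁺ on a
moving shell mesh (equal-thickness shells initially; each shell keeps its
polymer content and its volume follows the local φ), first-order
relaxation of bound-site occupancy toward the isotherm θ_eq = c/(c+c_half),
and local-equilibrium swelling φ = φ_map(θ) with a sigmoidal map
(φ 0.02 → 0.10, transition occupancy 0.5, width 0.05).  Defaults:
0.5 mm bead, D = 1e−9 m²/s, exchange rate 0.01 s⁻¹, site density
1000 mol per m³ polymer, 5 mol/m³ divalent bath over a 40 mol/m³ 1:1
background.  No explicit Na⁺ field: monovalent screening is folded into
the isotherm and the φ map.  No electro-diffusion coupling and no
stress-gradient kinetics — the model aims at the observed *structure*
(slow near-linear onset while surface occupancy builds, rapid contraction
while a collapsed skin coexists with the swollen core, slow plateau
approach; the reverse sequence on reswelling), not at laboratory numbers.

Numerics: the configured time step is validated against the explicit
stability bound dt < Δr²/(2·D·safety), safety ≥ 3, on the initial mesh;
because collapse contracts the mesh, the stepper sub-steps internally
whenever the current mesh tightens the bound.  Ion bookkeeping is exact
by construction (per-face flux telescoping plus a boundary-flux ledger),
so the audited conservation error is at machine precision, far below the
0.1% test bound.  Trajectories converge to < 0.1% between 24 and 48
shells for the default parameters.  Stage boundaries are located by an
exhaustive two-change-point piecewise-linear fit (prefix-sum OLS over a
decimated breakpoint grid).

Problem sizes: the test suite exercises the simulator at 200 shells
(≈3.5 min) and the unit tests at 16–48; the acceptance script uses 100
shells, where all audited properties are mesh-converged.

## Known limitations

* Ideal Donnan with unit activity coefficients; no Manning condensation,
  no electrostatic persistence-length effects.  The effective ionization
  is a lumped, calibratable parameter, not a prediction.
* Gaussian elasticity only; the high-swelling modulus upturn is flagged,
  not described.
* The χ(c_salt) dependence is empirical (tabulated or parametric input);
  the package provides no microscopic theory of ion-specific binding, and
  irreversible trivalent-ion binding is out of scope.
* The first-mode kinetics analysis assumes spherical beads and a
  size-independent modulus ratio; the shear-corrected multi-mode
  amplitudes are implemented but the generator uses the slowest mode for
  R > 0.
* The front simulator is qualitative by design; its parameters are not
  calibrated to any laboratory trajectory.
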