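# gelswell

Thermodynamics and swelling kinetics of polyelectrolyte gels: swelling-pressure
decomposition, ion-induced volume transitions, and collective-diffusion
analysis of bead swelling curves.

Charged polymer networks (polyacrylate, DNA, and by extension cartilage
matrix or marine microgels) swell or collapse in response to the ionic
composition of the surrounding bath.  This package implements the standard
thermodynamic description and the analysis pipeline used to interpret
osmotic, mechanical, and kinetic measurements on such gels, together with a
synthetic-data generator so that every stage can be validated as a closed
loop against known ground truth.

## The model

The swelling pressure of a gel at polymer volume fraction φ decomposes into
mixing, elastic, and ionic contributions:

    Π_tot(φ) = Π_mix + Π_el + Π_ion

    Π_mix = −(RT/V₁) [ln(1−φ) + φ + χ₀φ² + χ₁φ³]      (Flory–Huggins)
    Π_el  = −G₀ φ^(1/3) = −G(φ)                        (rubber elasticity)
    Π_ion = RT Σ_j (c_j^gel − c_j^bath)                (ideal Donnan)

with the internal ion concentrations fixed by a single Donnan ratio λ and
gel electroneutrality.  At free swelling Π_tot = 0; under osmotic stress
Π_tot equals the imposed external pressure.  When χ₁ grows with added
divalent salt, Π_tot develops multiple roots and the stable swelling degree
jumps discontinuously — the volume phase transition.

Swelling kinetics of spherical beads follow the collective-diffusion
relaxation

    d(t) = d_∞ + (d₀ − d_∞) Σ_n B_n exp(−t/τ_n),
    D_c  = a² / (β₁² τ₁),

where the first-mode amplitude B₁ and eigenvalue β₁ both depend on the
modulus ratio R = G/M_os through the spherical eigenvalue problem
β j₀(β) = 4R j₁(β) (pure-diffusion limit: B₁ = 6/π², β₁ = π).  The shear
modulus itself comes from uniaxial compression, σ = G(Λ − Λ⁻²), and follows
the concentration power law G = G₀ φ^(1/3).

## Worked example

```python
import numpy as np
from gelswell.synthetic import gen_swelling_curves, NoiseSpec
from gelswell.kinetics import analyze_family, master_curve

curves, truth = gen_swelling_curves(
    dc=3e-11, r_ratio=0.25, radii=[2.5e-4, 3.75e-4, 5.0e-4],
    noise=NoiseSpec(level=0.01, seed=2021),
)
for fit in analyze_family(curves, window_policy="all"):
    print(f"{fit.bead_id}: B1={fit.B1:.4f} tau1={fit.tau1:.0f} s Dc={fit.Dc:.3e}")
```

prints

```
a=0.00025: B1=0.7280 tau1=274 s Dc=3.065e-11
a=0.000375: B1=0.7277 tau1=614 s Dc=3.070e-11
a=0.0005: B1=0.7253 tau1=1103 s Dc=3.039e-11
```

Three beads of different sizes, one material: the relaxation time grows as
the radius squared (274 → 614 → 1103 s for radii 0.25, 0.375, 0.5 mm), the
first-mode amplitude is the same for all beads (the modulus ratio G/M_os is
size-independent), and the recovered collective diffusion coefficient
agrees with the generating value 3×10⁻¹¹ m²/s within ~1% for every bead.

The numbered drivers under `analysis/` replay the full workflow on
generated datasets and write their tables under `results/`:

```bash
python analysis/01_generate_datasets.py   # synthetic bundle + ground truth
python analysis/02_fit_modulus.py         # G from compression; phi^(1/3) law
python analysis/03_fit_chi.py             # (chi0, chi1) from Pi_mix(phi)
python analysis/04_swelling_kinetics.py   # B1, tau1, D_c, master curve
python analysis/05_transition_scan.py     # volume transition vs divalent salt
python analysis/06_front_simulation.py    # three-stage collapse + reswelling
```

A `gelswell` command-line interface wraps the same stages
(`gelswell generate|fit-modulus|fit-chi|fit-kinetics|scan-transition|simulate-front|run`),
reading the CSV schemas documented in `gelswell.io` and writing JSON with
input checksums for reproducibility.

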