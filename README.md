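# tpvdeploy

Reduced-order simulation of **self-expanding transcatheter pulmonary valve
(TPV) deployment** in an idealized right ventricular outflow tract (RVOT),
with material-uncertainty quantification and transannular-patch heterogeneity
studies.

## Who this is for

Cardiovascular biomechanics researchers who want a desk-scale, fully
reproducible pipeline for asking: *how sensitive are the stress and strain
fields of a simulated TPV deployment to the soft-tissue material parameters,
and what does a stiff surgical patch in the wall do to them?*  Patients with
repaired Tetralogy of Fallot typically have a dilated RVOT containing a
transannular patch; device simulations in such anatomies must assume material
properties that cannot be measured in vivo, so the sensitivity of the
simulated outcome to those assumptions is the central question.

## The model

**Wall mechanics.** The RVOT wall (thickness H = 1.5 mm) is an uncoupled
Holzapfel–Gasser–Ogden (HGO) solid: a neo-Hookean ground matrix plus two
symmetric families of dispersed collagen fibers at ±γ from the
circumferential direction,

```
Ψ = (c/2)(Ī₁ − 3) + (k₁/2k₂) Σ_α [exp(k₂⟨Ē_α⟩²) − 1] + (k/2)[(J² − 1)/2 − ln J]
Ē_α = κ(Ī₁ − 3) + (1 − 3κ)(Ī₄α − 1)
```

with tension-only fibers (⟨·⟩) by default.  Baselines: c = 200 kPa,
k₁ = 13480 kPa, k₂ = 1.06, γ = 18.85°, κ = 0.33, k = 1500 kPa.  The patch is
a compressible neo-Hookean solid matched to (E, ν = 0.495), with
E ∈ {1.1, 2.2, 4.4, 8.8}×10³ kPa.

**Deployment surrogate.** Instead of a 3-D contact finite-element solve, each
axial station is an exactly incompressible plane-strain thick-walled ring
(r(R) = √(r_i² + R² − R_i²)) in equilibrium with a linear self-expanding
radial-force law p_s = K_s·max(0, (r_free − r)/r_free).  The wall pressure is
the through-thickness integral p_w = ∫(σ_θθ − σ_rr)/r dr; the deployed radius
is the unique root of p_w = p_s.  Stations whose circumference mixes patch
and vessel material are solved as a composite ring in series (shared hoop
tension, circumference distributed by per-sector stretch).

**Uncertainty machinery.** Each uncertain parameter (c, k₁, k₂, γ, κ) gets a
gamma distribution moment-matched to its mean and a standard deviation
expressed as a percent of the mean (shape (μ/σ)², scale σ²/μ).  A
total-degree order-4 polynomial chaos expansion (PCE) on products of
generalized-Laguerre polynomials — orthonormal under each parameter's own
gamma measure — is fitted by least squares on a 126 + 10 = 136-run design;
first- and total-order Sobol indices follow from the squared coefficients,
and a 1000-query emulator summarizes output distributions.

## Worked example

```python
import numpy as np
from tpvdeploy import default_config, deploy, stent_enclosed_volume
from tpvdeploy.metrics import field_statistics, perimeter_derived_diameter

cfg = default_config()
geom = cfg.vessel()                      # 60 mm flare-waist-flare tube, 4 wall layers
stent = cfg.stent_for(geom)              # 25 mm device, 45 mm long, K_s = 50 kPa
res = deploy(geom, stent, {"vessel": cfg.baseline_hgo()})

waist = int(np.argmin(geom.R_inner))
print(f"waist: R_i = {geom.R_inner[waist]:.2f} mm -> deployed r_i = {res.r_inner_deployed[waist]:.3f} mm")
stats = field_statistics(res.field_table)
print(f"95th%ile stress = {stats['stress_p95']:.2f} kPa, 95th%ile strain = {stats['strain_p95']:.4f}")
print(f"narrowest perimeter-derived diameter = {perimeter_derived_diameter(res):.2f} mm")
print("enclosed volume (mm^3):", {k: round(v, 1) for k, v in stent_enclosed_volume(res).items()})
```

prints

```
waist: R_i = 9.00 mm -> deployed r_i = 9.675 mm
95th%ile stress = 75.73 kPa, 95th%ile strain = 0.0663
narrowest perimeter-derived diameter = 19.35 mm
enclosed volume (mm^3): {'distal': 6674.1, 'middle': 4899.8, 'proximal': 8466.7, 'total': 20040.6}
```

The device opens the 9 mm stenotic waist to 9.68 mm (77% of its 12.5 mm free
radius); the 95th-percentile first-principal Cauchy stress and
Green–Lagrange strain are volume-weighted over every through-wall sample;
the enclosed volume is reported per device third (distal/middle/proximal).

## Command line

```sh
tpvdeploy converge --out results          # wall-layer convergence study
tpvdeploy uq --seed 1 --out results       # 136-run sensitivity study + Sobol + emulator
tpvdeploy patch --out results             # 9-condition transannular patch sweep
tpvdeploy synth --out results             # write the idealized geometry (PLY/STL/VTK)
tpvdeploy metrics a.stl b.stl             # Hausdorff / symmetric distances of two surfaces
```

Configuration is YAML or JSON (same schema as `tpvdeploy.default_config()`);
every output CSV carries a provenance header with the config hash and seed.

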