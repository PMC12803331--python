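# Methods

This note documents the model, the numerical choices, and the limits of what
the package's synthetic studies can and cannot show about patient-specific
finite-element (FE) simulations of transcatheter pulmonary valve (TPV)
deployment.

## Constitutive models

**Vessel wall (uncoupled HGO).**  The deviatoric energy is

Ψ̃ = (c/2)(Ī₁ − 3) + (k₁/2k₂) Σ_{α=1,2} [exp(k₂ Ē_α²) − 1],
Ē_α = κ(Ī₁ − 3) + (1 − 3κ)(Ī₄α − 1),

with fiber families a₀ = (cos γ, ±sin γ, 0) in the local (circumferential,
axial, radial) frame, and deviatoric invariants built from
C̄ = J^(−2/3) FᵀF.  Two printed conventions required interpretation:

- *Volumetric law.*  The volumetric energy is implemented as
  U(J) = (k/2)[(J² − 1)/2 − ln J], the only reading of the published
  expression consistent with k acting as a bulk modulus: U(1) = 0,
  U′(1) = 0, U″(1) = k.  A finite-difference test pins these three
  identities.
- *Tension-only fibers.*  The exponential fiber term carries no explicit
  positive-part operator in print, but the standard HGO convention (and
  common FE implementations) excludes compressed fibers.  The switch is on
  by default and exposed as `tension_only` everywhere, so its effect can be
  measured.

Cauchy stress uses the standard uncoupled push-forward
σ = dev(F̄ S̄ F̄ᵀ)/J + U′(J) I with S̄ = 2∂Ψ̃/∂C̄.  No stress formula is
assumed correct by construction: a central-finite-difference oracle
σ = (∂Ψ/∂F)Fᵀ/J over seeded random states (rel. tol 1e-5) is the arbiter,
together with frame-indifference, fiber-symmetry (γ → −γ), and the
closed-form incompressible neo-Hookean uniaxial limit σ = c(λ² − 1/λ) at
k₁ = 0.

**Patch and tube.**  "Isotropic elastic" materials are realized as
compressible neo-Hookean solids matched to (E, ν) at small strain
(μ = E/2(1+ν), K = E/3(1−2ν)); a small-strain Hooke law is not objective at
deployment strains.  The linear limit is verified to 0.1%.

**Recorded-only device constants.**  The nitinol beam-element constants
(beam diameter 0.375 mm, E = 4.0×10⁷ kPa, G = 1.5×10⁷ kPa,
A = 0.111045 mm², I = 0.000970722 mm⁴, ρ = 6.5×10⁻⁶ kg/mm³) are carried as
metadata and never used: the device enters the reduced-order model only
through a free-radius profile and a radial stiffness.  The recorded area is
slightly inconsistent with πr² at r = 0.1875 mm (0.110447 mm²); it is kept
verbatim.

## The deployment surrogate

The central reduction: the 3-D beam/shell contact problem is replaced by
independent per-station, plane-strain (λ_z = 1), exactly incompressible
thick-walled-ring equilibria.

- Radial map r(R) = √(r_i² + R² − R_i²); λ_θ = r/R, λ_r = R/r, det F = 1
  identically.
- Wall pressure p_w(r_i) = ∫_{r_i}^{r_o} (σ_θθ − σ_rr)/r dr, evaluated with
  Gauss–Legendre quadrature using one panel per wall layer (4 points per
  panel).  The integrand uses only deviatoric stress differences, so the
  incompressibility reaction pressure cancels; the volumetric term is
  retained in the material module but inactive on the J = 1 manifold.  This
  replaces the nearly-incompressible FE formulation (k = 1500 kPa) with its
  exact-incompressibility limit — the surrogate's main constitutive
  fidelity gap.
- Device law p_s(r) = K_s·max(0, (r_free − r)/r_free): a linear radial-force
  recoil curve, zero at and beyond the free radius.  Default K_s = 50 kPa
  per unit relative recoil, a config value chosen so that the baseline
  vessel's 9 mm waist deploys to roughly 80% of the 12.5 mm free radius —
  the soft-tissue-dominated regime in which material sensitivity is
  visible.  The nominal 25 mm device diameter follows the device name; the
  free radius is a config default, not a measured quantity.
- Equilibrium: p_w is strictly increasing and p_s non-increasing in r_i, so
  the root in [R_i, r_free] is unique.  Root finding is deterministic
  bisection to a 1e-10 mm bracket followed by one Newton polish; an
  independent brute-force minimization of the total potential (wall strain
  energy minus device work) agrees to 1e-4 relative and is kept as a test
  oracle.
- Heterogeneous stations (patch arc + vessel arc) solve a composite-ring
  series model: a single hoop tension T = P_s(λ)·λR_i shared by all sectors
  with the circumference distributed by per-sector stretches
  (Σ φ_s λ_s = λ̄).  The homogeneous limit reduces exactly to the
  single-material path (tested to 1e-8 mm).
- Full through-wall fields: σ_rr follows from radial equilibrium
  σ_rr(r) = −p + ∫(σ_θθ−σ_rr)/r′ dr′, which fixes the hydrostatic reaction;
  first-principal Cauchy stress and Green–Lagrange strain
  (E = (FᵀF − I)/2, the "Lagrangian strain" of the FE convention) are
  reported per sample node.
- Field table: each station/sector contributes samples at the layer
  boundaries *and* layer midpoints (2n+1 points across the wall), each with
  a trapezoidal shell-volume weight; the weights are exact for the annulus
  (they telescope to π(R_o² − R_i²) per station), so the table's volume sum
  equals the wall volume to machine precision.  Node-based sampling keeps
  the inner-surface extremum in the table and makes the percentile
  statistics converge smoothly under layer refinement, which midpoint-only
  sampling does not.
- Staged release (compress → distal → proximal) is exposed as an ordered
  sequence of device profiles; the quasi-static surrogate is path
  independent, so the endpoint equals the direct solve (tested).

## Synthetic geometry

The patient anatomy is replaced by a parametric tube: 60 mm long, wall
1.5 mm, inner radius following a smooth flare–waist–flare curve
R(z) = R_f − (R_f − R_w)·exp(−((z − z₀)/w)²) with R_f = 16 mm, R_w = 9 mm,
w = 18 mm.  The waist is placed distal of the device center (z₀ = 27 mm of
a device centered at 30 mm): a dilated RVOT is not symmetric about the
device, and an off-center landing zone makes the two patch positions load
differently, as they do in the anatomical case.  The quad surface mesh
targets 1.5 mm elements; the solid mesh extrudes it through 1–6 layers.
Mesh checks: every interior edge shared by exactly two quads, Euler
characteristic 0 for the open tube, strictly positive hexahedral cell
volumes.

The transannular patch is a diamond in unrolled mid-wall coordinates
(u = R_mid·θ, v = z): |v − v₀|/(d₁/2) + |u − u₀|/(d₂/2) ≤ 1 with the long
diagonal d₁ = 30 mm axial and short diagonal d₂ = 20 mm circumferential.
Mid-wall arc length is used because the patch is a through-wall region;
mid-wall minimizes inner/outer bias.  Embedding updates per-station sector
arc fractions and surface/solid element labels; it is idempotent.

## Uncertainty machinery

- Standard-deviation magnitudes come from adult-artery media-layer data as
  std-as-percent-of-mean: c 49.61, k₁ 32.96, k₂ 39.83, γ 26.69, κ 36.  The
  source table's trailing column belongs to a different constitutive model
  and is carried verbatim only for the printed row average (39).
- Gamma distributions are moment matched: shape (μ/σ)², scale σ²/μ, with
  means at the simulation baselines.
- κ is physically confined to [0, 1/3]; draws are rejected-and-redrawn at
  the bound by default (a clip mode is exposed for comparison).  The
  effective κ distribution is therefore a truncation concentrated below
  1/3.
- The order-4, five-parameter basis has C(9,4) = 126 functions; the design
  adds 10 Monte-Carlo oversamples for 136 runs.  The published run count is
  matched; the original sampling scheme behind it is not stated, so only
  the count is pinned.  Least squares drops non-finite outputs (failed
  runs) and refits on survivors, aborting above a 2.5% failure fraction.
- Sobol indices come from the orthonormal coefficients:
  S_i = Σ_{α only i} a_α²/Var, S_Ti = Σ_{α∋i} a_α²/Var.  Exactness gates:
  basis orthonormality by Gauss–Laguerre quadrature (1e-8), exact
  reproduction of degree-≤4 polynomials, agreement with brute-force ANOVA
  quadrature on analytic functions (1e-6), and the partial-variance ledger
  summing to the total variance.
- The emulator is queried with 1000 seeded draws from the input measure;
  note that an order-4 polynomial extrapolates aggressively in the gamma
  tails, so emulator extrema are surrogate artifacts rather than physical
  bounds — the reported min/max ranges should be read with that in mind.

## Outcome metrics

- Percentiles are volume-weighted over all through-wall samples of all
  stations, using the inclusive sorted-cumulative-weight interpolation rule
  (reduces to the standard linear empirical quantile at unit weights).
  Whether the original element-wise percentiles were volume weighted is not
  stated; volume weighting is the defensible default for unequal cells.
- Geometry comparison: Hausdorff, mean symmetric and 95th-percentile
  symmetric distance over pooled two-directional point-to-surface
  distances.  Surfaces are sampled with an area-weighted seeded scheme
  keyed to (seed, mesh content), so the metrics are exactly symmetric in
  their arguments; point-cloud inputs fall back to exact brute-force
  point-set distances (the oracle path).  Point-to-triangle distances are
  computed by vectorized barycentric clamping.  The study runner compares
  deployed vertex grids as dense point clouds, adequate for the nearly
  coaxial tubes it produces.
- The device's enclosed volume integrates π r_i(z)² trapezoidally with the
  third boundaries inserted exactly (thirds sum to the total identically);
  perimeter-derived diameter is the sector-resolved cross-section perimeter
  over π.
- Wall-layer convergence: the study selects the smallest layer count at
  which both the 95th and 99th percentile strain change less than 1%
  relative to the previous refinement.  Under the default conditions the
  selection is 4 layers; the value is geometry dependent and only the
  existence of a selection is treated as a property.

## Study conditions and problem sizes

The default studies use the 60 mm tube at 1.5 mm mesh (41 stations), 4 wall
layers, the 136-run order-4 design, 1000 emulator queries, and the
9-condition patch sweep (baseline + 2 positions × 4 stiffnesses).  A full
sensitivity study runs in well under a minute on one CPU; the whole
acceptance pipeline in about one minute.  All randomness flows through a
single seeded generator per study; repeated runs with the same config and
seed are byte-identical.

## What the surrogate does and does not show

The synthetic studies reproduce, qualitatively and at desk scale: the
localization of stress and strain to the device contact zone; the smallness
of geometric variation across material draws relative to field variation
(Hausdorff distances of a few percent of the narrowest perimeter-derived
diameter); the patch strain decreasing monotonically with patch stiffness;
near-invariance (< 0.4%) of the device's enclosed volume across patch
conditions; and a finite wall-layer convergence selection under the 1%
criterion.

Two findings of full 3-D patient-specific FE simulations are *not*
reproduced, for structural reasons worth recording:

1. **Sensitivity ranking.**  In the plane-strain hoop-dominant state of the
   ring surrogate, the fiber-strain derivative ∂Ē/∂κ = (Ī₁−3) − 3(Ī₄−1) is
   large whenever the near-circumferential fibers (γ = 18.85°) are
   stretched, so the dispersion κ acts as a switch between a
   near-isotropic soft wall (κ → 1/3) and a strongly fiber-stiffened wall
   (κ < 1/3).  With κ varied over its truncated gamma, it captures ~98% of
   the output variance for every metric, displacing the ground-matrix
   modulus c from the top of the strain ranking that 3-D simulations
   report.  This is robust to the device stiffness (checked at K_s up to
   20× the default) and is a genuine fidelity limit of station-local
   plane-strain kinematics, where multi-axial deformation modes that
   de-emphasize the hoop fiber invariant are absent.
2. **Patch stress amplification.**  In a 1-D series composite, sectors share
   hoop tension, so a stiffer patch deforms less (strain ↓, reproduced) but
   carries essentially the same membrane tension — its maximum
   first-principal stress stays flat (within a few percent, mildly
   decreasing) rather than increasing.  Stress amplification inside a stiff
   inclusion is a 2-D/3-D load-funneling effect, and interface stress
   concentration at the patch boundary is explicitly outside the model's
   scope.

Both limits are visible in the acceptance checks rather than hidden by
them; they delimit what passing tests say about real anatomies.  Other
known simplifications: no contact mechanics or device bending (stress
localizes at maximum stretch rather than at device-end edge contact), no
inter-station coupling, no hemodynamics, diastole-only loading, and open
(uncapped) tube ends with fixed vessel extremities.
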