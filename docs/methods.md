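# Methods

## Transport model

The drug leaves the agar block and diffuses through the liquid film of the
germinal chamber. The governing equation is the linear diffusion equation
with first-order decay λ [s⁻¹] and retardation R [–] for linear,
reversible, instantaneous sorption:

    R ∂c/∂t = Dx ∂²c/∂x² + Dy ∂²c/∂y² + Dz ∂²c/∂z² − λc,  c(·, 0) = 0.

R is eliminated at evaluator entry by D → D/R, λ → λ/R
(`make_effective_medium`), so the (D, λ, R) and (D/R, λ/R, 1) paths are
bitwise identical. Defaults λ = 0 and R = 1: no decay or sorption
measurement exists for these drugs in egg white, so both are configuration
knobs, with R offered as the hook for albumin binding.

Assumptions: the medium is isotropic (Dx = Dy = Dz = D, the drug
diffusivity in water); the film is thin and vertically well mixed
("quasi-2D"), so no z-attenuation is applied in the strip geometry; the
release is boundary-limited, not matrix-limited, with f(t) ≡ 1 (residual
drug remained in the agar at the end of the experiments, so the boundary
never depleted); the lateral domain is effectively infinite (the embryo is
small and central relative to the chamber).

### Evaluators

* **1D closed form** (`conc_point_1d`): c = c₀·erfc(x/2√(Dt)) for λ = 0;
  for λ > 0 the standard two-term form
  ½c₀[e^(−x√(λ/D)) erfc(x/2√(Dt) − √(λt)) + e^(x√(λ/D)) erfc(x/2√(Dt) + √(λt))],
  with the growing exponential routed through erfcx so it cannot overflow.
* **Strip source** (`conc_strip`): exact Duhamel solution of the 2D
  half-plane problem with Dirichlet data c₀·f(t) on the strip |y| ≤ L_y,
  0 outside (see README for the integral). It reduces to the 1D form when
  L_y ≫ √(Dt) and obeys the maximum principle 0 ≤ c ≤ c₀.
* **Box source** (`conc_box`): triple erfc-product Green's superposition
  for a constant volumetric generation rate r₀ [M/s] in a box inside an
  infinite domain.

### Quadrature

The strip integrand has an essential singularity at τ → 0. Substituting
u = x/(2√(Dx·τ)) maps it to ∫ e^(−u²)·(bounded factor) du on
[x/2√(Dx·t), ∞), which `scipy.integrate.quad` handles routinely at
relative tolerance 1e-9 (absolute 1e-14, 200 subdivisions). x = 0 is
returned as the boundary value directly (c₀f(t) inside the strip, half
that on the strip edge, 0 outside). The lateral bracket is evaluated at
|y| so the y-symmetry of the kernel is exact in floating point. The box
integrand is bounded and is integrated in τ directly.

### Uncertainty in D

D = 6 × 10⁻⁶ cm²/s with half-width σ_D = 3 × 10⁻⁶ cm²/s (drug
diffusivity in water; the wide band absorbs the unknown effect of egg-white
proteins). Propagation is by three-point evaluation at D − σ, D, D + σ:
cheap, exact for monotone response, and safe where the response is not
monotone because the band is taken as min/max of the three values. The
band is attached to every profile row and exposure series; classification
against thresholds uses the central value, with a secondary
"uncertain" flag when the band straddles the LOEC.

## Source term and calibration

A 2 × 2 × 3 mm agar block soaked with 3 µL of 1 mM atropine or 2 µL of
0.1 M carbachol. The boundary concentration c₀ is under-determined by
that description, so three conventions are exposed
(`Calibration`): `volumetric` = injected moles / block volume (the stated
rule; 2.5 × 10⁻⁴ M for the AT block), `diluted` = moles / (block + soak
volume) (2.0 × 10⁻⁴ M), `soak` = the soak molarity (10⁻³ M). Two
evaluator geometries are exposed: `strip` (physical lateral half-width
L_y = 1 mm) and `axial` (wide-lateral 1D form in the Euclidean distance
from the releasing face).

Calibrated against the reported head exposures at 2 mm (1.09 × 10⁻⁴ ±
1.4 × 10⁻⁵ M at 2 h, 1.268 × 10⁻⁴ ± 1.45 × 10⁻⁵ M at 4 h):

| convention, geometry | 2 h | 4 h |
|---|---|---|
| volumetric, axial | 1.241e-4 | 1.576e-4 |
| **diluted, axial** | **0.992e-4** | **1.261e-4** |
| volumetric, strip | 0.575e-4 | 0.651e-4 |
| soak, strip | 2.30e-4 | 2.61e-4 |

Only (`diluted`, `axial`) lands inside both reported bands (volumetric/
axial is ~14% high, just outside). The physical strip bracket attenuates
roughly two-fold too much — consistent with the reported values having
been computed with a quasi-1D longitudinal form — and at 2 mm its steady
state (0.295·c₀) never reaches the AT LOEC at all, so the "effective
concentrations reached in < 3 h" observation is only reproducible under
the wide-lateral convention. Everything that reproduces reported numbers
therefore uses (`diluted`, `axial`); the forward-modelling default stays
(`volumetric`, `strip`) because it follows the stated physical rule.
Far-field reported values (e.g. 3.05 × 10⁻⁷ M at 1 cm) are not
reproduced by any convention; the geometry there is under-specified, and
no claim is made about them.

## Embryo kinematics

Growth is linear, L(t) = L₀ + v·t, with v derived from the anchor
lengths: EA, (5 − 1.04)/30 = 0.132 mm/h; EB, (2.9 − 1.5)/9 = 0.156 mm/h.
Staging interpolates HH stage linearly between the anchors (20 h → HH4,
24 h → HH6, 33 h → HH10, 50 h → HH14-15) and reports the nearest label;
times outside [20, 50] h are rejected.

Structure positions (JSON data files, editable) use two rule types: EA
structures interpolate between two measured anchor offsets (the hind-head/
heart locus runs 0.2 mm → 1.4 mm from the top over 30 h); EB uses the
fraction rule (heart at 2/5 of body length). Both parameterizations are
implemented; EA uses its anchors because they are directly measured.
T-labels are interpreted as hours after agar placement (EA: T30 = 50 h
incubation). The one time label that is inconsistent under any single
convention ("T8, 33 h incubation" in series EB, which starts at 24 h) is
treated as a typo and not modelled.

Placement geometry: the embryo axis is collinear with the source x-axis
for cephalic (A) and caudal (B) placements; lateral classes (C–F) add a
signed y-offset. The placement's reference structure — head for
cephalic-side, tail for caudal-side classes — holds the printed distance
while the rest of the body extends away from the source, matching the
observation that with a cephalic source the head keeps its distance and
the caudal end recedes.

## Exposure assessment

Series are evaluated on a 0.1 h grid over the series duration (default;
configurable). `time_to_threshold` takes the first grid time at or above
the LOEC and refines it by bisection on the continuous evaluator to
0.01 h. Events carry point time-labels; each is widened to a ±1 h window
(clipped at 0) for the exposed/not-exposed call. Whether the reported
"average concentrations" are spatial means over a segment or point values
is not stated; `segment_average` implements the spatial mean and reports
note the distinction. Event rows are joined with the observed
interference flags for each drug (the antagonist interferes with all nine
listed inductive events, the agonist with three), so the model output and
the observed outcome sit side by side.

## Finite-difference oracle

A deliberately plain explicit solver, used only to verify the analytic
evaluators. 2D: 5-point Laplacian, Dirichlet strip on the x = 0 edge with
edge cells weighted by their covered fraction (a node exactly on the strip
edge gets c₀/2, the analytic half-value), zero-value far boundaries at
5 diffusion lengths, time step at 90% of the stability bound, decay
applied as an exact exponential split step. Documented configuration:
D = 6e-6 cm²/s, c₀ = 2.5e-4 M, L_y = 1 mm, dx = dy = 0.01 cm (~104 × 227
nodes), dt = 4 s, probes on and off axis at 0.5–2 h, at least two
diffusion lengths from the far edges with the comparison denominator
floored at 10⁻³·c₀ — max relative error 0.37%, and a three-level
refinement study (dx = 0.04, 0.02, 0.01 cm) decreases monotonically. 3D
box verification: 81³ nodes with volume-weighted source cells, max error
0.49% at five probes. These sizes keep each oracle test under ~3 s.

## Synthetic experiments

The generator emulates the study design: groups of 60 eggs, placements
drawn with the observed 70% cephalic+caudal bias (A and B at 0.35 each,
the four lateral classes sharing 0.30), distances uniform on 2–10 mm,
lateral offsets 1–3 mm. Lengths are Gaussian about the growth line with
sd equal to the printed spreads (EA: 0.2 mm at start, 0.5 mm at the end),
truncated at zero. The drug response is deliberately minimal plumbing: a
growth-velocity multiplier, logistic in log₁₀(exposure/LOEC) above the
LOEC, saturating at 0.7 for the antagonist and 1.25 for the agonist.
Only the direction and the LOEC gating are observation-driven; the slope
(k = 2 per decade) and saturations are package choices, because the study
reports direction and significance, not a dose–response curve. A single
master seed drives all draws and is recorded in every output row.

What the generator does **not** emulate: mortality and seasonal anomaly
rates, somite-count staging, axis curvature, measurement error in the
georeferencing, or any biochemical readout. Passing recovery tests
therefore show that the estimation machinery is unbiased and adequately
powered under the stated noise model — not that real embryos obey it.

The recovery study (100 replicates, 60 eggs split between the first and
last sampling time, 0.3 mm noise) recovers the growth velocity within 15%
of truth in ≥ 90% of replicates; analytically the slope's standard error
under that design is ~0.0026 mm/h, so the 15% band is ~7.7 standard
errors and the criterion has large margin.

## Degenerate inputs and tie-breaks

t = 0 returns exactly 0 away from the source; x = 0 returns the boundary
value (half-value on the strip edge); zero soak volume gives c₀ = 0 and
an identically zero field; σ_D ≥ D is rejected; unstable FD steps are
rejected before stepping; unknown config keys are rejected rather than
ignored. `stage_at` snaps interpolated stages onto anchor labels when the
half-unit rounding lands on one.

## Known limitations

* The quasi-2D reduction ignores vertical attenuation; absolute far-field
  values are not trustworthy under any exposed calibration.
* Linear growth and straight-axis geometry are coarse beyond ~stage 12,
  when flexion begins.
* The LOEC comparison uses the central concentration; the band-aware
  "uncertain" flag is reported but not propagated into a probabilistic
  classification.
* Anisotropic or concentration-dependent D, swelling/erosion release
  kinetics and explicit albumin-binding chemistry are out of scope (R and
  f(t) are the only hooks).
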