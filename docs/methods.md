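# Methods

`discflux` simulates how mechanical loading shapes nutrient transport in
the human intervertebral disc.  Three models are coupled sequentially: a
large-strain biphasic (poromechanical) model of the disc and adjacent
vertebrae, an advection–diffusion–reaction model for oxygen and lactate on
the disc subdomain, and a cell-metabolism model closing the reaction terms.
This note records the governing equations, the parameter choices that are
genuinely ours, the numerical decisions, and what the synthetic geometry
does and does not represent.

## Poromechanics

The tissue is a saturated mixture of an intrinsically incompressible solid
skeleton and incompressible water.  Total stress splits into effective
solid stress and pore fluid pressure,

    sigma = sigma_eff(F) − p I,       p = mu_w + Delta_pi,

where `mu_w` is the water chemical potential (the continuous FE unknown)
and `Delta_pi` the osmotic swelling pressure of the nucleus, held constant
during deformation (0.15 MPa healthy, 0.05 MPa degenerated, zero
elsewhere).  The solid matrix is compressible neo-Hookean,

    W = G/2 (Ī₁ − 3) + K/2 (J − 1)²,    Ī₁ = J^(−2/3) tr(FᵀF),

with the printed region moduli G, K.  The annulus adds a tension-only
exponential fibre term along two criss-crossed families (±γ from the
transverse plane in the lamellar surface),

    W_f = Σ_α k₁/(2 k₂) [exp(k₂ ⟨I₄α − 1⟩²) − 1].

Fluid flow obeys Darcy's law with strain-dependent permeability: the
single-exponent law `k = k₀ exp(M (J − 1))` in NP and annulus (only M is
tabulated there) and the combined power/exponential law
`k = k₀ ((J − 1 + φ₀)/φ₀)^L exp(M (J² − 1)/2)` in the cartilage endplate
(the only region with both exponents).  Bone permeabilities are
strain-independent.  Porosity follows `φ = 1 − (1 − φ₀)/J`.

Mass balance in the total-Lagrangian frame,
`dJ/dt + Div(−J F⁻¹ k F⁻ᵀ Grad mu_w) = 0`, is discretised with backward
Euler and Taylor–Hood P2/P1 triangles (axisymmetric) or lines (benchmark
column) — an inf-sup stable pairing; the benchmark column shows no
pressure checkerboarding and matches the Terzaghi series to <1% L2.
Newton's method uses an element-wise central-difference tangent (forward
differences lose the quadratic rate in the nearly-incompressible
small-time-step limit), lazy re-factorisation, backtracking only on
element inversion or gross residual growth, automatic step subdivision,
and — under sinusoidal loading — a factorisation cache keyed by cycle
phase.  Reported fluid velocity is the seepage (pore fluid) velocity
`v = −k grad mu_w / φ`, the quantity that measures advective particle
transport.

Boundary conditions: bottom vertebral surface axially fixed, symmetry
axis radially fixed, uniform nominal compressive traction on the top
surface, and free drainage (`mu_w = 0`) on the vascularised outer annulus
surface.  The vertebral fluid route is closed by default (the calcified
endplate's pressure-driven fluid exchange is contested in the literature,
and opening it makes the simulated creep faster while the sustained-creep
magnitude is already above the in-vivo range); the drained facet set is a
configuration field, so the fully drained vertebral variant remains one
switch away.  Every
run starts from a free-swelling initialisation: osmotic pressure and a
0.1 MPa resting preload are ramped over 60 s and held until the height
rate falls below 0.01 %/h; that state is the reference for height
changes, matching the convention that the resting disc is the baseline.

## Transport and metabolism

Oxygen (tracked as partial pressure, kPa) and lactate (nmol/mm³ ≡ mM)
obey the tissue-averaged continuity equation

    dc/dt + v·grad c = div(D(φ) grad c) + R,

on the NP+annulus subdomain with quadratic elements, implicit Euler, and
streamline-diffusion (SUPG-type) stabilization of the advective term.
Diffusivity follows Mackie–Meares, `D = D_w (φ/(2 − φ))²`, from the
current porosity when the strain coupling is on, else from `φ₀`.
Dirichlet values hold 5.8 kPa / 0.9 nmol mm⁻³ at the outer annulus edge
and 5.1 kPa / 0.8 nmol mm⁻³ on the endplate interface, which spans the
full disc footprint (the cartilage layer covers nucleus and annulus
alike; restricting the supplied area to the NP + inner-annulus footprint
starves the mid-height outer annulus far below the ~1 kPa oxygen floor
observed in vivo).  Initial interior values are zero.  On a
deforming mesh, the previous-geometry mass matrix multiplies the previous
concentration, which conserves solute content exactly under compaction
with closed boundaries; an advective Courant check subdivides transport
increments when the locally refined endplate layers would otherwise see
C > 1.

Metabolic rates per cell follow the disc-cell culture regressions:

    oxygen consumption = 7.28 pO₂ (pH − 4.95) / (1.46 (pH − 4.95) + pO₂)
                         [nmol /10⁶ cells/h]
    lactate production = exp(−2.47 + 0.93 pH − 0.21 pO₂ + 0.016 pO₂²)
                         [nmol /10⁶ cells/h]
    pH = 7.5 − 0.1 · c_lactate   (clipped to [6.0, 7.6])

Lactate production falls with rising oxygen over the physiological range
(oxygen partly suppresses glycolysis) — required for the model's central
mechanism, in which shortened diffusion distances raise oxygen *and*
depress lactate — and falls as the tissue acidifies.  Oxygen units are
converted through a solubility of 1.0268e-2 nmol mm⁻³ kPa⁻¹.  The update
is staggered per coupling increment: oxygen consumes with the previous
pH, lactate produces from the new oxygen, and the new lactate sets the
pH for the next increment; swapping the order changes probe values by
<0.1% at the default increments, and the sensitivity shrinks linearly
with the increment.  Oxygen consumption is applied semi-implicitly
(Michaelis–Menten denominator lagged), which keeps the step positive;
quadratic interpolation can undershoot a few percent of the boundary
jump while the initial sharp layer diffuses, so concentrations are
clipped at zero and the run aborts if the undershoot ever exceeds 10% of
the boundary scale.

**Volumetric rate scale.** The tabulated cell densities
(e.g. NP 0.032 ×10⁶ cells/mm³) are an order of magnitude above the
human-disc densities measured after viability correction
(~3.2 ×10³ cells/mm³ for NP).  We keep the tabulated values as the
user-facing parameters and multiply them in the reaction terms by one
documented constant, `METABOLIC_ACTIVITY = 0.05`, calibrated once so the
healthy unloaded disc's minimum oxygen tension matches in-vivo
microelectrode measurements (~0.7–1 kPa at the disc centre).  This is
the only calibrated metabolic constant; it scales consumption and
production together.

## Geometry

The full-scale L4–L5 geometry is represented parametrically as an
axisymmetric section of an equivalent-area cylinder: the 50 × 35 mm
in-plane ellipse becomes a circle of equal area (radius 20.9 mm), with
the nucleus occupying 40% of the in-plane area, the annulus split evenly
into inner/outer rings, 0.8 mm cartilage endplates, 0.6 mm bony
endplates and 4 mm vertebral blocks (trabecular core, 1.5 mm cortical
rim).  Disc height is 13.7 mm (healthy) or 12.3 mm (degenerated; the
degenerated disc is the healthy section scaled axially by 0.9).  The
axial spacing inside the disc is graded so the element layer adjacent to
each endplate is ~0.1 mm — the drainage boundary-layer depth of a 60 s
load ramp — which is what makes the near-endplate fluid velocities
observable at all; peak fluid speed remains a discretisation-limited
quantity (the continuum oscillatory boundary layer at 1 Hz is microns
thick) and is reported at this stated resolution.  Probes sit at the
geometric centre (central NP) and at mid-height, mid-thickness of the
outer annulus (the anterior-annulus probe of the full 3D disc).

What the axisymmetric reduction cannot represent: the anteroposterior
asymmetry (anterior vs posterior annulus), the posteriorly offset
nucleus, lordotic wedging, and any circumferential variation.  Passing
desk-scale checks therefore demonstrates mechanism and direction, not
patient-scale absolute accuracy; all probe distances are preserved only
in order of magnitude.

## Fibre calibration

k₁, k₂ and the lamellar angles are not tabulated.  A sweep
(`scripts/calibrate_fibres.py`) against the sustained-compression creep
response shows the *instantaneous* (undrained) height loss is
fibre-controlled, while the multi-hour creep is controlled by the
drainage rate: with the tabulated moduli the drained skeleton is far
softer than the 0.5 MPa load, so the 7 h state is set by boundary-layer
consolidation and saturates near 21–22% height loss for any fibre
stiffness on this geometry (in-vivo and paper-scale values are
10–15%).  Defaults k₁ = 20 MPa, k₂ = 100, angles 35°/25° (inner/outer)
put the instantaneous response at ~4% and sit inside the published range
of annulus fibre angles (24–46°).  The residual creep overshoot is a
known limitation of the simplified geometry and constant-swelling
assumption, not a tunable.

## Scenarios and couplings

The diurnal protocol applies 16 h at 0.5 MPa and 8 h at 0.1 MPa per day
(60 s ramps), repeated for two days, with solutes starting from zero.
Mechanics and transport exchange geometry, porosity and velocity every
60 s in the half hour after each load transition and every 900 s inside
plateaus (halving the cadence changes probe values by <0.5%); cyclic
runs exchange once per load cycle.  Coupling modes are independently
switchable: *undeformed* (no mechanics, φ₀ diffusivities),
*distance-only* (mesh scaled axially by the mechanical height history,
diffusivities frozen — isolates the diffusion-distance effect),
*deformed* (displaced mesh; strain-dependent diffusivity and advection
as further toggles), and a constant-pH override (7.1) that decouples
oxygen consumption from lactate.  The cyclic scenario applies 0.5 MPa ±
{0, 0.1, 0.2} MPa at 1 or 0.1 Hz (≥20 implicit steps per cycle) from the
preconditioned end of the two-day diurnal run.  The sensitivity driver
varies one property group at a time (porosity, cell density, constant pH
6.2, endplate permeability, solid stiffening, swelling pressure, and
endplate stiffnesses), reusing the base mechanical solution whenever a
variant alters only transport or metabolic fields, and normalises
end-of-day-2 probe concentrations to the base model.  Regional values in
that table are probe-based (the two probe nodes), not volume averages.

## Numerical and reporting choices

Units are mm–N–MPa–s in mechanics, kPa and nmol/mm³ for solutes, hours at
reporting surfaces only, converted in `discflux.units`.  Desk-scale runs
use mesh resolution level 1 (~300 elements); the acceptance script runs
the full study at that level in roughly a quarter hour, with the 1 Hz
cyclic comparisons evaluated on a 200–400 s window (their peak fluid
speed saturates within the first ~40 s of cycling, which the recorded
velocity trace shows directly).  Porosity evaluation clamps at a 1%
floor in heavily squeezed boundary-layer elements (the tabulated annulus
permeability exponent is too weak to forbid local over-compaction that
the real tissue's pore-closure would prevent).  There is no randomness
anywhere in the pipeline; reruns are bit-reproducible given the same
configuration.

## Known limitations

* Absolute creep magnitude overshoots the in-vivo 10–15% (see fibre
  calibration); consequently distance-driven solute effects overshoot in
  magnitude while reproducing sign and ranking.
* Solute equilibration from zero initial conditions reaches quiescence
  (0.5%/h criterion) in ~10 h for oxygen on this geometry, faster than
  the 16–18 h of the full 3D disc — the equivalent-area cylinder
  shortens the slowest (anteroposterior) diffusion path.
* The constant-pH sensitivity variant changes oxygen consumption by tens
  of percent through the (pH − 4.95) factor; models in which this
  variant has a small effect must use a weaker pH coupling than the
  published rate law we implement.
* Swelling pressure is constant (no fixed-charge-density dependence), as
  assumed; glucose, cell death and matrix remodelling are out of scope.
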