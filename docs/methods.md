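# Methods

`ocuflow` simulates the electro-fluid-structure interaction (EFSI) of the
human conventional aqueous outflow pathway at desk scale: aqueous humor
driven by an intraocular-pressure (IOP) ramp through an idealized trabecular
meshwork (TM) / juxtacanalicular tissue (JCT) / Schlemm's-canal (SC)
inner-wall complex whose surfaces carry a charged endothelial glycocalyx.
This note records the model, the synthetic geometry, the numerical choices,
and the limits of what the package's tests demonstrate.

## Synthetic geometry

No tissue-resolved imaging geometry is distributed with the package; the
flow domain is generated. The default is a plane-2D slice with the flow
axis x:

- an anterior-chamber vestibule (fluid, 20 µm long, full height);
- a fluid channel of height 2 µm bounded above and below by 8 µm elastic
  tissue bands, running through a TM zone (120 µm) and a JCT zone (14 µm);
- an SC inner wall (2.2 µm thick) closing the channel, perforated by pore
  gaps of width 1.3 µm.  The printed areal pore density (835 pores/mm²)
  maps in 2D to a wall-gap spacing of 1/√835 mm ≈ 34.6 µm; with the
  default 2 µm channel a single centered gap results.  The planar patch
  generator (`place_inner_wall_pores`) retains the exact areal contract:
  `round(density × area)` pores on a centered lattice, with an optional
  seeded jitter under a hard non-overlap guarantee.

The TM microstructure (beams and inter-beam spaces) is homogenized into a
single open channel bounded by elastic tissue; resolved beams are out of
scope.  The channel height was chosen once so that the peak aqueous
velocity at 15 mmHg lands in the tens of mm/s, the scale reported for
microstructural outflow models; it also puts the Reynolds number near 0.05,
consistent with creeping flow.  Meshes are structured conforming
right-triangle grids whose lines are snapped to every material interface,
so region labels and facet tags (inlet, open outlet, glycocalyx wall,
symmetry, anchor) are reproducible functions of position; near-wall
refinement regenerates the grid from stored metadata and therefore
preserves tags exactly.

## Electric double layer

The glycocalyx (~109 nm) is represented as a charged boundary condition:
the zeta potential ζ = −19.5 mV is imposed on every tissue-fluid facet and
the quiescent potential obeys the linearized Poisson-Boltzmann
(Debye-Hückel) closure ∇²Φ = κ²Φ, ρ_f = −εκ²Φ, E = −∇Φ, with ε = 99 ε₀.
Linearization is appropriate because |ζ| is below the 25.7 mV thermal
scale.  P1 elements with a lumped Helmholtz term keep the discrete maximum
principle on the right-triangle meshes; the solver is verified against the
closed form Φ = ζ cosh(κy)/cosh(κh) to <0.1% and converges at second
order.

The Debye length κ⁻¹ is a configuration parameter because the source
constants include no ionic strength.  Its physical default is 10 nm
(physiological saline).  The canonical scenario suite instead uses an
enlarged κ⁻¹ = 2 µm: a deliberate scale model that makes the double layer
resolvable at the 0.5 µm default element size.  All scenario-level
comparisons in the acceptance suite are qualitative orderings that do not
depend on the specific Debye value.

## Fluid

Aqueous humor is Newtonian, homogeneous and laminar (ρ = 1000 kg/m³,
µ = 0.7185 mPa·s) and satisfies incompressible Navier-Stokes with the
electric body force entering, as in the source momentum balance, with a
negative sign (−ρ_f E; `force_sign` flips to the conventional
electrokinetic +ρ_f E for sensitivity runs).  Discretization: equal-order
P1-P1 velocity-pressure with Brezzi-Pitkäranta pressure stabilization
(α = 0.05, element scale √(2A)), implicit Euler at dt = 0.01 s, Picard
linearization of convection with a fresh-Stokes restart guard.  Boundary
conditions: a normal-traction inlet carrying the linear 0→15 mmHg, 1 s IOP
ramp; an open outlet with zero normal stress (f₀ = 0) at the pore exits;
no-slip (optionally moving-wall) glycocalyx boundaries; free-slip symmetry
planes on the lateral cuts.

Two consequences of the Debye-Hückel closure shape the electric results.
First, the quiescent body force is an exact gradient, ±∇χ with
χ = εκ²Φ²/2 the double-layer osmotic pressure, so in an incompressible
flow it is (analytically) absorbed into pressure.  Open boundaries that cut
through the double layer therefore carry χ in their normal-stress condition
— applying f₀ = 0 to the purely mechanical pressure would let the truncated
layer act as an artificial boundary pump of ~2×10⁻⁵ relative magnitude.
Second, what remains of the EFSI-vs-FSI velocity difference is the O(h)
non-gradient residual of the elementwise force product ρ_f E concentrated
at the pore constriction: ~4×10⁻⁵ relative at the default resolution.  The
flow the charge drives on its own (EFSI at 0 mmHg) comes from the same
residual and measures ~0.004 mm/s against ~20 mm/s at 15 mmHg — the
"negligible but nonzero" regime.  Electroviscous (streaming-potential)
retardation is genuinely negligible here: at the printed conductivity
(179×10⁻⁴ Ω⁻¹cm⁻¹) it scales to O(10⁻⁸) of the driving force.

Dropping the convective term changes the peak velocity by ~0.8%: the
inertial correction is set by the jet through the 1.3 µm pore orifice at
15 mmHg (orifice Reynolds number ~0.05) and is therefore fixed by the
printed constants rather than by mesh or geometry choices.  Convection
stays on by default.

## Tissue

TM, JCT and SC inner wall are isotropic linear-elastic (E = 4, 4,
7.48 kPa; ν = 0.495) in plane strain.  The stress splits into an elastic
part σ_t = λeI + 2µ_s ε(u_t) and an interstitial part σ_i = −P_i I, with
equilibrium ∇·(ε_t σ_total) = 0; the volume fraction ε_t defaults to 1 per
region, reducing to standard equilibrium.  Near-incompressibility is
handled with a two-field mixed (Herrmann) formulation, p_s = λe, P1-P1 with
weak pressure-gradient stabilization; the volumetric strain used in stress
recovery is the mixed p_s/λ, the locking-free quantity at ν → 0.5.  The
confined-slab closed form is reproduced to machine precision at both
ν = 0.3 and ν = 0.495 (constant-strain patch consistency), anchored
reactions balance applied loads to 10⁻¹², and external work equals stored
energy to solver precision.

P_i is the fluid pressure extended into the tissue from the interface by
nearest-interface-node lookup (no interstitial Darcy model is closed by the
available constants); the tissue continuity statement ∂e/∂t = ∇·V_t is
honored diagnostically through V_t = Δu_t/Δt rather than as an extra field
equation.

The ciliary pre-tension (~500 µN resultant) is applied as a statically
equivalent distributed tangential traction along the lateral TM boundary.
The force-to-line-load conversion uses an out-of-plane depth of 36 mm, the
circumference of the TM ring: the resultant loads the whole 360° band and a
plane slice carries its per-length share (~14 µN/mm).  With a 1 mm depth
the same resultant would produce ~0.4 mm displacements, far outside the
small-strain regime of this geometry.

Reported stress/strain maxima occur at re-entrant corners of the idealized
geometry (pore mouths, constriction corners), where linear-elastic fields
are singular; the maxima are therefore mesh-dependent diagnostics, useful
for scenario-to-scenario comparison on a fixed mesh but not as pointwise
physical values.

## Coupling

Each time step transfers the consistent nodal fluid traction (Dirichlet
reaction forces) and the interstitial pressure to the tissue; the interface
sub-iteration (`couple_step`) is a Dirichlet-Neumann fixed point with
fixed, Aitken, or Anderson (depth-5 quasi-Newton) relaxation, verified
against a directly assembled monolithic solution on manufactured linear
interface problems — including spectral radius above one, where plain
iteration diverges and Anderson still solves the interface system.

The reverse transfer — tissue interface velocity as a moving no-slip fluid
wall — is implemented but off by default
(`ScenarioConfig.wall_motion_feedback`).  With a fixed fluid mesh and an
inertia-free (quasi-static) solid, the Dirichlet-Neumann partition of an
incompressible fluid against a massless structure is added-mass unstable as
dt shrinks; at dt = 0.01 s the measured in-step gain crosses 1 during the
ramp.  The physical magnitude of the feedback here is ~3×10⁻⁵ of the flow
speed (sub-µm displacements over a 1 s ramp), and enabling it at dt = 0.1 s
(where the sub-iteration converges) changes the scalar outputs by <0.1%,
which is the quantitative basis for the stationary-wall default.  When the
feedback is on, the convective linearization is frozen during the
sub-iteration (so the fluid map is affine) and re-linearized in an outer
loop.

## Scenarios and reported scalars

The canonical trio — FSI at 15 mmHg, EFSI at 0 mmHg, EFSI at 15 mmHg — runs
on one shared mesh (identical digest) with 100 steps of 0.01 s.  Per step
the pipeline records max velocity (mm/s), max pressure (mmHg), max first
principal stress/strain (kPa, %), max shear stress/strain (kPa, %), the
nodal-averaged TM displacement (µm; unweighted mean of nodal magnitudes,
with a volume-weighted option), and the boundary flux balance.  Maxima are
reported at the final (peak-IOP) step; the time of the spatiotemporal
velocity maximum is also logged.  EFSI with ζ = 0 retraces the FSI solution
path bit-for-bit (the electric terms vanish identically), runs are
deterministic (hash-stable), and every accepted flow solution balances
boundary fluxes to better than 10⁻⁶ of the gross flux (global mass
conservation is exact in the stabilized formulation because the constant
pressure mode is unstabilized).

## Problem sizes and tolerances

Defaults used by the tests and the acceptance script: outflow mesh at
0.5 µm resolution (~23k triangles, ~9.6k fluid unknowns), 100 time steps
per scenario, coupling tolerance 10⁻⁶, Picard tolerance 10⁻⁸, direct sparse
LU throughout.  Oracle meshes: 4×64 channel for the double-layer solve
(κh = 1), a wall-graded 4×110 channel for the electroosmotic check
(κh = 50, first layer κ⁻¹/10, growth 1.1), 96×48 for Poiseuille, 12×12 for
the slab.  The full canonical suite takes on the order of two minutes on
one CPU.

## What the synthetic setting does and does not show

The generator reproduces the printed layer thicknesses, pore statistics,
material and electrical constants, and loading protocol, but not the
eye-specific microstructural geometry: absolute magnitudes (velocities,
stresses, displacements) are specific to the idealized slice and its
homogenized TM channel.  Passing tests demonstrate solver correctness
against closed forms, exact degeneracies, conservation, determinism, and
the qualitative scenario orderings (charge slows the outflow slightly;
charge alone moves aqueous but negligibly; the biomechanical role of the
charge is minor).  They do not validate outflow-facility magnitudes for
real eyes, segmental flow, viscoelastic or anisotropic tissue behavior, or
spatially varying glycocalyx thickness.
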