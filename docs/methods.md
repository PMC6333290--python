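# Methods

## Model

`shearswim` simulates a virtual monoflagellate: a rigid prolate spheroidal
cell body (major × minor axes 11 × 3.5 μm by default) carrying a single
anterior flagellum of length L = 13 μm whose planar beat is kinematically
prescribed in the swimmer-fixed frame,

    x1 = ξ,  x2 = A [ sin(2πξ/λ + 2πft) − sin(2πft) ],  x3 = 0,

with amplitude A = 1.8 μm, wavelength λ = 13 μm and frequency f = 28 Hz.
The subtraction pins the flagellar base to the body pole; the upper
parameter bound ξ*(t) is found by bracketed root-finding on an adaptive
arclength quadrature so that the centerline length is exactly L at every
instant (inextensible flagellum, conserved to 10⁻⁸ relative).  The wave
travels tip-to-base, making the swimmer a hydrodynamic puller whose
morphology and beat match the *Leishmania mexicana* promastigote; running
the beat backwards yields the morphologically identical pusher.  There is
no elastohydrodynamics: the beat shape is data, not the solution of a
force balance.

The ambient fluid is Newtonian Stokes flow (viscosity of water at 25 °C,
8.9×10⁻⁴ Pa·s) with an optional linear background shear — bulk
u_b = γ_d(x̂2, 0, 0), or wall-bounded u_b = γ_d(0, −x̂1, 0) vanishing on the
no-slip plane x̂1 = 0 — and an optional short-range repulsive wall force
per unit area f_wall(s) = g(μ/T_d) e^{−s/l}/(1−e^{−s/l}) n̂ with g = 1250
and l = 0.2 μm, s the local wall separation and T_d the beat period.

## Discretization

The swimmer surface is a watertight genus-0 triangulation built from
structured rings (far body pole → body rings → attachment rim → flagellar
tube → capped tip), stitched across unequal ring counts by an azimuthal
zipper.  The default level yields ~636 elements, matching the ~644-element
resolution the model was designed around; coarser and finer levels exist
for sweeps and convergence checks.  Ring radii are chord-compensated
(inflated by (π/n)/sin(π/n)) so the faceted surface carries the area — and
hence the viscous drag — of the smooth body; the default-level body area is
then within 0.9% of the closed-form prolate-spheroid area.  Flagellum nodes
are material points (fixed arclength fraction and tube azimuth); their beat
velocities come from central finite differences of position over 10⁻³ of a
beat period (verified second-order).  Tube section frames use the planar
curve normal and the out-of-plane binormal, so there is no frame twist.

The mobility problem uses a first-kind single-layer boundary integral with
piecewise-constant tractions collocated at element centroids.  The density
is the traction jump, so the force/torque-free closure appends six
constraint rows (∫q dS = −F_ext, ∫r×q dS = −T_ext) and six rigid-body
unknowns (U, Ω).  Singular self-element integrals use a polar (Duffy)
split at the collocation point that cancels the 1/r singularity exactly
(3 subtriangles × 4×4 Gauss); near-singular panels — judged by distance to
the panel or, for the wall kernel, to its image — are subdivided
adaptively (4-way, depth ≤ 3) with a 3-point rule per leaf.  The wall
kernel is the Blake image system (stokeslet + image + potential dipole +
stokeslet doublet), which vanishes on the wall to machine precision.  The
single layer is blind to the constant-normal density; a rank-one deflation
along that mode conditions the dense LU solve without changing velocities,
loads, or the exterior flow.  One factorization serves many right-hand
sides, which is what makes phase averaging and shear sweeps cheap.

Oracle accuracy at the resolutions used in the test suite: sphere drag
within 1–2%, free sphere advected exactly by a uniform flow, sphere spin in
shear within 1%, passive-spheroid in-plane rotation within 2% of Jeffery's
closed form, (U, Ω) affine in γ_d to 10⁻⁶.

Trajectories advance with Heun's method (explicit trapezoidal, measured
global order ≈ 2), dt defaulting to 1/100 of the beat period, orientation
by quaternion exponential with renormalization.  Against a passive wall the
run halts at 2 nm minimum surface clearance; contact occurring inside one
step (a panel crossing the plane) also halts.  All quantities are
dimensional (μm, s, Pa·s) — a consistent unit system in which matrix
entries are O(1)–O(10), used instead of a formal nondimensionalization.

## Phase-averaged reduction

Phase averaging means the arithmetic mean of the mobility solution over
(typically) 20 equispaced beat phases at frozen position and orientation.
In the bulk, frame invariance plus Stokes linearity reduce everything to
one factorization per phase with ten right-hand sides (the beat and the
nine unit velocity-gradient tensors); any planar orientation θ and shear
rate γ_d then evaluates without further boundary-element work
(`BulkPhaseTable`).  Near the wall the geometry is θ- and h-dependent, so
each grid node costs n_phases Blake solves with two right-hand sides (beat
and unit shear), giving a field exactly affine in γ_d; one grid scan covers
every shear rate.

The reduced bulk angle obeys θ̇(θ) extremely close to the Jeffery form
γ(r² sin²θ + cos²θ)/(r²+1) (θ clockwise from the flow axis): fitting
T = (2π/γ)(r + 1/r) to quadrature periods at γ_d ∈ {0.25, 0.5, 1} s⁻¹
yields an effective aspect ratio r ≈ 5.2 at the default resolution, with
γ·T constant to 10⁻¹¹ (exact Stokes linearity) and a pointwise orbit
residual against the equal-period Jeffery orbit of a few 10⁻³ rad.  The
rotation period across body scalings 0.25–1.5 (flagellum fixed) is maximal
at scaling 1.0 — the typical promastigote body.

Known approximation error: the frozen-configuration average neglects the
coupling of intra-beat translation and yaw with the beat itself.  For this
beat (surface speeds up to ~350 μm/s) the phase-averaged free-space speed
(15.6 μm/s at default resolution) exceeds the true one-beat
net-displacement speed (14.0 μm/s, dt-converged) by about 10%; reduced
trajectories inherit a bias of that order.  Full-vs-reduced comparisons in
the guidance tests use tolerances set by this measurement.

### Swimming-speed note

Two independent methods — the boundary-element solver and a
resistive-force-theory calculation (Gray–Hancock coefficients with exact
prolate-spheroid resistances) — agree that the beat above propels the
default swimmer at ~13–17 μm/s, robust to mesh, time step, and the choice
of material vs fixed-ξ surface velocities.  The 1.5–2 μm/s band sometimes
quoted for this morphology is not reproducible from these beat parameters;
`shearswim` reports the computed value.

## Wall phase plane

The reduced wall system (θ̇, ḣ) is interpolated with periodic cubic splines
in θ and cubic splines in h on a default grid of 24 angles × 16 log-spaced
heights (tests use 16 × 12 up to h = 120 μm; the coarsest mesh level).
Configurations that would intersect the wall at any sampled phase are
flagged invalid and filled from the nearest valid height (the flags, not
the fill, are authoritative).  Note the parallel-orientation clearance
envelope is 2A + tube radius ≈ 3.65 μm — the pinned-base term doubles the
beat swing — so heights below ~3.7 μm are resolvable only by the full
beat-resolved solver.

Fixed points are located by damped Newton iteration on the spline field
from every grid node (tolerance 10⁻¹⁰ of the field scale) and classified by
finite-difference Jacobian eigenvalues.  At γ_d = 1 s⁻¹ the system has a
single saddle (real eigenvalues of opposite sign) at θ* ≈ 1.48π, robust to
mesh level, phase count and grid; under γ_d ↦ −γ_d it maps to 2π − θ*
exactly (mirror symmetry, verified to 10⁻³).  The saddle height falls
monotonically with shear.  Its stable manifold, integrated backward from
±ε along the stable eigenvector, closes a homoclinic separatrix dividing
collision-bound from bulk-bound configurations: probes 12% below collide,
12% above survive (ten per side in the tests).  "Escape" above the
separatrix is a bounded tumbling orbit (h cycling with θ advancing), so the
classifier counts surviving a full tumble as escape alongside leaving the
resolved heights upward.

θ-orientation caveat: with the background-flow formulas above and the
convention that θ̇ > 0 in the bulk, the saddle appears near 3π/2 and the
downstream-facing boundary attractor near π/2.  The mirrored labelling
(saddle near π/2, attractor near 3π/2) corresponds to the same physical
system with the opposite sign of γ_d — exactly the θ ↦ 2π−θ mapping that
the shear-reversal analysis exploits — and depends on the handedness with
which the planar frame is drawn.

The critical shear is operationalized as the rate at which the saddle
approaches the wall to within one beat amplitude A (the floor below which
phase averaging is unreliable); if the saddle drops out of the resolved
grid while being tracked downward, the loss is treated as the crossing.
The threshold is a parameter (`proximity`), defaulting to A.

## Guidance and boundary cycles

Ensemble endpoint studies integrate the reduced planar system (vectorized
fixed-step RK4, dt = 0.01 s) from initial angles sampled uniformly or with
the Jeffery residence-time weight p(θ) ∝ 1/θ̇(θ) (inverse CDF on a 4097-
point grid); all sampling flows from one seed and is bitwise reproducible.
Shear schedules alternate ±γ with the first reversal at half the rotation
period and a full period between subsequent reversals, which retraces each
half-orbit and rectifies displacement along the flow axis; reversing the
target flips the sign pattern.

Near a repulsive wall, a hybrid scheme is used: the full beat-resolved
solver (Blake kernel + repulsive load in the force balance) runs while the
minimum surface clearance is below 0.6 μm (three repulsion decay lengths),
the reduced field otherwise, with an exit hysteresis at 1.5 μm to suppress
handoff chatter from beat-phase clearance wiggle.  An approach–escape cycle
is counted when a full-solver episode dips below two decay lengths and then
retreats past the hysteresis level.  Runs started facing downstream near
the wall settle into quasiperiodic cycling with strong net downstream
drift; runs started near the saddle wash out into bulk tumbling excursions.
Tumbling is labelled when the unwrapped θ sweeps a full circle.

## Numerical parameters that matter

| parameter | default | why |
| --- | --- | --- |
| mesh refinement | level 1 (~636 elements) | the resolution the model targets; level 0 (~176) for sweeps, level 2+ for convergence |
| dt | beat period / 100 | Heun global error ≪ 1% over a beat; convergence-tested |
| n_phases | 20 | 20 vs 40 phases changes averages by < 1% |
| collision clearance | 2×10⁻³ μm | ~2 nm contact scale |
| wall grid | 24 θ × 16 h ∈ [2.5, 30] μm (log) | saddle sits at h ≈ 5–11 μm for γ_d ∈ [0.5, 2] |
| repulsion g, l | 1250, 0.2 μm | strong, short-ranged steric force |
| handoff in/out | 0.6 / 1.5 μm | 3l, plus hysteresis above the beat-phase clearance wiggle |
| Newton tolerance | 10⁻¹⁰ | fixed-point residual in field units |

## What the fixtures emulate — and what they do not

The canonical configurations (`promastigote`, `pusher`,
`passive_spheroid(r)`, `small_body_0.2`) are idealizations: axisymmetric
body, exactly planar sinusoidal beat, rigid body, Newtonian fluid, a single
flat wall.  Passing tests therefore demonstrate the solver and the reduced
dynamics on this idealized swimmer; they say nothing about asymmetric
morphologies, three-dimensional or elastically generated beats,
non-Newtonian media (the sandfly midgut rheology is unknown), Brownian
noise, or swimmer–swimmer interactions, all of which are out of scope.

## Known limitations

* BEM0 (flat panels, constant tractions) limits drag-type accuracy to ~1%
  at the default mesh; the structured triangulation carries a small fixed
  chiral roll (~0.03 rad/s) and out-of-plane leakage of a few percent of
  the rotation scale.
* Phase averaging is a frozen-configuration approximation with ~10% speed
  bias for this strong beat (see above), and is unreliable within a beat
  amplitude of the wall — the hybrid scheme exists for exactly that gap.
* The separatrix polyline is truncated where it leaves the resolved height
  range; classification near the grid edges falls back to forward
  integration.
* Guidance assumes the shear schedule is imposed exactly; no actuation
  model, no feedback.
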