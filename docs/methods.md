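# Methods

`ibvalve` simulates intracardiac flow driven by prescribed wall motion on a
fixed Cartesian grid, with a virtually implanted prosthetic aortic valve, and
evaluates how candidate valve placements change the transvalvular pressure
drop and the viscous energy loss. This note records the model, the numerical
choices, what the synthetic phantom does and does not emulate, and the known
limitations.

## Flow model and immersed-boundary coupling

The fluid obeys the incompressible Navier-Stokes equations on a fixed
Eulerian domain; every moving structure (chamber wall, valve housing,
leaflets) is a Lagrangian point set coupled to the fluid by penalty
immersed-boundary forcing. For a structure point with reference position X,
current position chi, prescribed displacement D and prescribed velocity U_s,
the force density is

    F = kappa ((X + D) - chi) + eta (U_s - U_w),

a stiff spring toward the prescribed target plus damping toward the target
velocity, where U_w is the fluid velocity interpolated at the point. The
damping term is written with the stabilizing sign (it drives the local fluid
toward the target velocity; the opposite sign is anti-dissipative and
diverges, which the oscillation-decay behavior of the tests confirms). F is
treated as traction per unit arc length; per-point quadrature weights carry
it to the Eulerian force density.

Lagrangian-Eulerian transfer uses the three-point quadratic B-spline kernel,
which satisfies the partition of unity and the zero-first-moment condition,
so interpolation reproduces constant and linear velocity fields exactly and
`spread`/`interpolate` are exact discrete adjoints. Two measured properties
of this kernel matter in practice:

* **Effective wall position.** A straight penalty wall acts hydrodynamically
  like a no-slip plane 0.378 h inside the structure line (fitted from steady
  channel profiles at several resolutions; resolution-independent in units
  of h, analogous to the half-link offset of lattice-Boltzmann bounce-back
  walls). The channel verification case compensates for it; the phantom
  geometry does not (it cancels almost completely in area *changes*).
* **Quadrature under deformation.** Weights are recomputed on the deformed
  target configuration during a run: with reference weights, a contracting
  wall concentrates its spring stiffness and crosses the explicit stability
  limit at peak contraction.

Time stepping is explicit: hybrid central/upwind advection (upwind where the
cell Peclet number |u| h / nu exceeds 2), explicit viscosity, Chorin
projection. The pressure Poisson problem uses half-sample Dirichlet
("open", prescribed pressure) and Neumann ("no-slip wall") outer boundaries;
when the per-direction boundary types are uniform it is solved by DST/DCT
diagonalization, with a Woodbury low-rank correction for the outlet side
(solid wall except the orifice band), and by a cached sparse LU otherwise.
Projection makes the discrete divergence vanish to machine precision every
step. Structures advect with the interpolated fluid velocity; inside the
solver the kernels clamp stencil indices at the boundary (conservation and
adjointness are preserved exactly), which lets the phantom's channel walls
seal flush against the solid part of the outlet boundary. The time step is
the minimum of the CFL target (0.2 by default), the explicit viscous limit,
and the penalty spring/damping limits; with automatic penalty selection the
spring is placed at a fixed fraction (0.8) of its stability limit for the
chosen step, and eta at the stiffness ratio eta/kappa = 5e-4 s capped by its
own stability bound. Structures whose lines stack within one kernel width
(valve housing against the apposed wall, double-layer leaflets) carry a
reduced penalty scale so the summed collective stiffness stays inside the
margin.

## Prescribed motion

Wall displacement arrives as keyframes at 20 phases over one cycle (the
phase count of a retrospectively gated CT reconstruction at every 5% of the
R-R interval) and is interpolated in time per point and component with
shape-preserving cubic Hermite polynomials (PCHIP) built on three
concatenated cycles, which enforces periodic endpoint slopes without
inventing boundary derivatives; target velocity is the interpolant's
analytic derivative.

The valve moves rigidly with the **landing zone**: the annular wall region in
contact with the housing, identified by a nearest-neighbor distance query at
the reference configuration and frozen. Each step, the least-squares rigid
transform from the landing zone's reference to its displaced position is
computed by the planar specialization of the quaternion cross-covariance
construction (closed-form angle in 2D; the quaternion path is retained for
3D point sets) and applied to housing and both leaflet configurations. The
least-squares fit over all landing-zone points reproduces the mean
translation exactly for translation-dominated motion.

## Reduced-order leaflets

Leaflet kinematics collapse to a scalar L in [0, 1] blending the closed
(L = 0) and open (L = 1) configurations point by point; L integrates at the
fixed rate R_leaf = 20 1/s (50 ms full transition, inside the 25-75 ms range
reported for prosthetic leaflets) whenever the transvalvular gradient
sampled from the two 20-point pressure clouds exceeds +1 mmHg (opening) or
falls below -1 mmHg (closing), and holds inside the dead band. The dead band
prevents chatter at zero gradient; it also means that in a quasi-static
regime the valve can creep: the phantom's transition durations therefore
exceed 1/R_leaf (the gradient dips into the dead band mid-transition) while
remaining cycle-repeatable. Leaflet inertance and fluttering are outside the
model.

## Windkessel outlet

The outlet carries a three-element Windkessel: C dp_c/dt = Q - p_c/R2,
P_out = p_c + R1 Q, integrated with implicit Euler (unconditionally stable
at the solver step, first-order accurate; steady state exactly
Q (R1 + R2), relaxation constant exactly R2 C). Module defaults are the
patient-scale constants R1 = 0.072, R2 = 1.40 mmHg s/ml, C = 0.88 ml/mmHg
(R2 C = 1.232 s). P_out is applied as the Dirichlet pressure on the orifice
band of the outlet boundary, and Q is the discrete flux through that band.

## The phantom: what it emulates and what it does not

The phantom stands in for the CT-derived left heart at desk scale in 2D: an
elliptical contracting chamber (6 x 4 cm) joined to a straight outflow
channel (2.3 cm wide, the 23-mm valve analog) ending at the outlet, plus an
inflow port on the far side of the chamber. Chamber points move radially
with a blend that fades at the junctions; the amplitude at every keyframe is
solved exactly from the shoelace polygon area (quadratic in the amplitude),
so the configured ejection fraction (0.5) is met to machine precision. The
outflow-channel wall carries a 1-mm axial excursion (annular motion analog)
that exercises the landing-zone/Horn pipeline. The volume waveform is a
quintic-smoothstep systole (35% of the cycle), rapid early filling (30%),
then diastasis, with explicit pre-ejection and pre-filling phases (10% of
the stroke over 12% of the cycle each) during which the valves transition;
the cycle's phase origin lies in diastasis so a rest start settles through a
quiet quarter cycle. Without the pre-phases the reduced-order valve hovers
at its thresholds and races the volume ramp, making cycle metrics
irreproducible.

Design choices that depart from patient conditions, made once for the 2D
desk scale and not revisited:

* **Working fluid** mu = 0.2 Pa s, rho = 1060 kg/m^3 (jet Reynolds number
  ~25). Blood viscosity at this scale in 2D gives Re ~ 1000 jets whose
  vortices persist indefinitely (2D turbulence has no vortex stretching), so
  consecutive cycles never agree to the level the evaluation requires; the
  viscous fluid makes the limit cycle laminar and repeatable. Solver
  defaults (`FlowState`) keep blood properties.
* **Windkessel scaling.** The 2D stroke "volume" is ~950 ml per metre of
  depth, so the patient-scale resistances are rescaled to give a mean outlet
  pressure of roughly 8 mmHg while preserving the R1/R2 ratio and the
  R2 C = 1.232 s time constant; the initial compartment pressure is the
  limit-cycle end-diastolic value (6.6 mmHg), the desk-scale analog of a
  diastolic initial condition.
* **Inflow port.** The chamber must refill; the port carries a second
  instance of the same leaflet law with low thresholds (0.3 mmHg) and a
  faster rate (40 1/s) so it shuts promptly at systole onset and opens
  repeatably on diastolic suction. It is a phantom fixture, not a device
  under study.
* **Valve geometry.** Two leaflets (2D); the open configuration forms a
  conical nozzle with a 12-cell orifice so the systolic jet carries a
  measurable gradient and reverse flow closes the valve decisively. Each
  leaflet is a double point row (0.75 h apart) at half penalty: same
  collective stiffness, twice the through-flow resistance when closed.
* **Apposition.** After a rigid placement, channel-wall points snap
  vertically onto the housing's outer envelope with a smooth taper beyond
  its ends; identity and pure axial translations leave the wall
  bit-identical, rotations make the wall wrap both the protruding and the
  recessed corners, and the keyframes are rebuilt for the modified
  reference so the ejection fraction stays exact.

Because the phantom is 2D, energies and flows carry an implicit unit depth:
P_loss is W per metre and E_loss J per metre of depth, and neither is
numerically comparable to 3D patient values; the evaluation is the
*ordering* of placements. The pressure-drop ordering survives the reduction
robustly (monotone in malrotation severity). The energy-loss ordering
survives but with a compressed margin: the severe rotation exceeds baseline
by under 2% here versus ~38% at patient scale, because part of the tilted
jet's excess loss is realized inside the smeared penalty layer at the wall
it impinges on (excluded from the integral as unphysical shear) rather than
in resolved dissipation. The E_loss contrast is therefore the fragile
quantity of the desk-scale study, and it is sensitive to the valve seat's
penalty stiffness: with the housing coupling halved, the ordering inverts.

## Metrics

The pressure drop is mean(LV cloud) - mean(aorta cloud), each cloud 20
points on a small disc one annulus diameter up/downstream of the valve
plane, bilinearly interpolated from cell centers and reported in mmHg. The
same clouds gate the leaflet law. Viscous power loss integrates 2 mu S:S
(S the symmetric velocity gradient at cell centers) over the fluid interior
classified by even-odd ray crossing of the wall polygon closed by the
outlet and inflow segments, excluding a 1.5 h band around housing and
leaflets (smeared-interface shear is unphysical) and the outlet boundary
columns (they carry the Dirichlet condition, not interior dissipation);
energy loss is its trapezoidal time integral over one cycle. All reported
metrics come from the second simulated cycle; the first is discarded as
initialization, and the third is simulated to verify periodicity.

## Problem sizes and tolerances

The study grid is 256 x 128 cells at h = 0.5 mm (the in-heart resolution of
the reference fine level), time step 1e-4 s, three cycles per placement,
four placements; a half-resolution configuration (128 x 64, h = 1 mm)
serves the fast functional tests. The channel verification runs 16/32/64
cells across the gap and reaches steady state to a relative tolerance far
below the discretization error; observed convergence is second order.
Divergence after projection is at machine precision; the penalty
auto-selection targets a wall tracking error below half a cell at the
systolic pressure load. Tie-breaks and degenerate inputs: a rotation fit on
coincident points is rejected; placements that push the housing out of the
channel axially, beyond the far wall, or across the centerline are rejected
with diagnostics; an ejection fraction whose amplitude equation has no
admissible root reports the offending phase.

## Known limitations

* 2D: no out-of-plane jet dynamics, no vortex stretching, unit-depth
  energies; placement contrasts in E_loss are compressed relative to 3D.
* The penalty coupling leaks slightly under sustained transmural load
  (sub-percent of the channel flux per wall at default parameters); the
  outlet-volume/stroke closure is verified to 5%.
* Wall shear stress at immersed surfaces is not computed (the smeared
  interface does not support it).
* The reduced-order valve has no inertance; transition timing follows the
  gradient law exactly, including dead-band stalls.
* The landing zone is frozen at the reference configuration; large
  placements that change the contact set over the cycle are not modeled.
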