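# Methods

`dissectflow` analyses the hemodynamics of a chronic type-B aortic
dissection (TBAD) with a variable number of re-entry tears.  The
anatomy it models is a swine-style dissected thoracic aorta: a primary
entry tear 7 cm distal of the arch admits flow into a false lumen (FL)
that runs parallel to the true lumen (TL) down to a naturally formed
re-entry tear at 32 cm, with two surgically created 5 mm re-entry tears
at 21 and 26 cm that may be open or closed.  Three tear configurations
are compared: two open tears (entry + distal; "S1-like"), three
("S2mod-like", the 21 cm tear occluded), and four ("S2-like").

The package contains four largely independent analysis layers —
velocity-field metrics, Windkessel outlet calibration, a
lumped-parameter (0D) network model of the dissection, and lumen
morphometry — plus synthetic generators that produce every input at
study-like acquisition settings.

## Blood rheology

Blood is an incompressible shear-thinning fluid with constant density
ρ = 1022 kg/m³ and a power-law (Ostwald–de Waele) viscosity

    η(γ̇) = K γ̇^(n−1),  K = 0.08 Pa·s^n,  n = 0.55.

For n < 1 the law diverges at zero shear, so the viscosity is clamped
below a shear-rate floor (default 0.01 1/s, configurable).  The clamp
applies to the viscosity only: the wall shear stress τ = η γ̇ = K γ̇ⁿ
still vanishes at γ̇ = 0.  Carreau–Yasuda or hematocrit-dependent
rheology is out of scope.

## Synthetic acquisitions

The velocity-field generator emulates time-resolved, velocity-encoded
(4D-flow) MRI of a flow phantom: default 2 mm isotropic voxels, 20
frames per cycle (39.2 ms at the 0.78 s cardiac state), velocity
encoding (VENC) 150 cm/s, with additive Gaussian noise of standard
deviation 5 % of VENC per velocity component (applied everywhere, as in
a real phase-contrast acquisition; the noise-free field is exactly zero
on background voxels).  Two cardiac states are modelled: a short cycle
(0.78 s, peak inlet flow 15 L/min, systolic fraction 0.35) and a long
cycle (1.08 s, peak 16 L/min, systolic fraction 0.30).  The inlet
waveform is a half-sine systolic pulse over the systolic fraction of
the cycle followed by zero diastolic flow; its cycle mean has the
closed form peak·fraction·2/π, which the tests use as an oracle.

The spatial profile is quasi-parabolic (Poiseuille-shaped), rescaled
each frame so that the *discrete* cross-section flow equals the
prescribed waveform exactly.  This choice — rather than a Womersley
profile — makes every downstream flow metric exactly checkable.
Consequences for interpretation: passing tests demonstrate correct
integration, masking, sign conventions and unit handling, not fidelity
to pulsatile boundary-layer physics (no Womersley flattening, no
phase lag across the lumen, no eddy-current or phase-wrap artifacts).

The two-lumen phantom splits a circular tube with a flat 2 mm septum
and divides the inlet flow between the lumina at an imposed fraction
(default 56 % TL).  The imposed split is a free parameter of the
phantom, not a claim about any animal.

A separate steady phantom provides the exact laminar power-law pipe
solution u(r) = u_max(1 − (r/R)^((n+1)/n)) for validating wall-shear
estimation.  Its `exterior="extend"` option continues the analytic
profile smoothly past the wall so that interpolation error across the
masked wall discontinuity does not contaminate the measurement of
gradient truncation error; `exterior="zero"` reproduces the masked,
acquisition-like case (and is correspondingly less accurate near the
wall).

## Velocity-field metrics

Plane flow rate integrates velocity·normal over the intersection of an
analysis plane with the selected lumen.  When the plane normal is
grid-axis aligned (the phantom geometry) the default integration is a
midpoint rule on the voxel centers of the nearest slice — exact for
voxel data and therefore consistent with the generator's discrete
normalization.  For oblique planes or an explicit sampling pitch, a
regular in-plane grid with trilinear interpolation and
nearest-neighbour mask gating is used; its error decreases with grid
resolution (about −2.4 % at 8 voxels across the diameter, −0.5 % at
16 for the parabolic phantom at half-voxel pitch).

The reverse flow index of a signed periodic waveform Q(t) is

    RFI = 100 · |∫ Q_rev dt| / (|∫ Q_rev dt| + |∫ Q_fwd dt|),

with Q_fwd = max(Q, 0), Q_rev = min(Q, 0), trapezoid integration over
one period with periodic closure, and the 0/0 case (an all-zero
waveform) defined as 0.  RFI is computed on the *net* lumen waveform,
matching a single-number-per-plane presentation; voxel-wise reversal
fractions are a different quantity and are not computed.  Tear
waveforms are signed positive for TL→FL flow; forward through the
entry tear is TL→FL and forward through a re-entry tear is FL→TL, so
the re-entry RFI is evaluated on the negated waveform.

Flow distribution between the lumina uses cycle-mean net flows (again
matching one number per plane); a lumen with non-forward net flow is
flagged.  Arch-branch flows are estimated from the drop in cycle-mean
flow across the branch ostia, distributed over the branches
proportionally to their cross-sectional areas with exact conservation.
Inlet-profile extraction interpolates the in-plane velocity onto
arbitrary target points and rescales each frame uniformly so the flux
over the target discretization equals the source plane flow
(flux-conservative mapping; points outside the lumen are zero-filled
and counted).

## Wall shear stress

The wall shear rate is a first-order one-sided estimate: the
tangential velocity magnitude at a probe placed `probe_depth`
(default 0.25 voxel) along the inward wall normal, divided by the
depth (no-slip at the wall).  The probe sample uses cubic B-spline
interpolation (prefiltered `map_coordinates`).  Trilinear interpolation
is *not* used here: with a sub-voxel probe depth, a linear interpolant
makes the effective difference depth one whole voxel, which biases the
shear rate by ≈ −11 % on the power-law profile at 16 voxels across the
diameter (≈ −6 % in stress); the cubic spline leaves only the O(depth)
Taylor term (≈ −2 % in stress).  The spline prefilter is global, so
phantoms keep several voxels of padding between the lumen and the grid
boundary.  Stress uses the consistent nonlinear closure τ = K γ̇_wⁿ
evaluated at the estimated wall shear rate itself.  TAWSS is the
cycle average of |τ| (trapezoid, periodic closure), invariant under
time reversal.  Oscillatory shear index and curvature-corrected
gradients are out of scope.

## Windkessel outlets

Each outlet is a three-element Windkessel: proximal resistance Rp in
series with compliance C parallel to distal resistance Rd, discharging
at Pout (default 0 mmHg):

    C dPc/dt = Q − (Pc − Pout)/Rd,   P = Pc + Q·Rp.

Parameters are in clinical units (mmHg·min/L, L/mmHg); integration is
in SI with 1 mmHg = 133.322 Pa.  The implicit-Euler map over one cycle
is affine in Pc, so the simulator starts Pc at the exact periodic
fixed point of that map and then verifies the cycle-mean periodicity
criterion (0.1 % default).

Calibration replicates boundary-condition tuning from measured flow
and pressure: R_total = (mean pressure − Pout)/mean flow; Rp is a
fixed fraction of R_total (module default 0.1, the conventional
characteristic-impedance fraction); C is found by bisection (Brent on
log C) on the simulated pulse pressure, which is strictly decreasing
in C.  An unattainable pulse target — below the large-C limit set by
Rp·ΔQ or above the small-C limit — raises an error naming the
achievable range.  In the pipeline's comparative run the Rp fraction
defaults to 0.05 because the half-sine inflow has peak/mean ≈ 4.6, so
a 10 % fraction alone would exceed the 25 mmHg pulse target.

## The lumped dissection network

The 3D dissected aorta is reduced to a 0D node/element network.  This
is an explicit surrogate: it reproduces the *mechanism* of tear-count-
dependent flow redistribution and pressure relief with desk-scale,
exactly testable numerics; it does not claim the absolute flow splits,
velocities or pressures of any 3D computation, and directional
comparisons between tear configurations are its only claims.

* **Segments** (one per inter-tear region per lumen, with the long
  7–21 cm region split in two so five stations P2–P6 span the
  dissection): Poiseuille resistance 8ηL/(πr⁴) and blood-column
  inertance ρL/A.  The wall is rigid — no internal compliance; all
  compliance resides in the outlets.
* **Tears**: orifice elements with dP = R_lin·Q + ρ/(2C_d²A²)·Q|Q|,
  odd and strictly increasing in Q.  R_lin is Poiseuille flow through
  the 2 mm flap thickness; the quadratic term is the sharp-edged
  orifice loss with discharge coefficient C_d = 0.6.
* **Outlets**: three arch-branch Windkessels (branch areas 80/30/20
  mm² set their flow shares) and one distal Windkessel.
* **Inlet**: prescribed periodic flow at the arch.

Geometry defaults are fixtures informed by the measured anatomy, not
measurements: proximal aorta radius 12 mm, TL 7 mm, FL 10 mm (the FL
is the larger lumen), distal reconstituted aorta 8 mm; created tears
5 mm; the entry and distal tears are *effective circular orifices* of
14 and 12 mm (their measured axial calipers, ~20 and ~12 mm, describe
elongated slits whose hydraulic orifice is smaller).  Segment
viscosity is evaluated at a cycle-representative reference shear rate
of 30 1/s for assembled networks: diastole occupies most of the cycle
near zero flow, where the shear-thinning viscosity is several-fold
higher than at systolic wall shear (~70 1/s), and this damping is what
keeps the TL–FL loop from ringing unphysically.  (The
`segment_resistance` primitive itself defaults to 100 1/s; both are
configurable.)  With an underdamped parameterization the FL behaves as
a free-wheeling inertial loop — near-zero net flow, RFI ≈ 50 % —
which contradicts the near-unidirectional FL flow observed in vivo.

Time integration is implicit Euler (default dt = 1 ms) on the outlet
compliance states and segment inertances; each step solves the
nonlinear nodal system (Kirchhoff balance at every node) by Newton
with an analytic Jacobian to an absolute tolerance of 10⁻¹⁰ × peak
inlet flow.  Cycles repeat until cycle-mean nodal pressures change by
less than 0.1 % (the comparative pipeline uses 0.01 % so that
inter-scenario differences of a few hundredths of a mmHg are not
transient artifacts); outlet compliance states are initialized at
their DC values under a conductance-proportional share of the mean
inflow to keep the start-up transient small.  A false lumen left with
no open tear at all becomes a pressure-undefined island: it is flagged
as a sealed pouch, one island node is pinned, and all island elements
carry zero flow.  A dead-end FL (entry open, all re-entries closed)
needs no special handling — rigid incompressibility forces its flow
to zero through the ordinary balance equations.

Occluding a tear produces a network identical except for that tear's
patency.  Reported per-station metrics are the TL/FL shares of
cycle-mean flow, lumen RFIs, cycle-mean FL pressure, and the
cross-lumen pressure difference CLPD = P_FL − P_TL with its cycle
peak.

## Comparative run and trend validation

The pipeline's comparative run solves all three tear configurations
with one shared inlet state (the long-cycle state) and one shared
outlet calibration, so that scenario deltas isolate tear topology —
the occluded variant in the underlying study likewise reuses its
parent's boundary conditions.  `validate_trends` asserts directions
only: the distal TL flow share does not decrease, and the mean FL
pressure and the peak CLPD do not increase, as tears are added
(S1-like → S2mod-like → S2-like).  A 20-point sweep of the mid-tear
diameter from 0 to 5 mm exercises the same mechanism continuously and
is monotone in all three summaries.  With the default fixtures the
run also reproduces, directionally, the proximal observation that
*more* flow enters the FL near the entry when more re-entry tears are
open (station P2's TL share falls from ≈ 79 % to ≈ 75 %).

## Morphometry

Lumen volume is slice-wise: labelled-pixel count × pixel area × slice
thickness, with center-sampling pixel membership; the estimate
converges to πr²L on cylinder phantoms at observed order ≥ 1.
Maximum diameter is the per-axial-slice Feret (maximum caliper)
diameter over the pixel *corner* points of the labelled region (convex
hull, then the maximal vertex pair), so a single pixel reports its
diagonal; on a rasterized circle this convention overshoots the
analytic diameter by up to ~1.5 pixels.  No oblique reslicing or
inter-scan registration is performed.  Percent changes between scans
compose multiplicatively, 100·(Π(1 + cᵢ/100) − 1): sequential interval
rows between follow-up scans compose to the overall row within the
rounding of the printed inputs.  (Note the early printed interval rows
of the source table are mutually inconsistent under ratio composition;
only the composition of the final two intervals, which is
convention-independent, is used as a quantitative check.)

## Numerical choices and degenerate inputs

* Trapezoid rule with periodic closure for every cycle integral.
* RFI of an all-zero waveform is 0; flow distribution with zero total
  net flow is an explicit error; a lumen with non-forward net flow is
  flagged, not hidden.
* Branch-split conservation is pinned exactly onto the largest branch.
* Plane/lumen intersections that are empty raise an error naming the
  plane.
* All generators are bit-deterministic given their seed; pipeline
  artifacts embed the seed and a configuration hash, and repeated runs
  are byte-identical.

## Problem sizes

Default problem sizes are chosen so every analysis runs on a laptop
core: phantom grids of 14–30 voxels per side with 20–25 frames,
networks of 17 nodes solved at 1 ms over 15–35 cycles, and a 20-point
tear sweep; the full comparative pipeline completes in well under a
minute and the whole test suite in a few minutes.

## Known limitations

* The 0D surrogate has no wave propagation, no moving flap, no
  fluid–structure interaction and no thrombosis; absolute pressures
  and flow splits are not comparable with 3D computations.
* The phantom's quasi-parabolic profile understates pulsatile
  boundary-layer effects, so wall-shear magnitudes on the pulsatile
  phantom are illustrative; the quantitative wall-shear check lives on
  the steady power-law phantom.
* Windkessel calibration fits mean and pulse pressure only; waveform
  shape is not a fitting target.
* Station placement in the network is schematic (anchored to the tear
  layout), not anatomical.
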