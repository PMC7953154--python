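# Methods

`atriflow` simulates blood flow and blood age ("residence time") in an
idealized, moving left atrium (LA), and computes the stasis and energy metrics
used to characterize thrombogenic flow conditions in the left atrial appendage
(LAA). This note records the models, the numerics, the synthetic-data
generator's assumptions, and the package's known limitations. Units are cm, s
and ml throughout; velocities are cm/s, kinetic energy per unit mass cm²/s².

## Physical model

Blood is treated as an incompressible Newtonian fluid with kinematic viscosity
ν = 0.04 cm²/s. The chamber wall is *one-way prescribed*: a closed, moving
triangulated surface whose position and velocity come from a periodic kinematic
model; the fluid does not act back on the wall. The chamber sits inside a
sealed cube (side 13 cm by default) with free-slip boundaries; the fluid
outside the chamber is simulated too and simply acts as an ambient reservoir.

Flow boundary conditions mirror the physiology:

- **Pulmonary-vein (PV) inflow.** The combined PV flow rate is closed by mass
  conservation, Q_PV(t) = dV_LA/dt + Q_MV(t), split evenly over the four
  veins, and imposed by a relaxation body force f = (v_t − v)/τ in a small
  buffer region upstream of each inlet plane, with plug target
  v_t = (Q_i/A_i)·n and τ = 10 Δt. Backflow (the Ar wave) is permitted.
- **Mitral outflow.** The mitral plane opens instantly when Q_MV > 0 and
  closes instantly when Q_MV = 0. Closed: the plane's triangles join the
  immersed wall and the plane's normal velocities are zeroed after projection.
  Open: a relaxation actuator patch nudges the plane toward the uniform
  outflow profile Q_MV/A; in a sealed box the prescribed wall motion and PV
  forcing already fix the net mitral flux, so no hard constraint is imposed
  (an optional additive exact-flux correction exists for diagnostics; a
  multiplicative post-projection rescale proved unstable and is not used).

**Residence time.** T_R obeys ∂T_R/∂t + v·∇T_R = 1: it ages at unit rate and
is advected with the flow. It starts at zero and is relaxed to zero in the PV
buffers *and throughout the PV stub lumina* — blood in the veins is fresh by
definition. (With 3-cell buffers at desk-scale spacing the transit time
through the buffer is comparable to τ, so buffer-only resetting would let
inflowing blood keep an O(1) fraction of the ambient age.) With no flow and
no resets, T_R = t identically — the reference line of the washout plots.

## Discretization

Staggered Cartesian grid (isotropic spacing), centered second-order finite
differences, and a low-storage three-stage Runge–Kutta scheme (the
8/15, 5/12, 3/4 triplet, exposed as named constants) with explicit advection
and semi-implicit (Crank–Nicolson-weighted) viscosity per stage. Each stage
ends with a fractional-step pressure projection. With free-slip boundaries
both the pressure Poisson problem and the per-component viscous Helmholtz
problems diagonalize under cosine/sine transforms, giving exact direct solves;
when the viscous operator is within 2·10⁻³ of the identity (always true at
hemodynamic parameters) the Helmholtz solve uses an equivalent
tolerance-controlled Neumann series (relative residual < 10⁻¹²), which is
~3× faster. The post-projection divergence is at solver tolerance
(≤ 10⁻⁸ · max|u|/Δx) by construction.

The immersed boundary uses direct forcing: Lagrangian markers at the triangle
centroids of the wall model (areas as weights) carry the wall velocity; the
3-point Roma–Peskin kernel interpolates the fluid velocity to the markers and
spreads the correcting force back. The kernel's partition of unity makes the
spread force equal the marker force to machine precision.

Time step: adaptive under CFL ≤ 0.3 with a cap, or constant (the verification
experiments use a constant Δt sized for the fastest flow of full chamber runs
— the mitral E jet — so inlet-local Courant numbers are ≪ 0.3, as in the
two-resolution 20-beat protocol this pipeline's defaults mirror).

Residence-time transport shares the flow's Runge–Kutta staging and Δt.
Advective fluxes use third-order WENO reconstruction, upwinded on the
staggered face velocities, in conservative-minus-dilatation form. Within a
two-cell band of the immersed surface the reconstruction degrades to
first-order upwinding (the band is masked out of statistics anyway). WENO3 is
*essentially* non-oscillatory: bounded violations of the maximum principle at
the reset front are floored at zero below, and tolerated to 0.5% relative
above t; anything larger aborts the run as a monotonicity error.

## Synthetic anatomy and kinematics

Real 4D-CT segmentations are not distributable, so the generator builds
idealized cases with the same structure: an ellipsoidal body (semi-axes
3.1 × 2.7 × 2.3 cm), four PV stubs (radius 0.85 cm, inlet planes 4.2 cm from
the center), a mitral stub (radius 1.35 cm), and a tapered appendage tube
with 1–4 lobes. Everything is expressed as a *star-shaped radius field* over
sphere directions and meshed on a fixed icosphere template, so all phases
share one connectivity (frames are born corresponded), every frame is
watertight by construction, the tube end caps are exactly planar (inlet and
mitral planes), and interior/appendage membership tests are closed-form.

Wall motion is a time-varying isotropic scale of the body plus an independent
radial scale of the appendage; both are fitted per phase by 1-D root finding
so the meshed volumes match a prescribed V_LA(t) and V_LAA(t) to ≪1%. V_LA(t)
is a C¹ piecewise-cosine waveform through V_min → V_max (reservoir, peak at
0.40 T) → V_pre-A (E wave, window 0.42–0.60 T) → plateau (diastasis) → V_min
(A wave, final 22% of the cycle), anchored by the requested ejection
fractions; global, booster and passive EF are linked by
(1 − EF_global) = (1 − EF_passive)(1 − EF_booster), and mutually inconsistent
targets raise a parameter error. The transmitral waveform has sin² E and A
lobes whose peaks satisfy the requested E/A ratio and whose cycle integral
equals the prescribed transmitral stroke volume (default 72 ml, consistent
with a conduit-volume ratio of 0.33 at the default volumes). The fixed-wall
variant freezes the wall at the zero mode of its Fourier series and removes
the A lobe exactly.

Defaults emulate a normal atrium: V_max = 108 ml, global EF 0.45, booster EF
0.37, LAA EF 0.52, E/A 1.64, period 1.0 s, 20 phases per cycle. A seeded
jitter option perturbs the anatomy for cohort studies. The appendage axis
points laterally, *out of* the PV-to-mitral jet path: the LAA is a blind
pouch washed chiefly by its own contraction; aiming it into the left-PV jets
makes even a rigid chamber wash it efficiently, which inverts the wall-motion
contrast observed in normal atria.

The temporal wall model is a truncated Fourier series (6 modes by default)
per vertex: an exact trigonometric interpolant when the frame count equals
2·6+1, the least-squares (truncated-DFT) fit with more frames. Velocities are
the term-by-term analytic derivative, so position/velocity are exactly
periodic and mutually consistent, and dV/dt is evaluated exactly from the
product rule on the signed-volume sum — the mass-conservation closure
Q_PV − Q_MV − dV/dt holds to machine precision.

What the generator does **not** emulate: real wall-motion heterogeneity
(regional strain), PV anisotropy and ostium geometry, trabeculation and
pectinate muscles inside the LAA, valve leaflets, and inter-patient shape
families beyond lobe count and global dimensions. Passing tests therefore
demonstrate correctness of the numerics and directional recovery of the
wall-motion mechanism, not patient-level prediction.

## Metrics

- Kinetic energy K = ½(u² + v² + w²) at cell centers.
- Q-criterion: Q = ½(‖Ω‖² − ‖S‖²) from centered gradients, with vortex cores
  thresholded at Q > 1000 s⁻² by convention.
- Appendage statistics pool voxel samples of T_R and K over snapshots of the
  trailing beats (uniform grid → counts are the volume weighting). Samples
  come from the *eroded* appendage lumen: cells inside the one-cell band
  spanned by the regularized interface move with the wall and are permanently
  stagnant at coarse spacing. 95% CIs of the means use a seeded block
  bootstrap with heartbeats as blocks; densities use a Gaussian KDE with the
  Scott bandwidth rule (recorded in the result object).
- Washout convergence: the per-beat mean LAA T_R is declared quasi-periodic
  at the first of two consecutive beat-to-beat relative changes below 2%.
- Contrasts: ΔT_R = (T_R,FW − T_R,MW)/T_R,MW (same for K); group contrasts
  report the positive group's percent T_R excess and K deficit, averaging
  per-case means (each subject weighted equally) by default.

## Morphometrics

The appendage is voxelized from the star-shaped interior test (0.05 cm
default spacing), thinned with topology-preserving 3-D thinning
(scikit-image), and assembled into a 26-connected branch graph with
voxel-step arc lengths (1, √2, √3 × spacing). Terminal spurs shorter than the
pruning threshold (5 voxels by default) are removed iteratively. Lobes are
the remaining endpoints distal to the orifice; the orifice-side stub is
identified as the endpoint whose terminal branch contains the
orifice-adjacent root and which lies much nearer the root than the distal
tips. The appendage length is the longest orifice-to-tip path, including the
Euclidean gap between the orifice point and the skeleton root (thinning
retracts the skeleton from the mask boundary by roughly the local radius).
Both the pruning threshold and the orifice definition materially affect lobe
counts; they are explicit inputs. The voxel-step metric overestimates oblique
path lengths by up to ~8% (lattice artifact) — lattice-aligned phantoms
measure exactly.

## Problem sizes and tolerances used by the test suite

The full-scale protocol (two-resolution restart at 0.090/0.051 cm spacing,
256³ cells, 20 beats, statistics over the last 4 beats and 200 instants per
cycle) is exposed through configuration (`--preset full`), but the suite and
the acceptance script run desk-scale versions chosen as this package's own
verification sizes: Taylor–Green at 64 cells per side (energy decay within
0.5%, spatial order ≥ 1.9 from a 16→32 refinement), duct inflow fidelity at
48³ (acceptance script) and 32³ (suite) with a 3-cell buffer and τ = 10Δt
(deviation ≤ 5% of the peak target over a cycle), steady-duct residence
(≤ 2% of the transit time), and the wall-motion contrast at 40³ with 5
heartbeats on a shared anatomy (moving vs frozen walls, statistics over the
last 2 beats). All simulation-backed checks are deterministic given their
configuration.

## Known limitations

- At 32–48³ the PV and mitral stubs are only 2–4 cells in radius; the
  kernel-smeared immersed walls are partially permeable at that resolution,
  so the per-step balance between plane-measured PV/mitral fluxes and the
  chamber volume rate carries O(25–50%) leakage errors even though the global
  (box-level) mass balance is exact by construction. Washout and the
  moving-vs-fixed contrast are robust to this (both modes are equally
  affected), but quantitative per-plane flux accounting needs the fine-grid
  protocol.
- The appendage washout time constant is many beats; at 5–6 desk-scale beats
  the moving-vs-fixed residence-time contrast is directionally stable but far
  from its converged magnitude (the full-scale protocol uses ~15 beats to
  converge and 20 in total).
- The maximum principle for T_R holds only up to the essentially
  non-oscillatory tolerance of WENO3 (see above).
- Fixed-wall runs inherit all the caveats the comparison is designed to
  expose: no reservoir/booster transport, oversimplified inflow partitioning,
  and E-wave-only transmitral flow. For a normal-function chamber the net
  residence-time effect of freezing the walls is small and of either sign —
  the fixed-wall protocol's full-amplitude E jets stir the rigid chamber and
  can wash the appendage as well as the booster flush does (kinetic energy,
  in contrast, collapses robustly when the walls freeze). At the 40–48³
  scales checked here the fixed-wall appendage T_R comes out equal or lower
  than moving-wall, consistent with the equal-or-lower fixed-wall values
  reported for two of the three normal-function subjects in the reference
  cohort.
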