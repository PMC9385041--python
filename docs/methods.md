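# Methods

`cortox` simulates what a single 25 µm microembolus does to the oxygenation
of the cortical tissue column fed by one penetrating arteriole, and measures
the spatial relationship between the trapped bead and the resulting hypoxia
with two statistics that apply unchanged to segmented imaging data. This
note records the model, its assumptions, the numerical choices, and what the
synthetic data can and cannot show.

## Synthetic cortical columns

A column is a 375×375×1500 µm³ block: four triply periodic 375 µm capillary
cubes stacked in depth plus a stochastic penetrating-arteriole tree rooted
at the lateral centre of the cortical surface.

**Capillary cubes.** Nodes sit on a jittered simple-cubic lattice
(jitter ±22% of the spacing); the full periodic edge set is pruned by
seeded random deletion to the exact segment count implied by the target
density, keeping every node at degree ≥ 2 and keeping the *stacked finite*
network connected (periodic edges that will be cut at the lateral faces
carry no connectivity). Segment lengths follow the minimum-image
convention; diameters are clipped-normal (mean 7.55 µm, SD 0.8, clipped to
4.5–11 µm). At assembly, periodic segments crossing a z-interface become
straight inter-cube segments; segments crossing an outer face are cut at
the face, leaving boundary stubs.

**Penetrating arteriole.** The trunk descends from the surface, its
diameter falling linearly from the inlet (29–33 µm) to exactly 25 µm at a
mid-to-deep crossing depth (1050–1300 µm). The number of side branches it
sheds while above 25 µm is drawn uniformly from 5–14; with the first sub-25
µm trunk segment this fixes the trapping-site count to 6–15 per column.
Branch depths are spread evenly from the first-branch depth (60–120 µm) to
the crossing; side-branch root diameters follow Murray's law from the local
trunk taper step. Each side branch is a *descending secondary branch*: a
short oblique elbow followed by a near-vertical run whose length tracks the
local branch spacing, shedding short leaf twigs. Below the crossing the
trunk continues at 24→15 µm, still shedding (shadowed) offshoots. Branches
reflect off a 175 µm lateral half-width rather than leaving the box — the
fold-back stands in for the branches of neighbouring columns' arterioles
that would enter symmetrically. Every terminal is joined to the nearest
capillary node by a connector carrying the terminal's diameter.

Two geometric features were forced by the boundary conditions rather than
free choices. With every box-face node held at one outflow pressure,
(i) arteriolar delivery must stay near the column axis — peripheral
delivery short-circuits to the faces without perfusing the interior — and
(ii) delivery must cover every depth, or the uncovered band goes hypoxic
at baseline. The descending-branch geometry satisfies both; healthy
columns then show hypoxic fractions below 0.1%.

**Calibration.** Only two generator constants were tuned, once, against the
column-level geometry targets (vessel density 10846/mm³, vascular volume
fraction 2.82%): the cube-level segment density (9435/mm³ — lower than the
column target because face-cut stubs and the arteriole add segments at
assembly) and the capillary diameter mean. Ten default columns give
10837 ± 58 /mm³ and 2.84 ± 0.03%. The surface density of penetrating
arterioles, 1/0.375² = 7.11/mm², is an identity of the construction.

## Blood flow

Steady Poiseuille flow: segment conductance πr⁴/(8µL) with the in-vitro
apparent-viscosity law of Pries, Neuhaus & Gaehtgens (1992) at fixed
discharge haematocrit 0.45 and plasma viscosity 1.2 mPa·s. All box-face
nodes share the reference pressure (0); the inlet is a Dirichlet node whose
pressure is rescaled — the system is linear — so that inlet flow / column
volume equals 55 mL/100 mL/min. Mass conservation is enforced to 1e-8
relative; ≤ 200-node systems take a dense path, larger ones sparse
Cholesky-like elimination via `scipy.sparse`. Phase separation of
haematocrit is deliberately out of scope (second-order at this scale).

## Oxygen transport (Green's function method)

Vessels are discrete source elements (segments split to ≤ 60 µm); tissue is
a voxel grid (15 µm default, 30 µm for batch work) of Michaelis–Menten
sinks M(P) = M₀P/(P+P₀). Both propagate through the free-space kernel
G = 1/(4πD_tα_t r); a uniform far-field offset plus the global constraint
Σq = ΣM·V closes the system (without the constraint the mean tissue level
would have to be carried by a net monopole that leaks ~10% of the oxygen
to infinity, violating mass balance). No image corrections are applied;
residual boundary leakage shows up only as the far-field offset.

Parameters: α_b = 3.1e-5, α_t = 3.89e-5 cm³O₂ cm⁻³ mmHg⁻¹,
D_t = 2.41e-5 cm²/s, C_Hb = 0.5 cm³O₂ per cm³ RBC, Hill n = 3,
P50 = 38 mmHg, M₀ = 6.72e-4 cm³O₂ cm⁻³ s⁻¹ (human cortex), P₀ = 1 mmHg,
inlet PO₂ 90 mmHg, hypoxia threshold 10 mmHg. These are standard inputs of
cortical Green's-function modelling, not fitted values.

**Discretisation.** Element–element coupling uses the finite-line kernel
(2/L̄)·asinh(L̄/2r̃)/(4πK) with r̃ floored at the mean radius: it matches
1/r far away, equals the cylinder self-average at contact, and keeps every
mutual coefficient at or below the self term. A 10% self-term boost keeps
the matrix positive definite against near-contact clusters of cut stubs
and connectors (a floored point kernel is indefinite there and the solver
rides a growing zero-sum dipole mode). Voxel sinks superpose through an
FFT convolution whose zero-offset entry is the equal-volume-sphere
self-average.

**Iteration.** The outer loop alternates (i) an implicit tissue solve and
(ii) damped blood-side sweeps, until the tissue field changes by less than
0.1 mmHg (cap 200 iterations; non-convergence raises with the residual
history). Two stiffness problems rule out the plain under-relaxed Picard
iteration: the Michaelis–Menten sink has loop gain ≫ 1 over any coherent
hypoxic region, so the tissue subproblem P = ext − K∗[M(P)V] is solved by
(semismooth) Newton–Krylov with the FFT as the operator; and weakly
perfused elements flip between full and empty blood, so the wall-matching
system carries an implicit intravascular-convection resistance (dP/dC)/(2Q)
on its diagonal. The diagonal is static per solve (one dense LU); the RHS
is arranged as pb_mid(q_old) + D·q_old so the fixed point is independent
of the damping value. Elements whose entry PO₂ falls below 2 mmHg deliver
nothing: their q is pinned to zero through Sherman–Morrison–Woodbury
updates of the factorised system. Blood PO₂ is convected element-by-element
in flow order with flow-weighted mixing at converging nodes; contents are
inverted through a lookup table of the dissociation curve (the public
`content_to_po2` uses exact root finding). Transiently negative field
values carry zero consumption; the reported grid is clipped at zero.
Intravascular (wall) resistance beyond the convective term is omitted —
wall PO₂ equals blood PO₂ — which is a fidelity gap relative to full
implementations of the method.

## Occlusion scenarios

A 25 µm bead entering at the inlet follows the solved flow and lodges at
the inlet of the first vessel below 25 µm. All distinct first-trap
segments reachable through ≥ 25 µm flow-directed segments are enumerated
(canonical segment-id order) and weighted equally; capillaries and
connectors never trap. One bead per column. The trapped segment's
conductance is zeroed (geometry retained), flow is re-solved at the
unchanged healthy inlet pressure, oxygen is re-solved warm-started from the
healthy state, and the hypoxia mask (PO₂ < 10 mmHg) is taken. The relative
perfusion drop is 1 − Q_blocked/Q_healthy.

## Spatial statistics

*Pixel-based Gx*: the empirical CDF of the distance from every in-domain
hypoxic voxel centre (excluding voxels hypoxic at baseline) to the nearest
microsphere, honouring anisotropic spacing; reported on a 0–1000 µm grid in
10 µm bins (the bin width is a reporting choice). Per column, scenario
distances are pooled before the CDF; across columns, per-column curves are
averaged. *Hypoxic intensity*: the hypoxic volume fraction of in-domain
voxel centres within spheres of radius 50–500 µm (step 50) around a
microsphere; empty spheres report NaN, never zero. Classification: type A
if the fraction falls from 50 to 100 µm (or is 1.0 at both), type B if it
rises (or is 0.0 at both); an exact tie with partial hypoxia is type B (the
residual class). Subtype "local" iff any hypoxic voxel lies within 100 µm.
Monte-Carlo control points are drawn uniformly over in-domain voxels at the
observed bead density. The simulated and imaging arms call the *same*
functions (asserted by a test).

## Experimental-style data

Binary MIP masks of 50 µm coronal sections at 3.033 µm pixels are pooled
5×5 into 15.165×15.165×50 µm³ voxels; a voxel is hypoxic iff ≥ 50% of its
in-tissue pixels are hypoxic (ties count as hypoxic) and in-domain iff
≥ 50% of its block is tissue. Each section's content sits at its slab
centre. The synthetic-experiment generator plants disc-shaped hypoxia
blobs at recorded in-plane displacements from beads (beads at section
centres, displacement clearance from the field edge), plus optional
unrelated background blobs, so Gx/intensity recovery can be tested against
known truth. The in-plane displacement direction avoids confounding the
planted distance with the 50 µm z-quantisation.

## Problem sizes and runtime choices

Full columns hold ~2400 segments and ~2900 source elements. Batch work
(occlusion scenarios, cross-column summaries) runs on a 30 µm tissue grid
(12×12×50 voxels; the nominal edge is rounded to divide the box); healthy
single-column studies use the 15 µm default. A four-column scenario batch
(~40 occlusions) completes in minutes on one core. The grid-refinement
check (30 → 15 µm on a one-cube column) documents the discretisation
sensitivity of the hypoxic fraction rather than asserting a convergence
rate.

## What the synthetic data do and do not show

The generator reproduces the *statistics* the study conditions fix
(geometry densities, trapping-site counts, perfusion calibration) and the
qualitative tree architecture (mid-depth bead-size crossing, branch
territories spanning hundreds of micrometres). It does not reproduce any
specific morphological network, so instance-specific numbers (individual
perfusion drops, per-column PO₂ maps) have no counterpart here, and
passing tests say nothing about real segmented imaging beyond what the
planted-truth recovery tests cover. Venules, haematocrit phase separation,
autoregulation, pericyte responses, bead clearance and infarct progression
are out of scope; hypoxia here is the instantaneous steady state of a
passive network.

## Known limitations

- The free-space kernel with a far-field offset has no image corrections;
  tissue just inside a face sees slightly too much of the outside world.
- Wall (intravascular) resistance is omitted; tissue PO₂ near large
  vessels is slightly optimistic.
- The equal-probability trapping assumption ignores bead transport
  physics, exactly as the underlying model assumes.
- The capillary lattice has no venular hierarchy: all faces drain at one
  pressure, which forces the centralised-delivery tree geometry described
  above.
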