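# Methods

This note records the model, its assumptions, the numerical choices,
and what the synthetic study conditions do and do not establish.

## The model

**Frames and posture.** Global frame: +x anterior, +y medial, +z
dorsal, right limb; the pelvis is fixed at the identity. In the
neutral posture every bone hangs as a vertical column (+z proximal).
A posture is six angles (degrees): hip flexion–extension (measured
from the horizontal, negative anteroventral), hip abduction (positive
abducts), hip long-axis rotation (positive external), knee flexion,
ankle flexion, and the metatarsophalangeal (MTP) angle (positive
extension). The hip composes FE → AB/AD → LAR intrinsically; knee,
ankle and MTP are single-axis hinges with mediolateral axes fixed in
their proximal segments. The pes is a rectangular prism whose length
stands in for digit III; its centroid is taken as the centre of
pressure (COP).

**Admissibility.** A test posture must satisfy three constraints:
no interpenetration between non-articulating bones (discrete
convex-hull containment checks per posture; articulating pairs are
bridged by soft tissue and whitelisted); COP under the whole-body COM
in x within 1 mm (the mediolateral offset is balanced by Mₓ and any
x-residual by M_y, which stays ≪ BW·COM-height); and step width
(2·|COP_y|) under 15% of hip height. The `repair_posture` routine
enforces these by slaving the MTP angle (pes flat on the ground), the
ankle (root find on the COP–COM x offset) and, when the step width
binds, hip long-axis rotation (fallback: abduction) — so those
coordinates are constraint-followers while hip extension and knee
flexion remain the primary search coordinates.

**External loads.** Quasi-static: gravity plus a vertical 1 BW ground
reaction force at the COP. With body mass 1.56 kg and g = 9.81 m/s²,
BW = 15.304 N. The applied pes moment vector is the exact closure of
the global wrench balance; the reported scalar Mₓ = BW·(COP_y − COM_y)
follows the ground-reaction sign convention (the vector applied to the
pes is its negative).

**Static optimization.** Activations minimize Σa² subject to moment
balance at the six free DOFs, 0 ≤ a ≤ 1, with all actuator maximum
forces equal to 2 BW by default (a per-muscle mode with
architecture-derived forces, isometric stress 3×10⁵ N/m², runs through
the identical solver path). Ligaments are linear reserve actuators
without slack length or elasticity. Moment arms use the tendon
excursion definition r = −dL/dθ with central differences of 0.05°;
generalized external moments come from virtual work with the same
differencing, so muscle and load terms are exactly conjugate. The MTP
reserve (capacity 1000 Nm) enters only the MTP row; its activation
M/1000 carries a quadratic objective weight (default 1), making the
problem a strictly convex QP with a unique solution. The QP is solved
by a semismooth Newton iteration on the 6-dimensional dual of the
box-constrained least-norm problem (KKT residual tolerance 1e-10,
inclusive treatment of the clip kink); tests cross-check it against an
independent SLSQP solve to 1e-6 on 50 random systems. Infeasibility
(moment demands beyond actuator capacity, e.g. extreme crouches where
the required plantarflexion exceeds 2 BW × available arms) raises an
error naming the unbalanced DOFs; the posture search treats such
candidates as inadmissible.

**Joint reactions.** Newton–Euler distal→proximal with gravity,
polyline actuator point forces (the tension pulls every attachment and
via point along the local tangents; the set is self-equilibrated), the
external loads and the MTP reserve as an internal moment pair. The
hip, a ball-and-socket, carries no reaction moment once the three hip
rows are balanced; per-segment residuals are audited below 1e-9.

**Finite elements.** Constant-strain 4-node tetrahedra, isotropic
linear elasticity (bone 17 GPa/0.3/2060 kg·m⁻³, cartilage 50 MPa/0.45,
knee soft-tissue composite 100 MPa/0.3; MPa table values converted to
SI on load). Two simulations per posture: the femur (restrained on the
acetabular bookend's outer face, knee force applied via the
proximal-crus bookend) and the tibiotarsus+fibula (restrained on the
proximal-tarsometatarsus bookend, knee force via the distal-femur
bookend). Muscle forces attach to the same geometric points as in the
statics, snapped to the nearest focal-bone surface node and spread
evenly over the ~20 nearest surface nodes. Joint forces are
minimum-norm statically equivalent nodal distributions whose resultant
passes through the knee centre with zero moment (an explicit
distribution rather than the multipoint kinematic constraints of
commercial codes; the stated contract — correct resultant through the
joint centre — is preserved and unit-tested against a pseudo-inverse
oracle). The knee moment is an equivalent nodal couple on the focal
bone's contact face; the ankle moment is deliberately *not* applied in
the tibiotarsus simulation (the restraint sits too close to transmit
it; a flag enables it for exploration). Segment weight acts through a
remote point at the segment COM. Inertia relief (mass-proportional
d'Alembert loads cancelling the net force and moment) is available for
unrestrained load sets and balances arbitrary loads to < 1e-9
relative; the bookended driver solves with restraints. Nodal stress is
the volume-weighted average of adjacent element stresses within one
entity (never across material interfaces); the patch test is exact.

**Trajectories and scoring.** Principal stresses by symmetric
eigendecomposition, sorted σ₁ ≥ σ₂ ≥ σ₃, directions treated as axial
(canonical sign: first non-negligible component positive). Nodes with
near-repeated eigenvalues (relative gap < 1e-6) are flagged degenerate
and excluded from regional means. Directional statistics are
orientation-tensor based: the regional mean is the dominant
eigenvector of (1/N)Σvvᵀ, and angles are arccos|a·b| ∈ [0°, 90°].
Because fabric is a bone property, stress fields are rotated into the
bone-local frame before comparison. Scored regions (all in bone-local
coordinates): femoral head (sphere of half the fitted head radius,
centred half a radius under the loaded surface), medial femoral
condyle (one third of the fitted condyle-sphere radius at the
anatomical condyle centre), a trochanteric femur region, and proximal
and distal tibiotarsus regions. Weights default to femoral head 2,
others 1 — the head has priority, and the tibiotarsus regions
formalize the whole-limb correspondence that otherwise guides the
search only qualitatively (they are also what makes the knee angle
identifiable in the inverse problem). When a prescribed region is
small relative to the mesh's nodal spacing, the regional mean falls
back to a deterministic sub-grid of the sphere with nearest-sample
interpolation. The mid-shaft summary reports torsion obliquity as the
mean per-node angle between the more axis-parallel principal family
and the long axis (a mean *direction* would cancel the circumferential
components of a helix), torsion sense from the circumferential drift
of the σ₁ helix, and the bending neutral surface from a linear fit of
the axial stress across the section.

**Search.** The posture refinement is a deterministic coordinate
descent over the joint hierarchy (hip extension, then knee flexion,
then the hip coronal angles), steps 10° → 5° → 2.5°, each candidate
repaired to admissibility before evaluation, accepted only on strict
improvement of the weighted score (improvements under 0.5° count as
"similar" at the coarser steps), terminating when a full sweep at the
minimum step yields nothing further. The audit trail records every
evaluated posture with its score and constraint report; the accepted
score sequence is non-increasing by construction.

## Synthetic study conditions

The generator emulates a 1.56 kg chicken-scale biped: limb mass
0.159 kg (thigh 0.100, shank 0.045, tarsometatarsus 0.010, pes 0.004 —
the per-segment split is the package's own choice at realistic avian
proportions), so the pelvis segment (body minus limb) is 1.401 kg with
its COM 0.068 m anterior to the hip and level with it. Bone lengths:
femur 75 mm, tibiotarsus 110 mm, tarsometatarsus 72 mm, pes prism
55 × 14 × 8 mm. The femoral head is an exact sphere band (radius
4.5 mm, offset 4.5 mm medially from the shaft axis) so sphere fitting
is noiseless; the cnemial crest and a lateral fibular lobe (merging
distally, i.e. the fibula is fused) flare the proximal tibiotarsus.
Mid-stance actuator activity flags and the 38-actuator topology follow
the avian arrangement at reduced fidelity; attachment sites are
idealized coordinates, with via points emulating the patellar tendon
(anterior knee), the hypotarsal canal (posterior ankle pulley) and the
plantar MTP channel. All meshes are mapped structured hex grids split
into 12 tetrahedra per cell about a centre node, faces triangulated
along their shortest diagonal by a purely geometric rule — so
independently generated blocks that share a face grid (bone ↔ joint
soft tissue ↔ bookend) are conformal and bonded contact reduces to
node sharing. Mesh edge lengths respect the cap of twice the parent
surface's mean (equilateral-equivalent) edge length.

Forward-generated fabric takes the σ₃ axial directions of the pipeline
at a chosen posture as u₁ (σ₁ optionally in tension-dominated regions
such as the anterior cnemial crest), perturbed by rotating each axis
about a random perpendicular through a folded-normal angle — seeded,
axial, and monotone in the requested standard deviation. Archetype
fabric blends per-region axes through inverse-distance-weighted
orientation tensors.

What passing tests show: the pipeline is self-consistent (its forward
fabric is a fixed point scoring exactly 0°), internally equilibrated,
linear in loads, and invertible to within ~one coarse step under 5°
axial noise on this geometry. What they do not show: that real
trabecular fabric obeys the trajectorial hypothesis, that the
idealized geometry reproduces any particular species' stress fields,
or that quantities tied to real anatomy (specific deviation angles,
degree-of-crouch values, muscle-by-muscle activation magnitudes)
transfer. Printed reference values reproduced here are restricted to
arithmetic consequences of stated inputs (mass bookkeeping, deviation
reductions).

## Numerical choices and degenerate inputs

* Finite-difference step for excursions and virtual work: 0.05°;
  QP dual tolerance 1e-10; FE solves by sparse Cholesky-like direct
  factorization (SuperLU).
* Problem sizes: default section grid 4×4 cells, stations every
  ~3–4 mm (≈ 5,000–6,500 tets per bone; assembled bone cases ≈ 8,000
  tets / 1,700–1,900 nodes), one FE solve ≈ 0.5 s and one full posture
  evaluation ≈ 1.5 s on one CPU; a posture search converges in ~30–60
  evaluations. The recovery experiments use targets offset (+8°, −6°)
  from the mid-stance start, chosen inside the statically feasible
  basin of the 2 BW actuator set.
* Degenerate inputs: zero-area surfaces, non-positive tet volumes,
  coplanar sphere fits, zero-length actuator path segments,
  non-symmetric stress tensors, empty scoring regions and zero-mass
  inertia relief all raise typed errors rather than propagating NaNs.
* Ties: the shortest-diagonal face split breaks exact ties
  lexicographically on coordinates, so conformality holds even for
  perfectly regular (cubic) cells.

## Design choices where the design was open

* The fibula is a lateral lobe of the tibiotarsus section rather than
  a separate rod: the two are one bonded entity in every use, and a
  single conformal sweep keeps the mesh machinery simple and testable.
* The MTP reserve enters the objective quadratically (activation
  M/1000 Nm, weight 1) rather than through a linear penalty: this
  keeps the program a strictly convex QP and matches standard
  static-optimization practice for reserve actuators; its huge
  capacity still makes it near-free, fulfilling the "used when muscles
  cannot reasonably balance" role.
* The degree-of-crouch metric is pluggable (registry); the default is
  1 − hip height / total functional limb length, which is 0 for a
  fully extended vertical limb. No published value is asserted for it.
* Scoring includes tibiotarsus regions (see above) — quantified stand-ins
  for whole-limb qualitative correspondence; weights are configurable.
* Bone-case restraints default to the entire outer face of the far
  bookend; the sub-surface offset of the femoral-head region defaults
  to one region radius. Both are config-exposed.

## Known limitations

* Constant-strain tets are stiff in bending: the cantilever benchmark
  needs the refined (8×2×40) bar to reach <10% of the Euler–Bernoulli
  surface stress, and absolute stress magnitudes on the coarse bone
  meshes are correspondingly approximate. Principal *directions*, the
  quantity the method actually consumes, are much less sensitive.
* No wrapping surfaces: via points are fixed in their host segments,
  so moment arms change less smoothly than with true tendon wrapping
  at extreme joint angles.
* The static feasibility basin of the uniform 2 BW actuator set on
  this idealized geometry excludes deep crouches (the plantarflexor
  demand outruns capacity); the search treats those postures as
  inadmissible rather than extrapolating.
* Single quasi-static load case per posture; no dynamics, no load-case
  ensembles, no remodelling feedback, no anisotropic material update.
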