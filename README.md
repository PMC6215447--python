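# osteotraj

Reverse trajectorial posture estimation for a bipedal hindlimb.

Cancellous (trabecular) bone adapts its strut architecture to habitual
loading: its primary fabric direction **u₁** aligns with the
continuum-level principal stress trajectories of normal use (the
trajectorial theory). Run forward, one simulates a posture and checks
the stresses against the fabric. `osteotraj` runs the idea *in
reverse*: given a musculoskeletal model of a bird-like hindlimb and an
observed (or synthetic) fabric field, it searches for the quasi-static
limb posture whose minimum-principal-stress (σ₃, compressive)
trajectories best align with **u₁** — an inverse approach to inferring
posture from bone architecture, aimed at comparative and
palaeobiological biomechanics.

Each candidate posture is evaluated by a three-stage forward pipeline:

1. **Musculoskeletal statics.** The limb (pelvis fixed; ball-and-socket
   hip, hinge knee/ankle/metatarsophalangeal joints; 38 via-point
   musculotendon actuators) is loaded with a vertical ground reaction
   force of 1 BW at the pes centroid, plus a mediolateral moment
   `Mₓ = BW·(COP_y − COM_y)` and a small M_y so the system is in exact
   static equilibrium. Muscle redundancy is resolved by minimizing
   Σa² subject to moment balance at the six free degrees of freedom
   (0 ≤ a ≤ 1, each actuator contributing `Mᵢ = a·F_max·rᵢ`, moment
   arms by tendon excursion, a 1000 Nm reserve at the MTP joint).
2. **Finite elements.** Two linear-elastic 4-node-tetrahedral
   simulations per posture — femur, and tibiotarsus+fibula — with the
   focal bone bookended by trimmed neighbouring bones, joint soft
   tissues as single bonded volumes, muscle forces spread over ~20
   surface nodes at the same attachment points used by the statics,
   the knee force introduced through the neighbouring bookend via a
   remote point at the knee centre, the knee moment applied directly
   to the contact surface, and segment weight via a remote point at
   the segment COM.
3. **Trajectory comparison.** Eigenanalysis of the nodal stress
   tensors; regional axial means of σ₃ are compared with **u₁**
   (angles are sign-free, `arccos|a·b|`) in spherical regions — the
   femoral head and medial condyle foremost — and combined into a
   weighted score in degrees that the posture search minimizes by
   deterministic coordinate descent over the joint hierarchy.

Because no scan data ships with the package, a first-class synthetic
generator builds an idealized chicken-scale hindlimb (1.56 kg body,
0.159 kg limb, 75 mm femur with an offset spherical head) as conformal
structured tet meshes, and synthetic fabric fields are either
forward-generated from a known posture (with seeded axial noise) or
analytic archetypes.

## Worked example

```sh
osteotraj generate-limb --out model.yaml --seed 1
# -> model written to model.yaml (pelvis segment 1.401 kg)

osteotraj pose --model model.yaml --posture start.yaml --out posed.yaml
# repaired admissible posture (degrees):
#   hip_extension -30.0, hip_abduction 5.0, hip_lar 2.2,
#   knee_flexion 93.0, ankle_flexion 70.2, mtp_angle 37.3
# degree_of_crouch: 0.264

osteotraj solve-statics --model model.yaml --posture posed.yaml \
    --out-csv activations.csv --out-json joints.json
# activations.csv, e.g.:  FMTE,0.492146158,15.0632159

osteotraj make-fabric --model model.yaml --posture posed.yaml \
    --noise-sd 5 --seed 2 --out-prefix fab
osteotraj score --model model.yaml --posture posed.yaml \
    --fabric-femur fab_femur.csv --fabric-tib fab_tibiotarsus_fibula.csv \
    --out score.yaml
# weighted score 0.93 deg, per-region deviations (deg):
#   femoral_head 1.28, medial_condyle 1.87, trochanteric 0.68,
#   proximal_tibiotarsus 0.29, distal_tibiotarsus 0.19
```

Reading the numbers: the pelvis segment is the body minus the modelled
limb (1.560 − 0.159 = 1.401 kg). The repair step keeps the pes flat on
the ground, puts the centre of pressure under the whole-body COM and
the step width below 15% of hip height. The score is the weighted mean
angular deviation between σ₃ and **u₁** over the scored regions — here
about 1°, because the fabric was forward-generated at this very
posture with 5° noise, so the posture is (up to noise) its own
solution. `osteotraj search` then minimizes exactly this number over
postures; `osteotraj report` summarizes a finished run from its audit
CSV.

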