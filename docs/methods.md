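# Methods

This note records the modelling choices, numerical settings and study
conditions behind `tarsus`, and what the synthetic-data tests do and do not
demonstrate.

## Model and coordinate conventions

All internal quantities are SI (metres, newtons, radians, seconds); marker
files in millimetres are converted on read, and registration residuals are
reported in millimetres.  Segment frames are right-handed with X anterior,
Y up and Z lateral (right side) in the reference pose; each segment's
origin is its proximal joint centre.  Joints compose an ordered sequence of
rotations/translations about joint-frame axes; the joint frame orientation
is stored identically on the parent and child side so the zero state
reproduces the reference pose exactly.  Knee coupling (Walker-style derived
translations/rotations as polynomials in knee flexion) is a pluggable
per-joint hook, off by default; the coefficients are user-supplied
configuration.

Muscles are via-point polylines and ideal force generators
(force = a·F<sub>max</sub>): no force–length–velocity scaling, no wrapping
surfaces.  Polylines reproduce the point-perturbation protocol directly;
an activation-independent force model keeps the redundancy problem a
box-constrained quadratic program.  Ligaments are carried as inert records
(never simulated): their in vivo mechanical properties are too uncertain to
contribute meaningfully.

The template's dimensions, inertial parameters and
F<sub>max</sub> values are documented, literature-plausible placeholders
sized for a juvenile (~1.45 m, 50 kg) lower limb.  They are configuration,
not code, and are deliberately not presented as any published model's
values.  Segment masses are distributed from the patient's total mass by
Dempster-style fractions (foot split 60/30/10 across
hindfoot/forefoot/toes).

## Geometry

**Registration** uses Horn's closed-form quaternion solution on named
corresponding landmarks (no iterative closest point: correspondence is
known).  Degeneracy rule: the configuration is rejected when the second
singular value of the cross-covariance falls below 1e-10 of the largest —
i.e. when the common points are collinear, which leaves the rotation
undetermined.  Planar sets (including the minimum of three points) are
fine.  The quaternion construction cannot return a reflection.

**Cylinder fitting** minimises Σ(dist-to-axis − r)² by trust-region least
squares (tolerances 1e-14) over axis point, axis direction (spherical
angles) and radius, initialised from each principal component of the cloud
in turn (best fit kept); the axis point is gauge-fixed to the centroid's
axial projection.  Near-coplanar clouds (smallest PCA eigenvalue < 1e-12 of
the largest) are rejected as ill-conditioned.  The "centre of the cylinder"
is the midpoint of the fitted axial extent — the only well-defined centre
of a finite patch.

**Ankle frames.**  The MR frame takes the fitted cylinder axis as the
flexion axis exactly (oriented medial→lateral using the malleoli), origin
at the cylinder centre, vertical axis towards the knee joint centre
orthogonalised against the axis.  The CGA frame follows the multi-segment
foot-model shank recipe: origin at the inter-malleolar midpoint, vertical
axis to the knee joint centre, anterior axis perpendicular to the plane of
the vertical axis and the inter-malleolar vector.  Both frames are stored in
the assembled model; either can be installed as the ankle joint's axes and
centre.

## Patient-model assembly

Stage order (each stage logs its transform and residual): static-trial
averaging → pelvis/femur/shank scaling → foot-markers-to-MRI registration →
MRI-to-model registration → per-segment muscle-point mapping → cylinder fit
→ ankle frame construction → leg registration → femur rotation optimization
→ pelvis registration.  Pelvis scaling is anisotropic with depth→anterior,
height→vertical, width→lateral (the dimensional recipe names distances, not
axes; this assignment is this package's convention).  The foot is assumed
rigid between the MRI pose and the standing trial; the logged residuals
expose the cost of that assumption on real data.  The femur-rotation stage
minimises the palpated-to-measured greater-trochanter distance over a
rotation about the knee flexion axis by bounded Brent search (tolerance
1e-10 rad); the left limb is not modelled, so the left-side pelvis-region
markers needed by the scaling rules ride on the pelvis segment.

## Simulation

**Inverse kinematics**: per frame, Levenberg–Marquardt least squares over
the unlocked coordinates (uniform marker weights by default), warm-started
from the previous frame.  The midfoot coordinates and the internal/external
ankle rotation are locked at zero throughout simulation: the GRF cannot be
distributed across the foot segments, and the ankle's bony/ligamentous
constraints are assumed to carry the internal/external rotation moment.

**Inverse dynamics** is quasi-static by default (virtual-work projection of
the plate wrench and segment weights onto each DoF axis); this matches the
free-body reasoning appropriate for walking, where inertial contributions
to the ankle moment are sub-percent (the `full` mode with central-difference
accelerations and optional 6 Hz low-pass agrees within 1% on the synthetic
gait).  Returned generalized forces are the moments internal structures
must produce.

**Moment arms** use the tendon-excursion definition, central differences
with δ = 1e-5 rad; a plantarflexor therefore has a negative dorsiflexion
moment arm.

**Static optimization** minimises Σa² subject to moment equality on the
free DoFs (hip ×3, knee, ankle flexion, ankle inversion/eversion, plus MTP
flexion only on frames where the toes carry load) and 0 ≤ a ≤ 1.
Feasibility is established per frame by an L1-slack linear program (HiGHS),
which also names the violated DoF on failure; the QP is then solved by
SLSQP from the LP point and verified to satisfy every constraint to
1e-6 N·m.  Reserve actuators are idealized per-DoF torques penalised by
w(r/τ₀)² with w = 1000 and τ₀ = 1 N·m; `reserves="auto"` enables them only
after an infeasibility.  Pelvis residual DoFs are never constrained
(ground-referenced free body).

**Joint reaction**: the ankle JRF is the bone-on-bone contact force on the
foot free body — minus the sum of the applied plate wrench force, the
foot-segment weights and the ankle-crossing muscle forces (each acting
along its crossing strand) — expressed in the installed ankle frame and
normalised by body weight.

The 2SEG switch is latched: once the centre of pressure has passed the MTP
axis along the foot's anterior direction the load stays on the toes, so COP
noise near the axis cannot cause chatter.

## Synthetic study conditions

The generator's defaults define the conditions under which the pipeline's
behaviour is exercised; they were chosen once, as a realistic composite, and
are not fitted to data:

| quantity | default | rationale |
|---|---|---|
| talar dome cylinder radius | 20 mm | juvenile talus |
| dome arc / axial half-length | 70° / 14 mm | articular patch actually visible in MRI |
| dome axis tilt | 15° internal about vertical | talar axis vs malleolar line discrepancy; drives the MR/CGA frame difference |
| GRF vertical humps | 1.1 / 0.8 / 1.2 BW | textbook double hump |
| stance / rates | 0.7 s; 100 Hz markers, 1 kHz plate | typical clinical capture |
| COP path | heel-lateral → midfoot dwell → hallux, ending 38 mm medial of the ankle-centre line | push-off through the first ray |
| push-off shear | +0.16 BW propulsive, −0.05 BW medial | medially directed force under the hallux |
| vertical free moment | 4 N·m peak | small-child magnitude |
| joint angle knots | ankle −15…+8°, knee 5–30° flexion, hip −10…+20°, MTP 0–20° | smooth, gait-like; exact values irrelevant to the oracle tests |

The pelvis translation is solved per frame so the ankle centre stays put (a
planted stance foot); walking markers come from forward kinematics of these
trajectories, so inverse kinematics has an exact recovery oracle.  Under
these conditions the MR-axes model solves without reserves with a
double-hump ankle JRF peaking near 5.7 BW, while the CGA (malleolar) frame
— rotated ~15° from the dome axis — accumulates an eversion demand at
push-off a few N·m beyond the peroneal capacity, so static optimization
fails on the inversion/eversion axis unless reserve actuators are enabled.
That margin is a property of these study conditions (axis tilt, medial COP
and shear, juvenile evertor strength); it reproduces the qualitative
phenomenon, not any particular patient.

What the synthetic data does **not** emulate: soft-tissue artefact,
marker-placement error between sessions, segmentation noise, non-rigid foot
deformation between MRI and standing, force-plate calibration error, and
real inter-trial variability beyond small smooth knot jitter.  Passing
oracle tests therefore demonstrates internal correctness of the pipeline's
mathematics, not accuracy on real patients.

## Numerical notes and limitations

* IK tolerances 1e-14 (xtol/ftol/gtol); noiseless synthetic markers are
  recovered to better than 1e-6 rad.  A frame that fails to converge keeps
  the previous frame's solution and warns.
* Stance detection: longest run of vertical force above 20 N (configurable);
  sub-threshold frames inside the stance window carry a zero wrench.
* Stance curves are resampled to 101 points (0–100%) before averaging
  across trials; percentage JRF changes are signed (perturbed minus
  original), tables report the stance mean and the largest-magnitude stance
  value, averaged across trials; muscles enter the report at
  |mean| ≥ 0.5%.
* Perturbations are applied one at a time, both signs along each hindfoot
  axis; the Achilles insertion (shared by soleus and both gastrocnemius
  heads) moves as a single structure.
* The force-plate-to-model ground rotation is explicit configuration; it is
  never guessed from the data.
* Known limitations: single right limb; no muscle dynamics or wrapping; no
  ligament mechanics or articular contact; quasi-static by default; the
  hybrid model's provenance log is the only record of registration quality —
  on real data those residuals will not be zero and should be inspected.
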