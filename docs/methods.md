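# Methods

## Model structure

The upper limb is a five-segment serial chain rooted in an inertial
thorax frame (x to the subject's right, y anterior, z superior; gravity
9.81 m/s² along −z).  Eleven generalized coordinates parameterize nine
degrees of freedom: intrinsic Euler triplets at the sternoclavicular
(Z-Y-X), acromioclavicular (Z-Y-X) and glenohumeral (Y-X-Y; plane of
elevation, elevation, axial rotation) joints, one hinge for elbow
flexion/extension about the ulnar x-axis and one for pronation/supination
about the radial z-axis.  The sequences are configurable per joint.  Two
holonomic constraints keep the scapular TS and AI landmarks on ribcage
ellipsoids; their Lagrange multipliers enter the load sharing as two
extra unknowns with the constraint Jacobians as generalized moment arms.

Every segment rotation is composed as `R = R_parent · C · E(q)` with a
fixed alignment rotation `C` computed once from the reference pose.  This
deliberately deviates from strict ISB frame alignment: the alignment
rotations make the stored reference geometry exact at the reference
coordinates and absorb anatomical offsets such as the fixed elbow
carrying angle, which an inherently aligned parameterization cannot
represent.  A fixed carrying angle is a known limitation: task-space
elbow kinematics at extreme pronation are approximated.

Geometry is stored as thorax-frame positions at the reference pose plus
an attached-segment token per point; bone-frame locals and alignment
rotations are derived at build time.  Equality between models is float
comparison at 1e−12 relative, the double-rounding floor of the cm↔m
schema conversion.

## Dynamics

The Lagrangian sums, per segment, translational and rotational kinetic
energy (diagonal bone-frame inertia) minus gravitational potential.
Generalized loads are evaluated by central finite differences:
the velocity gradient of the quadratic kinetic energy (exact up to
round-off at step 1e−3 rad/s), a directional time derivative along
(q̇, q̈) at step 1e−6 s, and a configuration gradient at step 1e−6 rad.
Against a closed-form statics oracle the residual is ~1e−10 relative;
energy consistency along dense trajectories holds to better than 1e−4.
The choice of differences over symbolic algebra keeps the formulation
robust to arbitrary model edits.

Segment inertias use transverse/lateral gyration radii about each bone's
long axis (x for the ulna per its anatomical frame, z for the radius,
y for the humerus).  The hand is a point mass (default 0.6% body mass)
plus an inertia block rigidly tied to the radius, folded in by the
parallel-axis theorem; only the diagonal of the shifted tensor is kept,
since the hand offset is nearly axial in the radius frame.  Clavicle and
scapula gyration radii are not covered by the predictive BSIP table; they
default to 30% of the geometric segment length, isotropic, and are
flagged as model parameters rather than predictions.

## Muscle paths and moment arms

Paths are massless strings routed origin → via points → insertion with at
most one analytic obstacle (sphere or cylinder) per gap, solved by the
single-obstacle construction: straight tangents joined by a geodesic arc,
engaged exactly when the chord penetrates the obstacle, C¹ at the tangent
points.  Spheres take the shorter circulation (a sphere has no preferred
side); cylinders store a per-muscle `wrap_side` so paths never flip
between frames.  Moment arms are computed two ways: tendon excursion
(−∂L/∂q, central difference at 1e−5 rad) and geometric (unit-tension
point forces crossed with the instantaneous joint axes, arc points
attached to the obstacle's segment).  The two agree to ~1e−5 relative on
smooth paths; the 1% agreement bound in the tests is dominated by arc
discretization (24 points) at wrap transitions.

## Load sharing

Per frame the QP minimizes f̃ᵀPf̃, P = diag(1/PCSA²) with a 1e−9
regularization weight on the two multiplier entries to keep the objective
strictly convex.  Bounds are 0 ≤ f ≤ σ·PCSA with σ = 25 N/cm² (a maximum
muscle stress consistent with small rotator-cuff reserves of tens of
newtons at ~2 cm²), and λ ≥ 0 (the ribcage pushes, never pulls; ellipsoid
normals point outward).  The glenohumeral stability constraint linearizes
a circular cone (apex at the humeral head center, axis through the
glenoid center, aperture the mean rim angle, default eight inscribed
facets) acting on the reaction force, which is affine in the muscle
tensions; the problem therefore stays a QP.

The solver is two-stage: scipy's trust-constr (or, warm-started, a
bounded-least-squares feasibility phase with slacked cone rows) provides
a feasible point, and a primal active-set iteration with exact KKT solves
terminates at the analytic optimum (stationarity ~1e−12; verified against
exhaustive active-set enumeration on small instances to 1e−8).  Warm
starts across frames make the sweep roughly 20× faster than interior
point alone.

The reaction force is assembled by Newton–Euler back-substitution over
the arm segments: muscle pulls applied to humerus/ulna/radius path points
plus gravity and center-of-mass inertia loads.  The constraint
multipliers act on the scapula and do not enter the glenohumeral
reaction.

## Synthetic anatomy and trajectories

The generator emulates a right-side adult male (1.86 m, 85.5 kg) from
hard-coded landmark proportions.  Its guarantees: ribcage ellipsoids are
exact dilations of the base ellipsoid through the reference TS/AI;
glenoid rim points are constructed *from* the requested inclination
(default 7°) and version (default −5°) so measurement round-trips are
exact; HU is the epicondyle midpoint; ulna/radius mass centers sit at the
midpoints of their proximal-to-styloid chords.  Rotator-cuff PCSAs
(20.84/33.32/35.68/6.80 cm² for supraspinatus/infraspinatus/
subscapularis/teres minor) follow the large whole-group convention, and
all other PCSAs were chosen on the same convention so the stress-squared
objective weighs muscles consistently.  Deltoid attachments were placed
so the abductor moment arms follow the physiological profile — rising to
~35 mm near 60–80° of elevation and declining at high elevation — which
is what makes the reaction force peak above 100° of abduction.  A nonzero
seed jitters only non-wrapping muscle attachments (1 mm SD) and non-cuff
PCSAs (3% SD); bone geometry, wrap clearances and study-condition values
are seed-invariant.

Synthetic abduction uses a minimum-jerk thoraco-humeral elevation
profile with a 2:1 glenohumeral-to-scapulothoracic rhythm; per frame the
shoulder-girdle coordinates are projected onto the constraint manifold by
a Gauss–Newton minimum-norm step (|Φ| < 1e−11) and the glenohumeral
plane/elevation coordinates are solved so the thoraco-humeral angle is
exact.  Marker-based inverse kinematics is a per-frame nonlinear least
squares over all eleven coordinates with the ribcage constraints in
penalty form (weight 1e4), warm-started frame to frame; noise-free
round-trips recover coordinates to ~1e−13 rad.

What the generator does not emulate: true bone surface geometry,
inter-subject shape variation, soft-tissue artifact in markers,
muscle-path branching over real tuberosities, and co-contraction.
Passing tests therefore validate the computational machinery and the
qualitative parameter responses, not subject-level predictive accuracy.

## Scaling

* BSIP: per-gender coefficients; masses in percent of body mass, lengths
  as stature fractions, inertias from gyration fractions of segment
  length; ulna/radius split the forearm mass 62/38.
* Morphology: all stored positions map through S; wrap radii scale by the
  mean in-plane diagonal entry (axis-orthogonal weighting for cylinders)
  since an anisotropic S has no single radius factor.
* Ribcage: the dilation polynomial is assembled by convolution and solved
  with the companion-matrix root finder, then polished by Newton to a
  substitution residual < 1e−10.  Exactly one admissible root (all
  semi-axes positive) exists; it is negative for shrinking subjects,
  which is geometrically correct — the landmark maps inside the base
  ellipsoid — and positive in the enlarging cases.
* Glenoid: inclination/version are measured from rim-vector projections
  in the scapular frame; adaptation applies the two rotation operators in
  a fixed-point loop (they couple at second order) about the humeral head
  center, so the stability-cone axis tilts by exactly the applied
  inclination change.  Round trips recover targets to < 1e−9 deg.
* PCSA: scaled by the subject-to-generic muscle-percentage ratio;
  subject-specific overrides replace scaled values exactly.  Out-of-range
  BMI warns and evaluates at the clamped bound.
* The height scenario of the parameter study covaries shoulder width with
  stature: a taller subject is proportionally wider, S is near-isotropic,
  and the gravity-lever and moment-arm growth cancel — the mechanism
  behind the near-zero height effect.  Holding width fixed instead
  changes the peak reaction force by about 6%.

## Problem sizes and numerical defaults

Default simulations run 131 frames over 20–150° of abduction; the
six-scenario parameter study completes in roughly two minutes on one
core.  Wrap arcs use 16 points for lengths and 24 for force resolution;
QP feasibility tolerances are 1e−9, stationarity is exact at the active
set; trajectory derivatives are second-order finite differences on the
sampled grid.
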