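# Methods

## Model

The lower limb is modelled as five rigid segments — pelvis, thigh, patella,
shank, foot — articulated by the hip (spherical, 3 rotational DOF), the
tibiofemoral joint split into medial and lateral compartments, the
patellofemoral joint, and the ankle. All segments move freely except the
thigh, whose translation is eliminated through the pelvis hip centre.
Muscles are ideal frictionless cables: straight line elements from origin
to insertion through optional via points, with uniform tension along the
element. Two surfaces may deflect elements around a cylinder (in the
shipped toy anatomy, a femoral-condyle cylinder for a gastrocnemius-like
element). Articular loads are unconstrained 3-vector contact forces applied
at documented contact points: the femoral-head centre (hip), the medial and
lateral tibiofemoral centres, the patellofemoral centre, and the ankle
centre. The patellar tendon is a tensile ligament element (bound 0–20 BW)
excluded from the muscle-stress objective; in the toy anatomy it is split
into two bands so the patella's moment balance has a full positive force
cone together with the patellofemoral contact.

### Equations of motion

For each dynamic segment m ∈ {foot, shank, thigh, patella} the 6-component
Newton–Euler balance about the segment's proximal joint rotation centre
(JRC) reads

    Σ forces  = M (a_com − g)
    Σ moments = M c̃ (a_com − g) + I ω̇ + ω × I ω

with c the lab-frame vector from the proximal JRC to the centre of mass, c̃
its cross-product matrix and I the lab-frame inertia about the centre of
mass. Muscle terms enter through per-path-point force records (each path
point applies F times the unit vector toward its neighbouring path points
to its host segment; a wrap applies the reaction of the two tangent-segment
tensions to the cylinder's segment at the tangent points — these records
sum to a zero wrench per element). The ground-reaction wrench is applied to
the foot at the centre of pressure. The pelvis carries no equation of
motion: its pose is tracked but its dynamics are not constrained, so the
system has 24 equality rows.

### Force sharing

Per frame the package solves

    min  Σᵢ (Fᵢ/Fᵢᵐᵃˣ)² + α ‖J_hip‖ / BW
    s.t. A x = b (24 equalities),  0 ≤ F ≤ Fᵐᵃˣ,  contacts free,

a convex program (quadratic + Euclidean norm, linear constraints, box
bounds). The production path scales variables (forces by Fᵐᵃˣ, contacts and
rows by BW), smooths the norm with δ = 10⁻⁸ BW, runs SLSQP twice (the
restart removes premature-termination bias of warm starts), and finishes
with an exact active-set refinement: null-space damped-Newton on the
current face, feasible line steps to the first blocking bound, release by
bound-multiplier sign. The refinement terminates at the exact optimum of
the convex program, so warm starting is purely a performance device. An
independent oracle (trust-constr interior point, cold start, δ = 10⁻⁹ BW,
analytic Hessian, same refinement) is used for ground truth and for
cross-checks; agreement between the two routes is at the 10⁻¹⁰ relative
level on toy problems. A frame is reported converged only when the scaled
equality residual is ≤ 10⁻⁸ BW (tests check 10⁻⁶ BW).

α defaults to 1. The α sweep utility exposes the scalarisation trade-off:
mean ‖J_hip‖ is non-increasing and the summed squared stress non-decreasing
in α; α = 0 recovers the classical minimum-squared-stress solution.

## Key parameters

| parameter | default | units | role |
|---|---|---|---|
| σmax | 31.39 | N/cm² | maximum muscle stress; Fᵐᵃˣ = σmax·PCSA |
| α | 1.0 | – | weight of ‖J_hip‖/BW in the objective |
| strength modifiers | ankle/knee 0.70, hip add./ext. 0.75, hip abd. 0.50 | – | ageing + hip-surgery reduction of Fᵐᵃˣ per group |
| filter | 4th-order Butterworth, 10 Hz, zero-phase | – | marker low-pass |
| calibration window | 0.1 | s | static-trial averaging window |
| g | (0,0,−9.81) | m/s² | lab frame, +Z up (configurable) |
| ligament bound | 20 | BW | patellar-tendon upper bound |

Segment inertial parameters come from an editable regression table
(fractions of body mass, of segment length for the centre-of-mass position,
and radii of gyration); the shipped default encodes generic adult-male
values of the de Leva/Zatsiorsky family, with a small nominal patella entry
that the regression sources do not tabulate.

## Numerical choices

- **IK**: rotation vectors per frame (singularity-free across per-frame
  increments), Levenberg–Marquardt on stacked marker residuals, thigh
  translation eliminated through the hip constraint (satisfied to machine
  precision by construction), warm start from the previous frame, missing
  markers masked out of the residual. Reported RMSE is over included
  markers.
- **Differentiation**: central differences inside the trial; a four-point
  one-sided second-derivative stencil (exact for cubics) at the first/last
  frame for the linear acceleration, and third-order one-sided stencils for
  the angular acceleration, because chaining two one-sided gradients is
  only first-order accurate at the very ends. Angular velocity is the axial
  vector of dR/dt·Rᵀ.
- **Filtering**: forward–backward (zero-phase) application with odd
  reflective padding. Zero-phase filtering of a finite record still leaves
  a small settling error in the outermost ~0.1 s; this, not the solver, is
  the dominant residual in the end-to-end recovery study (≈0.3 %BW RMS at
  60 Hz).
- **Wrapping**: single-cylinder obstacle-set method computed in the plane
  development of the cylinder; the axial coordinate is linear in developed
  arc length, total length = sqrt(L_planar² + Δz²), which is the exact
  geodesic solution for the tangent–arc–tangent class. The shorter wrap
  sense is chosen; near-ties honour the previous frame's sense
  (hysteresis), exact ties default to the positive-axis handedness.
  On-surface endpoints are permitted (the tangent segment degenerates);
  interior endpoints raise an error.
- **Tie-breaks in metrics**: waveform peaks break ties toward the earliest
  sample; monotone windows are flagged as plateaus. R² is 1 − SSres/SStot
  with the measured waveform as reference (it may be negative), not squared
  correlation — the quantity is prediction quality, not linear association.

## Synthetic data: what it emulates, and what it does not

The generator builds a reduced chain (2–5 segments, 1–4 muscle elements per
joint plus four quadriceps elements and a two-band patellar tendon when the
patella is present) with realistic magnitudes: segment lengths 0.15–0.4 m,
PCSA drawn uniformly from 22–40 cm², marker clouds of four non-collinear
markers per segment, 1 Hz sinusoidal joint motion of 12° default amplitude
with the knee counter-phased to the hip so the ankle stays under the hip (a
double-support-like posture), and a ground reaction of ~0.5 BW applied near
the ankle. Muscle elements are placed azimuthally with alternating helical
offsets so the moment space of every joint is spanned in all three axes
with both signs — necessary because the hip and ankle contacts act at the
proximal JRCs and give no moment authority there. These choices were fixed
once, from a feasibility analysis of the static pose, before any
recovery measurements. Chain kinematics are differentiated analytically
(recursive rigid-body formulas), GRF and inertial terms are mutually
consistent by construction, and the ground-truth force solution is defined
as the convex optimum at the stated α — making "recovery" a well-posed test
of the whole pipeline rather than of an unidentifiable inverse problem.

What passing these tests shows: the implementation chain (filtering → IK →
differentiation → geometry → assembly → optimization → metrics) is
internally consistent and solves its model exactly. What it does not show:
robustness to skin-motion artifact, marker misplacement, force-plate
miscalibration, anatomical mismatch between model and subject, or the
physiological fidelity of the toy geometry; real-data errors are dominated
by those sources. Marker noise is modelled as isotropic Gaussian per
coordinate only; GRF noise is optional and off by default.

Study sizes used by the shipped verification runs: 20 random frame problems
for the solver/oracle comparison; five 6-frame trials × five α values for
the sweep; one 60-frame trial at 60 Hz for the end-to-end recovery; 20
seeds at σ = 2 mm for the IK noise-consistency check, compared to the
linearised expectation σ·sqrt((3N − D)/N) with N markers and D fitted DOF.

## Design decisions where the design was open

- Patella scaling inherits the thigh factor (it is anatomically coupled to
  the femur and the quadriceps path); cylinder radii scale with their host
  segment's (radial-geometric-mean) factor.
- The muscle-stress term uses Fᵐᵃˣ *after* strength modifiers (the
  modifiers change physiological capacity); a configuration switch at the
  anatomy level allows computing Fᵐᵃˣ without them.
- Via points transmit the resultant of the adjacent sub-segment directions
  to their host segment; this is the unique convention that makes every
  element's records a zero net wrench.
- Contact forces carry no direction/cone constraint by default (they appear
  as free vectors in the segment equations); a compression-only option
  would be a modelling extension, not a bug fix.
- Frames are independent convex programs; warm starting cannot change the
  optimum and is used only for speed.
- The GRF enters the foot equation as an external wrench at the centre of
  pressure; without it the per-segment balances cannot close during stance.

## Known limitations

- No activation or contraction dynamics and no force–length–velocity
  properties: the optimization is static, frame by frame.
- Linear (isotropic per-segment) scaling only.
- Single-cylinder wrapping; no sphere/ellipsoid wrapping or muscle–muscle
  contact.
- The classical net-joint-load recursion traverses foot–shank–thigh only;
  patellar inertia (≈35 g) is routed through the patellofemoral contact in
  the optimization but not through the recursion, a discrepancy at the
  10⁻³ N·m level that the cross-module consistency test accounts for
  explicitly.
- Butterworth settling at record edges is the dominant recovery error; for
  real captures, record a margin around the analysed cycle and trim with
  the pipeline's `cycle` window.
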