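# Methods

This note records the models implemented in `handicor`, the conventions and
numerical choices behind them, what the synthetic generators do and do not
emulate, and the design decisions taken where the underlying procedure left
the design open.

## 1. The instant-radius construction

### Kinematics

For two rigid bodies in planar tangent contact, the instantaneous center of
rotation (ICOR) of the relative motion lies on the common normal through the
contact point, and its distance from the contact point equals the slip speed
divided by the relative angular rate — i.e. the sliding displacement consumed
per unit rotation, `dδ/dθ`. This is exact kinematics, not an approximation.

The package computes `dδ/dθ` from the two contact curves in polar form about
a shared pole:

    R*(θ) = √(r_h² + r_h′²) − √(r_b² + r_b′²)

Each square root is a polar arc-length rate, so this identity computes the
slip rate correctly **when the polar angle of each curve advances at the same
rate as the joint rotation angle**. That identification is the working frame
of the whole construction (we call it the *joint polar frame*); it is the
reason the phalanx axis is prescribed as the polar axis, giving a monotone,
shared angle-to-contact mapping for both curves.

### Direction of the instant radius

Two conventions are implemented for the normal direction angle `α`:

* `geometric` (default): the true outward normal of the fitted curve,
  `α = atan2`-angle of `−sign(κ)·J t̂`, with `t̂` the unit tangent
  `(r′e + rJe)/‖·‖` and `κ` the signed polar curvature
  `(r² + 2r′² − r r″)/(r² + r′²)^{3/2}`. The ICOR is placed at
  `contact + R*·n̂` with `n̂` toward the center of curvature, matching the
  statement that the ICOR lies between the contact point and its curvature
  center. For a circular arc about the pole this gives `α = θ` and the hinge
  and rolling limits come out exact.
* `paper`: `α = arctan(−1/r_h′)`, reduced to `(−π/2, π/2]` with `r_h′ = 0 ↦
  π/2`. This treats `r′(θ)` as a Cartesian slope; it coincides with the
  geometric normal only where the radius changes dominate the angular
  advance. It is shipped verbatim and unmodified so that its disagreement
  with the geometric normal is measurable (the oracle suite runs both and
  the tests record that `geometric` matches the velocity-field ground truth
  while `paper` does not on circular arcs). Nothing is silently corrected.

Whatever the mode, the polar radius of the constructed ICOR satisfies the
law-of-cosines form `r_c² = R*² + r_h² − 2R*r_h cos(θ − α)` by construction;
`icor_cartesian` re-derives `r_c` both ways at every sample and refuses to
return if they disagree by more than 1e-6 mm. Angle differences are reduced
to `(−π, π]` before the cosine; a radicand within −1e-9 of zero is clamped.

The signed `R*` carries the sign of `dδ/dθ`; the `sign_convention` option
(`curvature_center` default, `outward` alternative) selects which ray the
positive sign follows.

### Equivalent ICOR

`fit_equivalent_icor` minimizes `Σ w_i ‖c − p_i‖²`; the unique minimizer is
the weighted centroid, computed in closed form. Weightings: `uniform-theta`
(unit weights over a trajectory resampled uniformly in θ; the default,
101 samples in the pipelines) and `arc-length` (trapezoid weights by each
sample's share of the path length, which de-emphasizes regions where the
ICOR lingers in θ). The reported objective uses the raw, unnormalized
weights. Optimality is cross-checked in the tests against a 200×200
candidate grid.

## 2. Synthetic joints and the oracle

### What the generators emulate

A constant **slip ratio** `s ∈ [0, 1]` parameterizes the family: the
base-surface arc rate is `(1−s)` times the head-surface arc rate. `s = 0` is
rolling without slip (ICOR at the contact point), `s = 1` a fixed hinge
(pure sliding; ICOR at the head curve's center of curvature). The rigid
motion is constructed so that the contact point's polar angle advances with
the rotation angle and the material slip velocity at the contact is
tangential with magnitude `s`×(head contact speed); the ICOR of that motion
is exactly `contact + s·√(r_h²+r_h′²)·n̂`. The pose translation is obtained
by integrating `ḋ = ω J (d − ICOR(t))` with DOP853 at rtol 1e-12 (closed
form for the hinge and rolling cases), and the independent
`velocity_field_icor` oracle recovers the zero-velocity point from central
finite differences of the pose (step 1e-6), agreeing with the analytic
ground truth to ~1e-10 mm.

In the joint polar frame the base contact curve of this family is the head
curve **scaled radially by (1−s)** about the pole — the unique representation
for which the arc-rate identity above is exact at every θ (for
`r_b = (1−s) r_h`, `√(r_b²+r_b′²) = (1−s)√(r_h²+r_h′²)` identically). The
generators emit base contact points under this convention; the physical
material trace on the moving bone is retained separately
(`base_trace_body`) and is used by the tests to verify that the two surfaces
share a contact point (to 1e-9 mm) and that the traced arc lengths obey the
slip bookkeeping. A base surface *embedded in the moving body* that makes
the arc-rate identity exact at finite slip while remaining tangent to the
head does not exist (the tangency and polar-advance conditions are mutually
exclusive for 0 < s < 1); the joint polar frame is therefore the study
condition, which is also how the construction is meant to be applied to
measured contact curves.

Pure-sliding bases degenerate to a single material point and are emitted as
an analytic `DegenerateBaseCurve` (a zero-length cloud cannot be fitted);
`slip_ratio = 1` in the mixed generator does the same, since the scaled
curve collapses onto the pole. Noise is isotropic Gaussian on point
coordinates with a caller-supplied seed (independent draws for head and
base); regeneration with the same seed is bit-identical.

### What they do not emulate

Real CT-derived contact points carry segmentation bias, out-of-plane motion,
non-constant slip, and cartilage deformation — none of which the generators
model (rigid, planar, constant slip, isotropic noise). Passing the oracle
suite therefore shows the *estimator* is correct for its model class, not
that real articular data satisfy that class. The planar-projection helper
(`project_points_to_plane`) is the supported route from 3-D points into the
sagittal plane.

### Accuracy guidance

Two fitting paths feed the construction:

* **Spline path** (`PolarContactCurve.from_points`): cubic-spline
  interpolation of the polar samples (not-a-knot). On noise-free data this
  is exact at nodes and O(h⁴) between them; it is the path used by the
  oracle suite and the one that achieves the 1e-6 mm exact limits (measured
  ~1e-13 on circular families; convergence order ≈ 3 on non-circular
  profiles as density doubles, limited by the spline's derivative error).
* **Polynomial path** (`fit_head_curve` degree 4, `fit_base_curve`
  piecewise cubic with an automatic equal-count two-segment split,
  continuity enforced at value level only): for scattered data. A degree-4
  fit of a shallow circular arc carries ~1e-4 residual, so this path is
  accurate to fractions of the noise level, not to 1e-6 mm. Derivative
  jumps at breakpoints are permitted deliberately — the base data are the
  scattered side — and value continuity is built into the least-squares
  basis rather than penalized.

Pole placement is caller-supplied and recorded in outputs; the default
convention in the CLI is the head pole used by the generators. Angles are
radians and counterclockwise-positive internally, degrees at the CLI and in
configs; lengths are millimetres everywhere, with units embedded in column
names.

## 3. The three-loop ten-linkage finger

The mechanism has nine moving links `l1..l9` (links `l1, l2, l5, l7`
segmented with fixed bend angles; `l6` and `l8` carrying second rigid arms
whose coordinates `φ6′, φ8′` are affine in `φ6, φ8`, here with unit slope
and a fixed offset), a frame bar, and loops of 5/6/5 bars. Eleven Lagrangian
coordinates minus the rank of the dependency system (computed, not assumed)
gives nine independent coordinates; with six scalar closure constraints,
three driving inputs determine a configuration. Driving-coordinate selection
is caller-specified (defaults `φ1, φ5, φ9`); the prototype's actual
actuation is not published.

The hardware dimensions are likewise not published, so the default geometry
is a **synthetic, non-anatomical embedding**: a planar vertex layout chosen
once at design time from which every length, bend angle and initial
coordinate is derived, guaranteeing the initial state closes all loops to
machine precision. Loop membership is config-declared and validated against
the bar counts only. Flexion readouts map mechanism coordinates to joint
angles affinely, with scales fixed at design time so the default sweep spans
the assisted ranges of motion (MCP 0–75°, PIP 0–103°, DIP 0–74°)
monotonically; the joint-limit tables carry those assisted ranges (four
fingers and thumb variants) as inclusive bounds.

Closure is solved by damped Newton iteration (analytic Jacobian with
dependency chain rule, backtracking line search, max 100 iterations,
residual tolerance 1e-9 mm, singularity flagged at condition number 1e12).
Branch selection is nearest-to-guess; sweeps warm-start each step from the
previous solution, and a failed step bisects the driving increment (up to 10
levels) to stay on the same branch. The four-bar subcase is verified against
law-of-cosines closed forms on 100 random geometries.

Crossing-type pairs relocate the MCP or PIP pivot to a supplied equivalent
ICOR (the DIP keeps a conventional revolute pair for space reasons and is
rejected). The lateral swing is a rigid rotation of the solved planar pose
about the vertical axis through the configured flexion-platform origin,
perpendicular to the palm plane; the axis placement is config-overridable.

For alignment studies the physiological reference is a **three-hinge
surrogate finger** (pivots at 0/45/70 mm, tip at 90 mm, flexing
simultaneously through the assisted ranges): the measured physiological
trajectories are not published, and the surrogate makes the RMSE procedure
executable with a known answer (zero RMSE at zero pivot offset, RMSE growing
linearly with offset magnitude). It is a stand-in, and results against it
say nothing about any individual hand.

## 4. Evaluation metrics

* **Cycle averaging**: each cycle linearly resampled to `n` phases uniform
  in [0, 1] (default 101), then averaged pointwise — the 20-cycle averaging
  used to stabilize measured trajectories.
* **Trajectory RMSE**: phase correspondence after common resampling
  (default); nearest-point correspondence is available separately and is
  reported as such (it is not symmetric). Published trajectory comparisons
  rarely state their correspondence rule; phase correspondence is the
  simplest reproducible choice.
* **Pressure summaries**: peak = grid maximum; mean over *active* cells
  (above a 0.1 kPa noise-floor threshold, config-overridable — whether the
  original mean is over all or active cells is unstated, so the convention
  is recorded in the summary metadata); area = active-cell count × cell
  area. Total force (sum × cell area) is invariant under the threshold.
* **Paired t-test**: two-sided on the differences, df = n−1, delegated to
  `scipy.stats.ttest_rel`; zero-variance differences raise a degenerate-test
  error instead of returning an infinite statistic. The test suite checks
  the implementation against a from-scratch formula oracle to 1e-12.

### Misalignment→pressure generator

The generator embodies the alignment hypothesis — misalignment increases
relative sliding and concentrates interface force — as an isotropic Gaussian
blob of fixed total force with spread `σ(m) = σ0 / (1 + g·m)`; peak pressure
rises and active area falls as the misalignment `m` grows, with total force
conserved exactly before noise. Defaults: `σ0 = 4 mm`, 40×40 grid of 1 mm
cells (the patch spans ≥ 5σ so the blob is never clipped at the sensor
edge), total force 2000 kPa·mm². The gain `g = 0.065/mm` was calibrated
once, in closed form, from the untruncated model: peak ∝ (1+g·m)², so a
misalignment drop from 3 mm to 0.5 mm yields a peak reduction
`1 − ((1+0.5g)/(1+3g))²` in the experimentally reported 20–30 % band for
`g ∈ [0.048, 0.081]`; the midpoint was taken. With the default threshold the
active-cell mean reduction lands in the reported 15–25 % band as a
consequence, not by separate tuning. The generator *demonstrates* the
mechanism and exercises the metrics; it does not validate the experimental
percentages, whose raw sensor data are unavailable.

## 5. Reported problem sizes

The shipped tests and the acceptance script use 200-point contact sets, a
101-sample equivalent-ICOR resampling, 20-step closure sweeps, 100 random
four-bar geometries, 1,000 law-of-cosines evaluations and 20 pressure
cycles — sizes at which every quantity is at its numerical floor (1e-9 mm or
better for the exact properties) while the whole suite runs in seconds.

## 6. Known limitations

* Strictly planar: no helical axes, no out-of-plane articular geometry.
* Constant slip ratio; no friction, force or deformation modeling.
* The linkage geometry is synthetic; structural counts and solver behavior
  transfer to real hardware, link-length-specific results do not.
* No mechanism-level pressure prediction: the pressure generator is a
  phenomenological stand-in driven by a scalar misalignment.
* The `paper` direction mode is intentionally preserved as specified even
  where it disagrees with the geometric normal; users comparing modes on
  strongly curved polar profiles should expect large differences.
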