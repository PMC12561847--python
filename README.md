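# handicor

Continuous modeling of finger-joint instantaneous centers of rotation (ICOR)
and kinematic-alignment analysis for hand-exoskeleton design.

Finger joints (MCP, PIP, DIP) do not rotate about fixed axes: the articular
surfaces roll *and* slide on each other, so the instantaneous center of
rotation drifts during flexion. An exoskeleton that assumes a fixed hinge is
therefore misaligned with the limb it drives, which shows up as fingertip
trajectory error and concentrated interface pressure on the skin. `handicor`
is for biomechanics and rehabilitation-robotics engineers who need to go from
planar articular contact points (e.g. extracted from segmented CT slices) to
an engineering pivot location, and to quantify what a given misalignment
costs.

## The model

Given the contact curves traced on the phalangeal head and base, expressed in
polar form `r_h(θ)`, `r_b(θ)` about a common pole with the phalanx axis as the
polar axis (the polar angle identified with the joint rotation angle), the
sliding displacement δ accumulates at the rate

    dδ/dθ = √(r_h² + r_h′²) − √(r_b² + r_b′²)

— the difference of the two curves' arc-length rates. For two rigid bodies in
planar contact the relative ICOR lies on the common normal through the contact
point at exactly this distance, so the **instant radius** is `R*(θ) = dδ/dθ`
and

    ICOR(θ) = contact(θ) + R*(θ) · n̂(θ),

with `n̂` the unit contact normal toward the head curve's center of curvature.
The polar radius of the ICOR obeys the law of cosines
`r_c² = R*² + r_h² − 2 R* r_h cos(θ − α)`, with `α` the outward-normal
direction angle. Two direction conventions are implemented: `geometric` (the
true curve normal; exact, the default) and `paper`
(`α = arctan(−1/r_h′)`, which reads the polar derivative as a Cartesian slope
and is kept selectable so the two can be compared rather than silently
merged).

Because a physical revolute pair needs one axis, the drifting trajectory is
reduced to the **equivalent ICOR** — the fixed center minimizing
`Σ w_i ‖c − p_i‖²` (the weighted centroid) — which is where a crossing-type
biomimetic pair is installed. The package also models the three-loop
ten-linkage exoskeleton finger that carries such pairs: nine moving links
`l1..l9` plus frame, 11 Lagrangian coordinates `φ1..φ9, φ6′, φ8′` with two
affine dependencies (9 independent — underactuated), loops of 5/6/5 bars
solved by damped Newton iteration on the vector-loop equations, a lateral
swing DOF per finger (10 DOF across the hand), fingertip-trajectory RMSE
against a physiological surrogate, and interface-pressure summaries
(peak / active-cell mean / distribution area, percent reductions, paired
t-test).

Everything is validated against synthetic joints with analytically known
ICOR trajectories spanning pure rolling (`slip_ratio = 0`, ICOR at the
contact point) through pure sliding (`slip_ratio = 1`, a fixed hinge), with
an independent velocity-field oracle that locates the zero-velocity point of
the true rigid motion.

## Worked example

```sh
python examples/01_icor_from_contact_points.py
```

```
polar domain: [1.071, 2.071] rad
ICOR radius about the pole: 2.5000..2.5000 mm
max deviation from the velocity-field ground truth: 9.159e-14 mm
```

A joint with a 5 mm circular head and slip ratio 0.5 keeps its ICOR 2.5 mm
inside the contact point (`R* = s·ρ`), so the recovered polar radius is
constant at 2.5 mm and agrees with the independent oracle to machine
precision. Reducing that trajectory to one pivot
(`examples/02_equivalent_center.py`):

```
uniform-theta: center = (-0.0000, +2.3951) mm, rms deviation from the trajectory = 0.7166 mm
arc-length   : center = (-0.0000, +2.3971) mm, rms deviation from the trajectory = 0.1117 mm
```

The equivalent center sits at the centroid of the 1-rad ICOR arc; the rms
deviation is the drift a fixed pivot must absorb. The remaining examples
solve the linkage flexion sweep (loop residuals < 1e-9 mm while spanning
MCP 0–75°, PIP 0–103°, DIP 0–74°), tabulate fingertip RMSE versus pivot
offset (0 mm → 0 RMSE, 5 mm → 7.03 mm RMSE, monotone), and demonstrate the
misalignment→pressure mechanism (24.9 % peak and 21.7 % mean pressure
reduction when misalignment drops from 3 mm to 0.5 mm, paired t-test on
20 cycles).

The same operations are scriptable from the shell via the `handicor` CLI
(`simulate-joint`, `fit-icor`, `equivalent-icor`, `simulate-linkage`,
`evaluate rmse|pressure`); every invocation writes a `manifest.json` with the
tool version, config echo and input checksums.

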