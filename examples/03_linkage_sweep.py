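"""Solve the three-loop ten-linkage finger over a flexion sweep.

Builds the default synthetic finger topology (9 moving links, 11 Lagrangian
coordinates with 2 affine dependencies, loops of 5/6/5 bars), checks the
structural counts, then drives a flexion sweep with loop closure solved at
every step and a 10-degree lateral swing applied.
"""

import numpy as np

from handicor import (
    FOUR_FINGER_LIMITS,
    build_topology,
    check_joint_limits,
    count_lagrangian_coordinates,
    dof_summary,
    fingertip_trajectory,
    independent_coordinate_count,
    loop_closure_residuals,
)

topo = build_topology()
print(f"Lagrangian coordinates: {count_lagrangian_coordinates(topo)} "
      f"({independent_coordinate_count(topo)} independent -> underactuated)")
print(f"loop bar counts: {topo.loop_bar_counts()}")
print(f"hand DOF summary: {dof_summary()['total']} across five fingers")

poses = fingertip_trajectory(topo, n_steps=30, abduction_angle=10.0)
tips = np.array([p.fingertip for p in poses])
worst = max(np.abs(loop_closure_residuals(topo, p.state)).max() for p in poses)
last = poses[-1].flexion_angles
print(f"flexion spans reached: MCP {last['MCP']:.1f} deg, PIP {last['PIP']:.1f} deg, "
      f"DIP {last['DIP']:.1f} deg")
print(f"fingertip excursion: {np.linalg.norm(tips[-1] - tips[0]):.1f} mm, "
      f"out-of-plane z at full flexion: {tips[-1][2]:.1f} mm")
print(f"worst loop-closure residual over the sweep: {worst:.2e} mm")
violations = [v for p in poses for v in check_joint_limits(p, FOUR_FINGER_LIMITS)]
print(f"joint-limit violations along the sweep: {len(violations)}")
# The sweep spans the assisted ranges of motion (about 75/103/74 degrees);
# residuals below 1e-9 mm mean all three loops stay geometrically closed.
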