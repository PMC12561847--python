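"""Topology validation, loop closure, DOF accounting, alignment properties."""

import math

import numpy as np
import pytest

from handicor import (
    FingerPose,
    JointLimits,
    apply_crossing_pair,
    build_topology,
    check_joint_limits,
    count_lagrangian_coordinates,
    default_config,
    dof_summary,
    fingertip_trajectory,
    independent_coordinate_count,
    loop_closure_residuals,
    solve_configuration,
)
from handicor.errors import (
    ConfigError,
    SolverError,
    UnsupportedJointError,
)
from handicor.evaluation import Trajectory, trajectory_rmse
from handicor.linkage import (
    FOUR_FINGER_LIMITS,
    LoopEdge,
    VectorLoopSystem,
    joint_link_vectors,
    surrogate_fingertip_trajectory,
)


class TestStructure:
    def test_canonical_counts(self, topology):
        assert count_lagrangian_coordinates(topology) == 11
        assert independent_coordinate_count(topology) == 9
        assert topology.loop_bar_counts() == {"L1": 5, "L2": 6, "L3": 5}
        assert len(topology.link_lengths) == 9

    def test_single_bare_link(self):
        sys1 = VectorLoopSystem(coordinates=["phi1"], dependencies={}, loops={})
        assert count_lagrangian_coordinates(sys1) == 1
        assert independent_coordinate_count(sys1) == 1

    def test_counts_without_primed_coordinates(self):
        cfg = default_config()
        # strip the primed coordinates and everything referencing them
        cfg["coordinates"] = [c for c in cfg["coordinates"] if not c.endswith("p")]
        cfg["dependencies"] = {}
        sysd = VectorLoopSystem(coordinates=cfg["coordinates"], dependencies={}, loops={})
        assert count_lagrangian_coordinates(sysd) == 9

    def test_three_dependencies_give_eight(self):
        sysd = VectorLoopSystem(
            coordinates=[f"c{i}" for i in range(11)],
            dependencies={
                "c8": ("c0", 1.0, 0.1),
                "c9": ("c1", 2.0, 0.0),
                "c10": ("c2", 1.0, -0.4),
            },
            loops={},
        )
        assert independent_coordinate_count(sysd) == 8

    def test_missing_link_rejected(self):
        cfg = default_config()
        for name in ("l7a", "l7b"):
            del cfg["pieces"][name]
        cfg["loops"]["L2"] = [e for e in cfg["loops"]["L2"] if e[0] != "l7a"]
        cfg["loops"]["L3"] = [e for e in cfg["loops"]["L3"] if e[0] != "l7b"]
        with pytest.raises(ConfigError, match="l7"):
            build_topology(cfg)

    def test_nonpositive_length_rejected(self):
        cfg = default_config()
        cfg["pieces"]["l3"]["length"] = -1.0
        with pytest.raises(ConfigError, match="l3"):
            build_topology(cfg)

    def test_wrong_bar_count_rejected(self):
        cfg = default_config()
        cfg["loops"]["L2"] = [e for e in cfg["loops"]["L2"] if e[0] != "l6a"]
        with pytest.raises(ConfigError):
            build_topology(cfg)

    def test_unclosed_initial_state_rejected(self):
        cfg = default_config()
        cfg["initial_state_deg"]["phi3"] += 10.0
        with pytest.raises(ConfigError, match="unclosed"):
            build_topology(cfg)

    def test_circular_dependency_rejected(self):
        with pytest.raises(ConfigError, match="circular"):
            independent_coordinate_count(
                VectorLoopSystem(
                    coordinates=["a", "b"],
                    dependencies={"a": ("b", 1.0, 0.0), "b": ("a", 1.0, 0.0)},
                    loops={},
                )
            )


class TestLoopResiduals:
    def test_unit_square_closes(self):
        edges = [LoopEdge(1.0, f"t{i}", 0.0, 1) for i in range(4)]
        sysq = VectorLoopSystem(
            coordinates=[f"t{i}" for i in range(4)], dependencies={},
            loops={"L": edges},
        )
        vals = {f"t{i}": math.radians(90.0 * i) for i in range(4)}
        assert np.abs(sysq.residuals(vals)).max() < 1e-12

    def test_first_order_perturbation_bound(self):
        edges = [LoopEdge(10.0, f"t{i}", 0.0, 1) for i in range(4)]
        sysq = VectorLoopSystem(
            coordinates=[f"t{i}" for i in range(4)], dependencies={},
            loops={"L": edges},
        )
        vals = {f"t{i}": math.radians(90.0 * i) for i in range(4)}
        vals["t1"] += 1e-4
        r = np.linalg.norm(sysq.residuals(vals))
        assert r == pytest.approx(10.0 * 1e-4, rel=1e-3)

    def test_zero_lengths_close_trivially(self):
        edges = [LoopEdge(0.0, f"t{i}", 0.0, 1) for i in range(3)]
        sysz = VectorLoopSystem(
            coordinates=[f"t{i}" for i in range(3)], dependencies={}, loops={"L": edges}
        )
        vals = {f"t{i}": 0.3 * i for i in range(3)}
        assert np.abs(sysz.residuals(vals)).max() == 0.0

    def test_canonical_initial_state_closes(self, topology):
        r = loop_closure_residuals(topology, topology.initial_state)
        assert r.shape == (3, 2)
        assert np.abs(r).max() < 1e-9


def fourbar_closed_form(a, b, c, d, th2):
    """Open-branch coupler/rocker angles of a four-bar by the law of cosines."""
    P = a * np.array([math.cos(th2), math.sin(th2)])
    D = np.array([d, 0.0])
    g = np.linalg.norm(D - P)
    cos3 = (g * g + b * b - c * c) / (2 * g * b)
    if abs(cos3) >= 0.999:
        return None
    phi = math.atan2(-P[1], D[0] - P[0])
    th3 = phi - math.acos(cos3)
    C = P + b * np.array([math.cos(th3), math.sin(th3)])
    th4 = math.atan2(C[1] - D[1], C[0] - D[0])
    return th3, th4


def fourbar_system(a, b, c, d):
    return VectorLoopSystem(
        coordinates=["t2", "t3", "t4"],
        dependencies={},
        loops={
            "L": [
                LoopEdge(a, "t2", 0.0, 1),
                LoopEdge(b, "t3", 0.0, 1),
                LoopEdge(c, "t4", 0.0, -1),
                LoopEdge(d, None, 0.0, -1),
            ]
        },
    )


class TestClosureSolver:
    def test_fourbar_matches_law_of_cosines_on_random_geometries(self):
        rng = np.random.default_rng(42)
        checked = 0
        worst = 0.0
        while checked < 100:
            a, b, c, d = rng.uniform(2.0, 10.0, 4)
            th2 = rng.uniform(0.2, 2.9)
            closed = fourbar_closed_form(a, b, c, d, th2)
            if closed is None:
                continue
            th3, th4 = closed
            sol = fourbar_system(a, b, c, d).solve(
                {"t2": th2}, {"t2": th2, "t3": th3 + 0.05, "t4": th4 - 0.05},
                tol=1e-12,
            )
            err = max(
                abs(sol["t3"] - th3),
                abs((sol["t4"] - th4 + math.pi) % (2 * math.pi) - math.pi),
            )
            worst = max(worst, err)
            checked += 1
        assert worst < 1e-9

    def test_fixed_point_of_consistent_state(self, topology):
        state = topology.initial_state
        driving = {d: state[d] for d in topology.config["drivers"]}
        sol = solve_configuration(topology, driving, initial_guess=state)
        for c in topology.system.coordinates:
            assert sol[c] == pytest.approx(state[c], abs=1e-9)

    def test_impossible_closure_raises(self):
        # crank longer than all other bars combined: the loop cannot close
        sysb = fourbar_system(50.0, 2.0, 3.0, 4.0)
        with pytest.raises(SolverError):
            sysb.solve({"t2": 0.7}, {"t2": 0.7, "t3": 0.0, "t4": 1.0})

    def test_wrong_number_of_drivers_rejected(self, topology):
        with pytest.raises(ConfigError, match="driving"):
            solve_configuration(topology, {"phi1": 1.0})

    def test_solved_sweep_keeps_residuals_and_dependencies(self, topology):
        poses = fingertip_trajectory(topology, n_steps=15)
        deps = topology.system.dependencies
        for pose in poses:
            r = loop_closure_residuals(topology, pose.state)
            assert np.abs(r).max() < 1e-9
            for dep, (src, a, b) in deps.items():
                assert pose.state[dep] == pytest.approx(
                    a * pose.state[src] + b, abs=1e-12
                )


class TestCrossingPair:
    def test_identity_relocation_is_noop(self, topology):
        p = topology.joint_centers["PIP"]["point"]
        new = apply_crossing_pair(topology, "PIP", tuple(p))
        assert np.allclose(new.joint_centers["PIP"]["point"], p, atol=1e-12)
        assert new.joint_centers["PIP"]["type"] == "crossing"

    def test_offset_shifts_adjacent_link_vectors(self, topology):
        before = joint_link_vectors(topology, "PIP")
        new = apply_crossing_pair(
            topology, "PIP",
            np.asarray(topology.joint_centers["PIP"]["point"]) + [1.0, 0.0],
        )
        after = joint_link_vectors(new, "PIP")
        assert np.allclose(after["incoming"] - before["incoming"], [1.0, 0.0])
        assert np.allclose(after["outgoing"] - before["outgoing"], [-1.0, 0.0])

    def test_dip_rejected(self, topology):
        with pytest.raises(UnsupportedJointError):
            apply_crossing_pair(topology, "DIP", (0.0, 0.0))

    def test_aligned_pivot_beats_offset_pivot(self):
        frac = np.linspace(0, 1, 60)
        truth = Trajectory(points=surrogate_fingertip_trajectory(frac))
        aligned = Trajectory(
            points=surrogate_fingertip_trajectory(frac, pivot_offsets={"PIP": (0, 0)})
        )
        offset = Trajectory(
            points=surrogate_fingertip_trajectory(frac, pivot_offsets={"PIP": (3.0, 0)})
        )
        assert trajectory_rmse(truth, aligned) < trajectory_rmse(truth, offset)


class TestAlignmentMonotonicity:
    def test_rmse_nondecreasing_in_offset_magnitude(self):
        frac = np.linspace(0, 1, 80)
        truth = Trajectory(points=surrogate_fingertip_trajectory(frac))
        direction = np.array([0.8, 0.6])
        rmses = []
        for mag in np.linspace(0.0, 5.0, 11):
            off = Trajectory(
                points=surrogate_fingertip_trajectory(
                    frac,
                    pivot_offsets={"MCP": mag * direction, "PIP": mag * direction},
                )
            )
            rmses.append(trajectory_rmse(truth, off))
        assert rmses[0] == pytest.approx(0.0, abs=1e-12)
        assert all(b >= a - 1e-12 for a, b in zip(rmses, rmses[1:]))


class TestFingertipTrajectory:
    def test_planar_at_zero_abduction(self, topology):
        poses = fingertip_trajectory(topology, n_steps=8)
        assert all(p.fingertip[2] == 0.0 for p in poses)

    def test_abduction_is_rigid_rotation_about_swing_axis(self, topology):
        p0 = fingertip_trajectory(topology, n_steps=8, abduction_angle=0.0)
        p10 = fingertip_trajectory(topology, n_steps=8, abduction_angle=10.0)
        a = math.radians(10.0)
        sx = topology.config["lateral_axis_point"][0]
        for q0, q10 in zip(p0, p10):
            x, y, _ = q0.fingertip
            expect = np.array(
                [sx + (x - sx) * math.cos(a), y, (x - sx) * math.sin(a)]
            )
            assert np.allclose(q10.fingertip, expect, atol=1e-12)

    def test_trajectory_continuity(self, topology):
        poses = fingertip_trajectory(topology, n_steps=60)
        tips = np.array([p.fingertip for p in poses])
        jumps = np.linalg.norm(np.diff(tips, axis=0), axis=1)
        assert jumps.max() < 5.0  # mm between consecutive steps

    def test_default_sweep_spans_assisted_ranges(self, topology):
        poses = fingertip_trajectory(topology, n_steps=30)
        last = poses[-1].flexion_angles
        assert last["MCP"] == pytest.approx(75.0, abs=2.0)
        assert last["PIP"] == pytest.approx(103.0, abs=2.0)
        assert last["DIP"] == pytest.approx(74.0, abs=2.0)


class TestDOFAndLimits:
    def test_canonical_hand_has_ten_dof(self):
        s = dof_summary()
        assert s["total"] == 10
        assert all(v == 2 for v in s["per_finger"].values())

    def test_flexion_only_hand(self):
        cfg = [{"name": n, "flexion": True, "lateral": False} for n in "abcde"]
        assert dof_summary(cfg)["total"] == 5

    def test_four_finger_dual_dof(self):
        cfg = [{"name": n, "flexion": True, "lateral": True} for n in "abcd"]
        assert dof_summary(cfg)["total"] == 8

    def test_mcp_over_flexion_flagged(self):
        pose = FingerPose(
            flexion_angles={"MCP": 80.0, "PIP": 50.0, "DIP": 30.0},
            abduction_angle=0.0, fingertip=(0, 0, 0),
        )
        v = check_joint_limits(pose, FOUR_FINGER_LIMITS)
        assert len(v) == 1 and v[0]["motion"] == "mcp_flexion"

    def test_inclusive_upper_bound(self):
        pose = FingerPose(
            flexion_angles={"MCP": 10.0, "PIP": 103.0, "DIP": 10.0},
            abduction_angle=0.0, fingertip=(0, 0, 0),
        )
        assert check_joint_limits(pose, FOUR_FINGER_LIMITS) == []

    def test_midpoints_pass(self):
        pose = FingerPose(
            flexion_angles={"MCP": 37.5, "PIP": 51.5, "DIP": 37.0},
            abduction_angle=2.5, fingertip=(0, 0, 0),
        )
        assert check_joint_limits(pose, FOUR_FINGER_LIMITS) == []

    def test_bad_limit_range_rejected(self):
        with pytest.raises(ConfigError):
            JointLimits(ranges={"mcp_flexion": (10.0, 10.0)})
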