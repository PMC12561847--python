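"""Instant-radius modulus/direction, ICOR trajectories, equivalent center."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import polar_pair
from handicor import (
    delta_rate,
    fit_equivalent_icor,
    generate_rolling_sliding,
    icor_cartesian,
    icor_polar,
    icor_trajectory,
    instant_radius_direction,
    instant_radius_modulus,
)
from handicor.contact_curves import PolarContactCurve
from handicor.errors import DomainError, EmptyInputError
from handicor.synthetic_joint import PolarHeadProfile


def constant_slope_curve(r0=5.0, slope=0.0, domain=(0.5, 2.0)):
    return PolarContactCurve.from_callable(
        r=lambda th: r0 + slope * (np.asarray(th) - domain[0]),
        r_prime=lambda th: np.full_like(np.asarray(th, dtype=float), slope),
        r_second=lambda th: np.zeros_like(np.asarray(th, dtype=float)),
        domain=domain,
        pole=(0.0, 0.0),
    )


class TestDeltaRate:
    def test_identical_curves_give_zero(self, rolling_case):
        head, base = polar_pair(rolling_case)
        q = np.linspace(*head.domain, 21)
        assert np.abs(delta_rate(head, base, q)).max() < 1e-9

    def test_degenerate_base_hinge_limit(self, hinge_case):
        head, base = polar_pair(hinge_case)
        th = 0.5 * sum(head.domain)
        assert delta_rate(head, base, th) == pytest.approx(5.0, abs=1e-9)

    def test_mixed_case_half_slip(self, mixed_case):
        head, base = polar_pair(mixed_case)
        q = np.linspace(*head.domain, 21)
        assert np.abs(np.asarray(delta_rate(head, base, q)) - 2.5).max() < 1e-6

    def test_outside_domain_raises(self, hinge_case):
        head, base = polar_pair(hinge_case)
        with pytest.raises(DomainError):
            delta_rate(head, base, head.domain[1] + 1.0)


class TestInstantRadiusModulus:
    @pytest.mark.parametrize("s", [0.0, 0.25, 0.5, 0.75])
    def test_circular_head_gives_slip_times_radius(self, s):
        case = generate_rolling_sliding(5.0, s, 1.0, n_samples=200)
        head, base = polar_pair(case)
        R = instant_radius_modulus(head, base)
        q = np.linspace(*R.domain, 41)
        assert np.abs(np.asarray(R(q)) - s * 5.0).max() < 1e-6

    def test_hinge_radius(self, hinge_case):
        head, base = polar_pair(hinge_case)
        R = instant_radius_modulus(head, base)
        q = np.linspace(*R.domain, 21)
        assert np.abs(np.asarray(R(q)) - 5.0).max() < 1e-6

    def test_disjoint_domains_raise(self):
        a = constant_slope_curve(domain=(0.0, 1.0))
        b = constant_slope_curve(domain=(2.0, 3.0))
        with pytest.raises(DomainError):
            instant_radius_modulus(a, b)


class TestInstantRadiusDirection:
    @pytest.mark.parametrize(
        "slope,expected",
        [(0.0, np.pi / 2), (1.0, -np.pi / 4), (-2.0, np.arctan(0.5))],
    )
    def test_paper_mode_values(self, slope, expected):
        curve = constant_slope_curve(slope=slope)
        alpha = instant_radius_direction(curve, mode="paper")
        th = 1.0
        assert alpha(th) == pytest.approx(expected, abs=1e-12)
        assert -np.pi / 2 < alpha(th) <= np.pi / 2

    def test_geometric_mode_circle_outward_radial(self):
        curve = constant_slope_curve(slope=0.0)
        alpha = instant_radius_direction(curve, mode="geometric")
        q = np.linspace(0.6, 1.9, 17)
        # outward normal of a circle about the pole is the radial direction
        assert np.abs(np.asarray(alpha(q)) - q).max() < 1e-9


class TestICORPolar:
    def test_zero_instant_radius_returns_head_radius(self):
        curve = constant_slope_curve(slope=0.3)
        R = lambda th: np.zeros_like(np.asarray(th, dtype=float))
        alpha = instant_radius_direction(curve, mode="geometric")
        th = 1.2
        assert icor_polar(curve, R, alpha, th) == pytest.approx(
            float(np.asarray(curve.r(th))), abs=1e-12
        )

    def test_full_radius_at_aligned_normal_hits_pole(self):
        curve = constant_slope_curve(slope=0.0)  # circle: alpha == theta
        R = lambda th: np.full_like(np.asarray(th, dtype=float), 5.0)
        alpha = instant_radius_direction(curve, mode="geometric")
        assert icor_polar(curve, R, alpha, 1.0) == pytest.approx(0.0, abs=1e-9)

    def test_hinge_case_all_theta(self, hinge_case):
        head, base = polar_pair(hinge_case)
        R = instant_radius_modulus(head, base)
        alpha = instant_radius_direction(head, mode="geometric")
        q = np.linspace(*R.domain, 51)
        assert np.abs(np.asarray(icor_polar(head, R, alpha, q))).max() < 1e-6


class TestICORCartesian:
    def test_zero_instant_radius_reproduces_contact_curve(self):
        curve = constant_slope_curve(slope=0.2)
        R = lambda th: np.zeros_like(np.asarray(th, dtype=float))
        R.domain = curve.domain
        alpha = instant_radius_direction(curve, mode="geometric")
        traj = icor_cartesian(curve, R, alpha, n_samples=60)
        assert np.abs(traj.xy - curve.point_world(traj.theta)).max() < 1e-9

    def test_hinge_trajectory_at_pivot(self, hinge_case):
        head, base = polar_pair(hinge_case)
        traj = icor_trajectory(head, base, n_samples=120)
        assert np.linalg.norm(traj.xy, axis=1).max() < 1e-6

    @pytest.mark.parametrize("s", [0.25, 0.5, 0.75])
    def test_mixed_case_matches_velocity_field_truth(self, s):
        case = generate_rolling_sliding(5.0, s, 1.0, n_samples=200)
        head, base = polar_pair(case)
        traj = icor_trajectory(head, base, n_samples=200)
        truth = (1 - s) * 5.0 * np.column_stack([np.cos(traj.theta), np.sin(traj.theta)])
        assert np.abs(traj.xy - truth).max() < 0.1  # interpolation tolerance
        assert np.abs(traj.xy - truth).max() < 1e-8  # achieved: exact family

    def test_convergence_with_sample_density(self):
        """Non-circular head: ICOR error shrinks as point density doubles."""
        prof = PolarHeadProfile(
            center=(0.0, 0.0),
            r_func=lambda th: 6.0 + 0.6 * np.sin(2.0 * th),
            r_prime_func=lambda th: 1.2 * np.cos(2.0 * th),
            r_second_func=lambda th: -2.4 * np.sin(2.0 * th),
        )
        errs = []
        for n in (26, 51, 101, 201):
            case = generate_rolling_sliding(prof, 0.4, 1.0, n_samples=n)
            head, base = polar_pair(case)
            traj = icor_trajectory(head, base, n_samples=n)
            # truth at the sampled theta values via the analytic profile
            errs.append(np.abs(traj.xy - truth_icor_at(prof, 0.4, traj.theta)).max())
        assert errs[-1] < errs[0]
        order = np.log2(errs[0] / errs[-1]) / 3.0
        assert order > 1.5  # at least ~quadratic convergence

    def test_paper_mode_direction_disagrees_on_circles(self, mixed_case):
        """The verbatim direction formula is not the geometric normal for a
        circular arc; geometric mode matches the oracle, paper mode does not."""
        head, base = polar_pair(mixed_case)
        geo = icor_trajectory(head, base, mode="geometric", n_samples=100)
        paper = icor_trajectory(head, base, mode="paper", n_samples=100)
        truth = 0.5 * 5.0 * np.column_stack([np.cos(geo.theta), np.sin(geo.theta)])
        assert np.abs(geo.xy - truth).max() < 1e-8
        assert np.abs(paper.xy - truth).max() > 0.5


def truth_icor_at(prof, s, theta):
    r = prof.r(theta)
    rp = prof.r_prime(theta)
    rpp = prof.r_second(theta)
    e = np.column_stack([np.cos(theta), np.sin(theta)])
    Je = np.column_stack([-np.sin(theta), np.cos(theta)])
    tang = rp[:, None] * e + r[:, None] * Je
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    sign = np.sign(r**2 + 2 * rp**2 - r * rpp)
    n_cc = sign[:, None] * np.column_stack([-tang[:, 1], tang[:, 0]])
    return prof.center + r[:, None] * e + (s * np.sqrt(r**2 + rp**2))[:, None] * n_cc


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    a0=st.floats(4.0, 10.0),
    a1=st.floats(-0.8, 0.8),
    b1=st.floats(-0.8, 0.8),
    rstar=st.floats(-3.0, 3.0),
    mode=st.sampled_from(["geometric", "paper"]),
)
def test_law_of_cosines_consistency_random_profiles(a0, a1, b1, rstar, mode):
    """The polar radius of the vector-constructed ICOR equals the
    law-of-cosines expression for arbitrary smooth profiles, in both
    direction modes."""
    curve = PolarContactCurve.from_callable(
        r=lambda th: a0 + a1 * np.sin(np.asarray(th)) + b1 * np.cos(2 * np.asarray(th)),
        r_prime=lambda th: a1 * np.cos(np.asarray(th)) - 2 * b1 * np.sin(2 * np.asarray(th)),
        r_second=lambda th: -a1 * np.sin(np.asarray(th)) - 4 * b1 * np.cos(2 * np.asarray(th)),
        domain=(0.3, 2.1),
        pole=(0.0, 0.0),
    )
    R = lambda th: np.full_like(np.asarray(th, dtype=float), rstar)
    R.domain = curve.domain
    alpha = instant_radius_direction(curve, mode=mode)
    traj = icor_cartesian(curve, R, alpha, n_samples=25)
    law = icor_polar(curve, R, alpha, traj.theta)
    assert np.abs(np.linalg.norm(traj.xy, axis=1) - np.asarray(law)).max() < 1e-6


class TestEquivalentICOR:
    def test_coincident_samples(self):
        pts = np.tile([2.0, -1.0], (7, 1))
        eq = fit_equivalent_icor(pts)
        assert np.allclose(eq.center, [2.0, -1.0])
        assert eq.sum_sq_residual == pytest.approx(0.0, abs=1e-18)

    def test_two_sample_closed_form(self):
        eq = fit_equivalent_icor(np.array([[0.0, 0.0], [2.0, 0.0]]))
        assert np.allclose(eq.center, [1.0, 0.0])
        assert eq.sum_sq_residual == pytest.approx(2.0, abs=1e-12)

    def test_circle_of_samples(self):
        th = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pts = np.array([1.0, 1.0]) + 3.0 * np.column_stack([np.cos(th), np.sin(th)])
        eq = fit_equivalent_icor(pts)
        assert np.abs(eq.center - 1.0).max() < 1e-6
        assert eq.sum_sq_residual == pytest.approx(900.0, rel=1e-9)

    def test_empty_input(self):
        with pytest.raises(EmptyInputError):
            fit_equivalent_icor(np.empty((0, 2)))

    def test_grid_search_never_beats_closed_form(self, mixed_case):
        head, base = polar_pair(mixed_case)
        traj = icor_trajectory(head, base, n_samples=101)
        eq = fit_equivalent_icor(traj)
        pts = traj.xy
        span = 4.0
        gx = np.linspace(eq.center[0] - span, eq.center[0] + span, 200)
        gy = np.linspace(eq.center[1] - span, eq.center[1] + span, 200)
        X, Y = np.meshgrid(gx, gy)
        obj = ((X[..., None] - pts[:, 0]) ** 2 + (Y[..., None] - pts[:, 1]) ** 2).sum(-1)
        assert obj.min() >= eq.sum_sq_residual - 1e-9

    def test_arc_length_weighting_is_trapezoid_centroid(self):
        th = np.linspace(0.2, 1.2, 60)
        pts = np.column_stack([np.cos(th), np.sin(th)])
        a = fit_equivalent_icor(pts, weighting="arc-length")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        w = np.zeros(len(pts))
        w[:-1] += seg / 2
        w[1:] += seg / 2
        expected = (w[:, None] * pts).sum(0) / w.sum()
        assert np.abs(a.center - expected).max() < 1e-12

    def test_hinge_residual_near_zero(self, hinge_case):
        head, base = polar_pair(hinge_case)
        traj = icor_trajectory(head, base, n_samples=101)
        eq = fit_equivalent_icor(traj)
        assert eq.sum_sq_residual < 1e-9
        assert np.linalg.norm(eq.center) < 1e-6

    def test_pure_rolling_equivalent_is_contact_centroid(self, rolling_case):
        head, base = polar_pair(rolling_case)
        traj = icor_trajectory(head, base, n_samples=101)
        eq = fit_equivalent_icor(traj)
        contact = head.point_world(traj.theta)
        assert np.abs(eq.center - contact.mean(axis=0)).max() < 1e-9
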