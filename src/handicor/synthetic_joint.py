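"""Synthetic planar joint-motion generators with known ICOR ground truth.

Real finger joints combine rolling and sliding at the articular contact, so
the instantaneous center of rotation (ICOR) drifts during flexion.  CT-derived
contact points carry no ground truth, which makes validating an ICOR estimator
on them impossible.  The generators here construct planar joint motions whose
ICOR trajectory is known in closed form, spanning the whole rolling-sliding
spectrum through a constant slip ratio ``s``:

* ``s = 0`` -- pure rolling: equal arc lengths consumed on both surfaces; the
  ICOR is the contact point itself.
* ``s = 1`` -- pure sliding: a fixed hinge; the ICOR is the (fixed) center of
  curvature of the head surface.
* ``0 < s < 1`` -- mixed: the base-surface arc rate is ``(1 - s)`` times the
  head-surface arc rate and the ICOR sits at a signed distance
  ``s * (head arc rate)`` from the contact point along the contact normal.

Contact curves are emitted in the joint polar frame: the polar angle about the
head pole is identified with the joint rotation angle, under which the
base-side contact curve of a constant-slip joint is the head curve scaled
radially by ``(1 - s)``.  The physical material trace on the moving bone is
retained separately (``base_trace_body``) for contact-consistency checks.

An independent oracle, :func:`velocity_field_icor`, recovers the ICOR of any
rigid motion by numerically differentiating the pose and locating the
zero-velocity point; generators never use it to produce their ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np
from scipy.integrate import solve_ivp

from handicor._geometry import J, rot, unit
from handicor.contact_curves import ContactPointSet, DegenerateBaseCurve
from handicor.errors import DegenerateMotionError, InvalidParameterError


@dataclass
class RigidMotion1P:
    """One-parameter planar rigid motion of the moving bone.

    ``angle(t)`` (rad) and ``translation(t)`` ((2,) mm) give the pose of the
    phalangeal base relative to the fixed phalangeal head for t in [0, 1],
    with angle(0) = 0 and translation(0) = (0, 0): a body point q maps to
    ``R(angle(t)) @ q + translation(t)``.
    """

    angle: Callable[[float], float]
    translation: Callable[[float], np.ndarray]
    frame_note: str = "moving phalangeal base relative to fixed phalangeal head"

    def pose(self, t: float):
        return rot(self.angle(t)), np.asarray(self.translation(t), dtype=float)

    def transform(self, t: float, points) -> np.ndarray:
        R, d = self.pose(t)
        return np.asarray(points, dtype=float) @ R.T + d


def velocity_field_icor(
    motion: RigidMotion1P, t: float, dt: float = 1e-6
) -> np.ndarray:
    """ICOR of ``motion`` at parameter ``t`` from the numerical velocity field.

    Differentiates the pose with central differences and solves for the point
    whose material velocity vanishes: with pose velocity (omega, ddot),
    ``v(x) = omega * J @ (x - d) + ddot``, so the zero is at
    ``x = d + J @ ddot / omega``.

    Raises
    ------
    DegenerateMotionError
        If |omega| < 1e-9 rad per unit t (ICOR at infinity).
    """
    R1, d1 = motion.pose(t - dt)
    R2, d2 = motion.pose(t + dt)
    R0, d0 = motion.pose(t)
    Rdot = (R2 - R1) / (2 * dt)
    ddot = (d2 - d1) / (2 * dt)
    # Rdot = omega * J @ R  =>  omega = (J^T Rdot R^T) trace/2; entry (1,0) of Rdot R^T
    omega = (Rdot @ R0.T)[1, 0]
    if abs(omega) < 1e-9:
        raise DegenerateMotionError(
            f"|angular velocity| = {abs(omega):.3g} rad per unit t at t={t}; "
            "ICOR is at infinity"
        )
    return d0 + (J @ ddot) / omega


@dataclass
class CircularHeadProfile:
    """Circular phalangeal-head articular surface (radius mm about center)."""

    center: np.ndarray
    radius: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(2)
        if self.radius <= 0:
            raise InvalidParameterError("head profile radius must be > 0")

    @property
    def pole(self) -> np.ndarray:
        return self.center

    def r(self, theta):
        return np.full_like(np.asarray(theta, dtype=float), self.radius)

    def r_prime(self, theta):
        return np.zeros_like(np.asarray(theta, dtype=float))

    def r_second(self, theta):
        return np.zeros_like(np.asarray(theta, dtype=float))

    def point(self, theta):
        return self.center + np.asarray(self.r(theta))[..., None] * unit(theta)


@dataclass
class PolarHeadProfile:
    """General star-shaped head surface r(theta) about ``center``.

    Derivatives default to central finite differences when not supplied.
    """

    center: np.ndarray
    r_func: Callable
    r_prime_func: Callable | None = None
    r_second_func: Callable | None = None

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(2)

    @property
    def pole(self) -> np.ndarray:
        return self.center

    def r(self, theta):
        return np.asarray(self.r_func(np.asarray(theta, dtype=float)), dtype=float)

    def r_prime(self, theta, h: float = 1e-6):
        if self.r_prime_func is not None:
            return np.asarray(self.r_prime_func(np.asarray(theta, dtype=float)))
        t = np.asarray(theta, dtype=float)
        return (self.r(t + h) - self.r(t - h)) / (2 * h)

    def r_second(self, theta, h: float = 1e-4):
        if self.r_second_func is not None:
            return np.asarray(self.r_second_func(np.asarray(theta, dtype=float)))
        t = np.asarray(theta, dtype=float)
        return (self.r(t + h) - 2 * self.r(t) + self.r(t - h)) / h**2

    def point(self, theta):
        return self.center + self.r(theta)[..., None] * unit(theta)


HeadProfile = Union[CircularHeadProfile, PolarHeadProfile]


@dataclass
class SyntheticJointCase:
    """A generated joint motion with analytically known ICOR trajectory."""

    head_profile: HeadProfile
    slip_ratio: float
    head_contact_points: ContactPointSet
    base_contact_points: ContactPointSet | DegenerateBaseCurve
    truth_icor: np.ndarray  # (n, 2) mm
    t: np.ndarray  # (n,) motion parameter in [0, 1]
    motion: RigidMotion1P
    noise_sd: float = 0.0
    contact_points: np.ndarray | None = None  # (n, 2) noise-free world contact
    base_trace_body: np.ndarray | None = None  # (n, 2) material trace, body frame
    theta: np.ndarray | None = None  # (n,) joint polar angle of each sample
    seed: int = 0
    note: str = ""

    @property
    def pole(self) -> np.ndarray:
        return self.head_profile.pole


def _theta_grid(sweep: float, n_samples: int, start: float | None) -> np.ndarray:
    # Center the swept arc about the top of the profile so that y = f(x)
    # stays single-valued and shallow for Cartesian fitting.
    theta0 = (np.pi / 2 - sweep / 2) if start is None else start
    return theta0 + sweep * np.linspace(0.0, 1.0, n_samples)


def generate_fixed_hinge(
    pivot,
    radius: float,
    sweep: float,
    n_samples: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
    joint: str = "PIP",
    start_angle: float | None = None,
) -> SyntheticJointCase:
    """Pure-sliding limit: the moving bone rotates about a fixed pivot.

    The head surface is a circular arc of the given radius about the pivot;
    the base contact trace degenerates to one material point, so the base is
    emitted as an analytic :class:`DegenerateBaseCurve`.  The ICOR is the
    pivot at every instant.
    """
    pivot = np.asarray(pivot, dtype=float).reshape(2)
    if radius <= 0:
        raise InvalidParameterError("radius must be > 0")
    if sweep <= 0:
        raise InvalidParameterError("sweep must be > 0")
    if n_samples < 3:
        raise InvalidParameterError("n_samples must be >= 3")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_samples)
    theta = _theta_grid(sweep, n_samples, start_angle)
    contact = pivot + radius * unit(theta)
    head_pts = contact + rng.normal(0.0, noise_sd, contact.shape) if noise_sd else contact

    def angle(tt):
        return sweep * np.asarray(tt, dtype=float)

    def translation(tt, _pivot=pivot, _sweep=sweep):
        return _pivot - rot(_sweep * float(tt)) @ _pivot

    motion = RigidMotion1P(angle=angle, translation=translation)
    q0 = pivot + radius * unit(theta[0])
    return SyntheticJointCase(
        head_profile=CircularHeadProfile(center=pivot, radius=radius),
        slip_ratio=1.0,
        head_contact_points=ContactPointSet(
            joint=joint, side="head", points=head_pts,
            source=f"fixed hinge pivot={tuple(pivot)} radius={radius} seed={seed}",
        ),
        base_contact_points=DegenerateBaseCurve(
            material_point=q0, joint=joint, source="fixed hinge (pure sliding)"
        ),
        truth_icor=np.tile(pivot, (n_samples, 1)),
        t=t,
        motion=motion,
        noise_sd=noise_sd,
        contact_points=contact,
        base_trace_body=np.tile(q0, (n_samples, 1)),
        theta=theta,
        seed=seed,
        note="pure sliding about a fixed hinge",
    )


def generate_pure_rolling(
    rolling_radius: float,
    base_radius: float,
    sweep: float,
    n_samples: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
    joint: str = "PIP",
    start_angle: float | None = None,
) -> SyntheticJointCase:
    """Rolling without slip: a circle of ``rolling_radius`` rolls on the fixed
    head circle of ``base_radius``.

    Equal arc lengths are consumed on both surfaces at every instant, and the
    ICOR coincides with the instantaneous contact point.  In the joint polar
    frame the base contact curve coincides with the head contact curve (zero
    slip), so the emitted base points equal the head arc samples (with an
    independent noise draw).
    """
    if rolling_radius <= 0 or base_radius <= 0:
        raise InvalidParameterError("radii must be > 0")
    if sweep <= 0:
        raise InvalidParameterError("sweep must be > 0")
    if n_samples < 3:
        raise InvalidParameterError("n_samples must be >= 3")
    rng = np.random.default_rng(seed)
    r, R = rolling_radius, base_radius
    center = np.zeros(2)
    t = np.linspace(0.0, 1.0, n_samples)
    # body rotation Theta = sweep * t; contact polar angle advances at
    # psi = Theta * r / (R + r) (external rolling)
    ratio = r / (R + r)
    psi_span = sweep * ratio
    psi = _theta_grid(psi_span, n_samples, start_angle)
    psi0 = psi[0]
    contact = center + R * unit(psi)
    head_pts = contact + rng.normal(0.0, noise_sd, contact.shape) if noise_sd else contact
    base_noise = rng.normal(0.0, noise_sd, contact.shape) if noise_sd else 0.0
    base_pts = contact + base_noise

    c_b = (R + r) * unit(psi0)  # moving-circle center, body frame (= world at t=0)

    def angle(tt):
        return sweep * np.asarray(tt, dtype=float)

    def translation(tt, _sweep=sweep, _ratio=ratio, _psi0=psi0, _cb=c_b, _Rr=R + r):
        th = _sweep * float(tt)
        c_w = _Rr * unit(_psi0 + _ratio * th)
        return c_w - rot(th) @ _cb

    motion = RigidMotion1P(angle=angle, translation=translation)
    trace = np.array(
        [rot(-(sweep * ti)) @ (contact[i] - motion.pose(ti)[1]) for i, ti in enumerate(t)]
    )
    return SyntheticJointCase(
        head_profile=CircularHeadProfile(center=center, radius=R),
        slip_ratio=0.0,
        head_contact_points=ContactPointSet(
            joint=joint, side="head", points=head_pts,
            source=f"pure rolling r={r} R={R} seed={seed}",
        ),
        base_contact_points=ContactPointSet(
            joint=joint, side="base", points=base_pts,
            source=f"pure rolling r={r} R={R} seed={seed} (joint polar frame)",
        ),
        truth_icor=contact.copy(),
        t=t,
        motion=motion,
        noise_sd=noise_sd,
        contact_points=contact,
        base_trace_body=trace,
        theta=psi,
        seed=seed,
        note="rolling without slip (ICOR = contact point)",
    )


def _polar_curvature_sign(r, rp, rpp) -> float:
    # Signed curvature of a polar curve w.r.t. the left normal of increasing theta:
    # kappa = (r^2 + 2 r'^2 - r r'') / (r^2 + r'^2)^(3/2)
    return float(np.sign(r * r + 2.0 * rp * rp - r * rpp) or 1.0)


def generate_rolling_sliding(
    head_profile: HeadProfile | float,
    slip_ratio: float,
    sweep: float,
    n_samples: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
    joint: str = "PIP",
    start_angle: float | None = None,
) -> SyntheticJointCase:
    """Mixed rolling-sliding joint with a constant slip ratio.

    The contact point advances along the head surface with the joint polar
    angle identified with the body rotation angle; the material slip velocity
    at the contact is tangential with magnitude ``slip_ratio`` times the head
    contact speed.  Consequences, all exact for this family:

    * base-surface arc rate = (1 - slip_ratio) x head-surface arc rate;
    * the ICOR sits at distance ``slip_ratio * sqrt(r_h^2 + r_h'^2)`` from the
      contact point along the normal toward the head curve's center of
      curvature;
    * the base contact curve in the joint polar frame is the head curve scaled
      radially by (1 - slip_ratio) about the pole.

    ``head_profile`` may be a bare radius (shorthand for a circle about the
    origin).  ``slip_ratio = 1`` degenerates to a hinge and emits an analytic
    degenerate base curve.
    """
    if isinstance(head_profile, (int, float)):
        head_profile = CircularHeadProfile(center=np.zeros(2), radius=float(head_profile))
    if not 0.0 <= slip_ratio <= 1.0:
        raise InvalidParameterError(f"slip_ratio {slip_ratio} outside [0, 1]")
    if sweep <= 0:
        raise InvalidParameterError("sweep must be > 0")
    if n_samples < 3:
        raise InvalidParameterError("n_samples must be >= 3")
    rng = np.random.default_rng(seed)
    s = float(slip_ratio)
    pole = head_profile.pole
    t = np.linspace(0.0, 1.0, n_samples)
    theta = _theta_grid(sweep, n_samples, start_angle)
    r = np.asarray(head_profile.r(theta), dtype=float)
    rp = np.asarray(head_profile.r_prime(theta), dtype=float)
    rpp = np.asarray(head_profile.r_second(theta), dtype=float)
    contact = pole + r[..., None] * unit(theta)

    # unit tangent and normal-toward-curvature-center in the (world==polar) frame
    tang = rp[..., None] * unit(theta) + r[..., None] * (unit(theta) @ J.T)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    left_normal = tang @ J.T
    sign = np.array([_polar_curvature_sign(r[i], rp[i], rpp[i]) for i in range(n_samples)])
    n_cc = sign[..., None] * left_normal
    arc_rate = np.sqrt(r * r + rp * rp)
    truth = contact + (s * arc_rate)[..., None] * n_cc

    def icor_of(tt):
        th = theta[0] + sweep * float(tt)
        rv = float(np.asarray(head_profile.r(th)))
        rpv = float(np.asarray(head_profile.r_prime(th)))
        rppv = float(np.asarray(head_profile.r_second(th)))
        p = pole + rv * unit(th)
        tg = rpv * unit(th) + rv * (J @ unit(th))
        tg = tg / np.linalg.norm(tg)
        nc = _polar_curvature_sign(rv, rpv, rppv) * (J @ tg)
        return p + s * np.sqrt(rv * rv + rpv * rpv) * nc

    # Pose translation d(t): the body origin's material point obeys
    # d' = omega * J @ (d - icor(t)) with omega = sweep rad per unit t.
    sol = solve_ivp(
        lambda tt, d: sweep * (J @ (d - icor_of(tt))),
        (0.0, 1.0),
        np.zeros(2),
        dense_output=True,
        rtol=1e-12,
        atol=1e-13,
        method="DOP853",
    )

    def angle(tt):
        return sweep * np.asarray(tt, dtype=float)

    def translation(tt, _sol=sol):
        return _sol.sol(float(tt))

    motion = RigidMotion1P(angle=angle, translation=translation)
    head_pts = contact + rng.normal(0.0, noise_sd, contact.shape) if noise_sd else contact

    if s == 1.0:
        base: ContactPointSet | DegenerateBaseCurve = DegenerateBaseCurve(
            material_point=contact[0], joint=joint,
            source=f"rolling-sliding slip_ratio=1 seed={seed}",
        )
    else:
        base_clean = pole + (1.0 - s) * (contact - pole)
        base_noise = rng.normal(0.0, noise_sd, contact.shape) if noise_sd else 0.0
        base = ContactPointSet(
            joint=joint, side="base", points=base_clean + base_noise,
            source=f"rolling-sliding slip_ratio={s} seed={seed} (joint polar frame)",
        )

    trace = np.array(
        [rot(-(sweep * ti)) @ (contact[i] - sol.sol(ti)) for i, ti in enumerate(t)]
    )
    return SyntheticJointCase(
        head_profile=head_profile,
        slip_ratio=s,
        head_contact_points=ContactPointSet(
            joint=joint, side="head", points=head_pts,
            source=f"rolling-sliding slip_ratio={s} seed={seed}",
        ),
        base_contact_points=base,
        truth_icor=truth,
        t=t,
        motion=motion,
        noise_sd=noise_sd,
        contact_points=contact,
        base_trace_body=trace,
        theta=theta,
        seed=seed,
        note=f"hybrid rolling-sliding, slip ratio {s}",
    )


def project_points_to_plane(points, origin, normal, x_axis=None) -> np.ndarray:
    """Project 3-D points onto a plane and return 2-D in-plane coordinates.

    The instant-radius construction is planar (sagittal); CT-derived 3-D
    contact points must be projected onto the flexion plane first.  ``normal``
    defines the plane through ``origin``; ``x_axis`` (optional) fixes the
    in-plane abscissa direction, defaulting to the projection of the global
    x axis (or y axis if degenerate).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidParameterError("expected an (n, 3) array of 3-D points")
    origin = np.asarray(origin, dtype=float).reshape(3)
    n = np.asarray(normal, dtype=float).reshape(3)
    nn = np.linalg.norm(n)
    if nn == 0:
        raise InvalidParameterError("plane normal must be nonzero")
    n = n / nn
    if x_axis is None:
        cand = np.array([1.0, 0.0, 0.0])
        if abs(cand @ n) > 0.9:
            cand = np.array([0.0, 1.0, 0.0])
        x_axis = cand
    u = np.asarray(x_axis, dtype=float).reshape(3)
    u = u - (u @ n) * n
    un = np.linalg.norm(u)
    if un < 1e-12:
        raise InvalidParameterError("x_axis is parallel to the plane normal")
    u /= un
    v = np.cross(n, u)
    rel = pts - origin
    return np.column_stack([rel @ u, rel @ v])
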