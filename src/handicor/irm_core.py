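"""Instant-radius construction of continuous ICOR trajectories.

For two rigid articular surfaces in planar contact, the instantaneous center
of rotation (ICOR) of the relative motion lies on the common normal through
the contact point, at a distance equal to the sliding displacement consumed
per unit of joint rotation.  With the head and base contact curves expressed
in polar form about a common pole (the polar angle identified with the joint
rotation angle), that distance has the closed form

    R*(theta) = sqrt(r_h^2 + r_h'^2) - sqrt(r_b^2 + r_b'^2),

the difference of the two curves' arc-length rates.  The ICOR is then

    ICOR(theta) = contact(theta) + R* x (unit normal toward the head curve's
                  center of curvature),

and its polar radius obeys the law of cosines

    r_c(theta) = sqrt(R*^2 + r_h^2 - 2 R* r_h cos(theta - alpha)),

with alpha the direction angle of the outward contact normal.  Two direction
conventions are provided: ``"geometric"`` (the true normal of the fitted
curve; exact, the default) and ``"paper"``
(alpha = arctan(-1 / r_h'(theta)), which treats the polar derivative as a
Cartesian slope and is exact only where the polar angle increment dominates
the radius change).  Both are exposed so their disagreement can be measured
rather than silently corrected.

Finally, :func:`fit_equivalent_icor` reduces a drifting ICOR trajectory to the
single fixed center minimizing the sum of squared deviations -- the pivot at
which a crossing-type revolute pair is physically installed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from handicor._geometry import J, rot, unit, wrap_pi
from handicor.contact_curves import DegenerateBaseCurve, PolarContactCurve
from handicor.errors import (
    DomainError,
    EmptyInputError,
    InvalidParameterError,
    NumericalInconsistencyError,
)

DIRECTION_MODES = ("geometric", "paper")
SIGN_CONVENTIONS = ("curvature_center", "outward")


@dataclass
class InstantRadiusProfile:
    """Signed instant-radius modulus R*(theta) and normal direction alpha(theta)."""

    R_star: Callable
    alpha: Callable
    domain: tuple
    mode: str = "geometric"


@dataclass
class ICORTrajectory:
    """Sampled ICOR trajectory in polar and Cartesian form.

    ``theta``/``r_c`` give the polar representation about ``pole`` (angles
    from ``axis_angle``); ``xy`` are world coordinates.  Samples are ordered
    by theta.
    """

    theta: np.ndarray
    r_c: np.ndarray
    xy: np.ndarray
    pole: np.ndarray
    axis_angle: float = 0.0

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.r_c = np.asarray(self.r_c, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        self.pole = np.asarray(self.pole, dtype=float).reshape(2)
        if np.any(np.diff(self.theta) < 0):
            raise InvalidParameterError("trajectory samples must be ordered by theta")
        if np.any(self.r_c < 0):
            raise InvalidParameterError("polar ICOR radius must be >= 0")

    def __len__(self) -> int:
        return len(self.theta)


@dataclass
class EquivalentICOR:
    """Fixed center minimizing the weighted sum of squared deviations."""

    center: np.ndarray
    sum_sq_residual: float
    n_samples: int
    weighting: str = "uniform-theta"

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(2)


def _base_arc_rate(base, theta):
    if base is None or isinstance(base, DegenerateBaseCurve):
        return np.zeros_like(np.asarray(theta, dtype=float))
    base.check_theta(theta)
    return base.arc_rate(theta)


def delta_rate(
    head: PolarContactCurve,
    base: PolarContactCurve | DegenerateBaseCurve | None,
    theta,
):
    """Sliding-displacement rate d(delta)/d(theta) at ``theta`` (mm/rad).

    The difference of polar arc-length rates of the head and base contact
    curves; a degenerate base (pure sliding) contributes zero.
    """
    head.check_theta(theta)
    out = head.arc_rate(theta) - _base_arc_rate(base, theta)
    return float(out) if np.ndim(out) == 0 else out


def shared_domain(
    head: PolarContactCurve,
    base: PolarContactCurve | DegenerateBaseCurve | None,
) -> tuple:
    """Intersection of the head and base polar domains."""
    lo, hi = head.domain
    if isinstance(base, PolarContactCurve):
        lo = max(lo, base.domain[0])
        hi = min(hi, base.domain[1])
    if not hi > lo:
        raise DomainError("head and base polar domains do not overlap")
    return (lo, hi)


def instant_radius_modulus(
    head: PolarContactCurve,
    base: PolarContactCurve | DegenerateBaseCurve | None,
) -> Callable:
    """Signed instant-radius modulus R*(theta) on the shared polar domain.

    Returns a vectorized callable carrying a ``domain`` attribute.  R* is the
    closed form of the sliding rate d(delta)/d(theta): the distance from the
    contact point to the ICOR.
    """
    dom = shared_domain(head, base)

    def R_star(theta):
        return delta_rate(head, base, theta)

    R_star.domain = dom
    return R_star


def instant_radius_direction(head: PolarContactCurve, mode: str = "geometric") -> Callable:
    """Direction angle alpha(theta) of the contact normal, in the polar frame.

    mode="geometric"
        True outward normal of the curve (away from the local center of
        curvature), measured from the polar axis.  Exact for any curve.
    mode="paper"
        alpha = arctan(-1 / r_h'(theta)), the negative reciprocal of the
        polar derivative, reduced to (-pi/2, pi/2]; r_h' = 0 maps to pi/2.
        This reads the polar derivative as a Cartesian slope.

    Returns a vectorized callable with a ``mode`` attribute.
    """
    if mode not in DIRECTION_MODES:
        raise InvalidParameterError(f"unknown direction mode {mode!r}")

    if mode == "paper":

        def alpha(theta):
            head.check_theta(theta)
            rp = np.asarray(head.r_prime(theta), dtype=float)
            with np.errstate(divide="ignore"):
                a = np.where(rp == 0.0, np.pi / 2, np.arctan(-1.0 / np.where(rp == 0, 1.0, rp)))
            # reduce to (-pi/2, pi/2]
            a = np.where(a <= -np.pi / 2, a + np.pi, a)
            return float(a) if a.ndim == 0 else a

    else:

        def alpha(theta):
            head.check_theta(theta)
            th = np.atleast_1d(np.asarray(theta, dtype=float))
            r = np.asarray(head.r(th), dtype=float)
            rp = np.asarray(head.r_prime(th), dtype=float)
            rpp = (
                np.asarray(head.r_second(th), dtype=float)
                if head.r_second is not None
                else np.zeros_like(th)
            )
            tang = rp[..., None] * unit(th) + r[..., None] * (unit(th) @ J.T)
            tang /= np.linalg.norm(tang, axis=-1, keepdims=True)
            kappa_sign = np.sign(r * r + 2 * rp * rp - r * rpp)
            kappa_sign = np.where(kappa_sign == 0, 1.0, kappa_sign)
            outward = -kappa_sign[..., None] * (tang @ J.T)
            a = np.arctan2(outward[..., 1], outward[..., 0])
            return float(a[0]) if np.ndim(theta) == 0 else a

    alpha.mode = mode
    return alpha


def icor_polar(
    head: PolarContactCurve,
    R_star: Callable,
    alpha: Callable,
    theta,
    sign_convention: str = "curvature_center",
):
    """Polar ICOR radius r_c(theta) by the law of cosines.

    With the default sign convention (ICOR displaced from the contact point
    by R* toward the center of curvature, i.e. opposite the outward normal
    angle alpha):

        r_c = sqrt(R*^2 + r_h^2 - 2 R* r_h cos(theta - alpha))

    A radicand within -1e-9 of zero is clamped to zero; anything more
    negative raises :class:`NumericalInconsistencyError`.
    """
    if sign_convention not in SIGN_CONVENTIONS:
        raise InvalidParameterError(f"unknown sign convention {sign_convention!r}")
    head.check_theta(theta)
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    rs = np.asarray(R_star(th), dtype=float)
    rh = np.asarray(head.r(th), dtype=float)
    al = np.asarray(alpha(th), dtype=float)
    sgn = -1.0 if sign_convention == "curvature_center" else 1.0
    radicand = rs * rs + rh * rh + 2.0 * sgn * rs * rh * np.cos(wrap_pi(th - al))
    if np.any(radicand < -1e-9):
        bad = th[np.argmin(radicand)]
        raise NumericalInconsistencyError(
            f"negative law-of-cosines radicand {radicand.min():.3g} at theta={bad:.6g}"
        )
    r_c = np.sqrt(np.clip(radicand, 0.0, None))
    return float(r_c[0]) if np.ndim(theta) == 0 else r_c


def icor_cartesian(
    head: PolarContactCurve,
    R_star: Callable,
    alpha: Callable,
    sign_convention: str = "curvature_center",
    n_samples: int = 200,
    domain: tuple | None = None,
) -> ICORTrajectory:
    """Cartesian ICOR trajectory from the instant-radius profile.

    For each sampled theta the ICOR is the contact point displaced by the
    signed instant radius along the contact normal; the polar radius of every
    constructed point is cross-checked against the law-of-cosines form within
    1e-6 mm.

    Raises
    ------
    NumericalInconsistencyError
        Naming the offending theta if the cross-check fails.
    """
    if sign_convention not in SIGN_CONVENTIONS:
        raise InvalidParameterError(f"unknown sign convention {sign_convention!r}")
    dom = domain if domain is not None else getattr(R_star, "domain", head.domain)
    th = np.linspace(dom[0], dom[1], n_samples)
    rh = np.asarray(head.r(th), dtype=float)
    rs = np.asarray(R_star(th), dtype=float)
    al = np.asarray(alpha(th), dtype=float)
    sgn = -1.0 if sign_convention == "curvature_center" else 1.0
    icor_pf = rh[..., None] * unit(th) + sgn * rs[..., None] * unit(al)
    r_c_vec = np.linalg.norm(icor_pf, axis=-1)
    r_c_law = np.atleast_1d(icor_polar(head, R_star, alpha, th, sign_convention))
    dev = np.abs(r_c_vec - r_c_law)
    if np.any(dev > 1e-6):
        bad = th[int(np.argmax(dev))]
        raise NumericalInconsistencyError(
            f"law-of-cosines consistency failure ({dev.max():.3g} mm) at theta={bad:.6g}"
        )
    xy = head.pole + icor_pf @ rot(head.axis_angle).T
    return ICORTrajectory(
        theta=th, r_c=r_c_vec, xy=xy, pole=head.pole, axis_angle=head.axis_angle
    )


def icor_trajectory(
    head: PolarContactCurve,
    base: PolarContactCurve | DegenerateBaseCurve | None,
    mode: str = "geometric",
    sign_convention: str = "curvature_center",
    n_samples: int = 200,
) -> ICORTrajectory:
    """One-shot pipeline: instant-radius profile -> Cartesian ICOR trajectory."""
    R_star = instant_radius_modulus(head, base)
    alpha = instant_radius_direction(head, mode=mode)
    return icor_cartesian(
        head, R_star, alpha, sign_convention=sign_convention, n_samples=n_samples
    )


def fit_equivalent_icor(traj, weighting: str = "uniform-theta") -> EquivalentICOR:
    """Least-squares reduction of an ICOR trajectory to one fixed center.

    Minimizes ``sum_i w_i ||c - p_i||^2``; the unique minimizer is the
    weighted centroid.  ``weighting="uniform-theta"`` uses unit weights over
    the trajectory samples (assumed resampled uniformly in theta);
    ``"arc-length"`` weights each sample by its share of the trajectory's arc
    length, de-emphasizing regions where the ICOR lingers in theta.

    The reported ``sum_sq_residual`` (mm^2) is the objective at the optimum
    with the raw (unnormalized) weights.
    """
    pts = traj.xy if isinstance(traj, ICORTrajectory) else np.asarray(traj, dtype=float)
    pts = np.atleast_2d(pts)
    if pts.size == 0:
        raise EmptyInputError("cannot fit an equivalent ICOR to an empty trajectory")
    if weighting == "uniform-theta":
        w = np.ones(len(pts))
    elif weighting == "arc-length":
        if len(pts) == 1:
            w = np.ones(1)
        else:
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            w = np.zeros(len(pts))
            w[:-1] += seg / 2
            w[1:] += seg / 2
            if w.sum() == 0:  # coincident points: fall back to uniform
                w = np.ones(len(pts))
    else:
        raise InvalidParameterError(f"unknown weighting {weighting!r}")
    center = (w[:, None] * pts).sum(axis=0) / w.sum()
    resid = float(np.sum(w * np.sum((pts - center) ** 2, axis=1)))
    return EquivalentICOR(
        center=center, sum_sq_residual=resid, n_samples=len(pts), weighting=weighting
    )
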