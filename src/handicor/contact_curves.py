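"""Fitting articular contact curves and transforming them to polar form.

The instant-radius construction consumes two planar contact curves per joint --
one traced on the phalangeal head (the fixed bone of the pair), one on the
phalangeal base (the moving bone) -- expressed in polar coordinates about a
common pole with the phalanx axis as the polar axis.  This module provides:

* :class:`ContactPointSet` -- labeled, ordered 2-D contact samples;
* :func:`fit_head_curve` -- single least-squares polynomial (head points are
  regular and shallow);
* :func:`fit_base_curve` -- value-continuous piecewise polynomial (base points
  are scattered and need piecewise treatment);
* :func:`to_polar` / :meth:`PolarContactCurve.from_points` -- polar transform
  about a caller-supplied pole and axis.

Conventions: millimetres, radians, counterclockwise positive; the polar angle
is measured from ``axis_angle`` (the phalanx axis direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from handicor._geometry import rot, unit
from handicor.errors import (
    AmbiguousMappingError,
    DomainError,
    FitError,
    InvalidParameterError,
)

JOINTS = ("MCP", "PIP", "DIP")
SIDES = ("head", "base")


@dataclass
class ContactPointSet:
    """Ordered 2-D articular contact samples for one joint and bone side.

    Parameters
    ----------
    joint : {"MCP", "PIP", "DIP"}
    side : {"head", "base"}
    points : (n, 2) array_like, millimetres
        Ordered monotonically along the articular surface.
    source : str
        Free-text provenance (e.g. generator parameters, input file).
    """

    joint: str
    side: str
    points: np.ndarray
    source: str = ""

    def __post_init__(self):
        if self.joint not in JOINTS:
            raise InvalidParameterError(f"unknown joint label {self.joint!r}")
        if self.side not in SIDES:
            raise InvalidParameterError(f"unknown side label {self.side!r}")
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidParameterError("points must be an (n, 2) array")
        if not np.all(np.isfinite(pts)):
            raise InvalidParameterError("contact points must be finite")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class DegenerateBaseCurve:
    """Pure-sliding base 'curve': a single material contact point.

    When the joint slides without rolling (a hinge), the contact trace on the
    moving bone has zero arc length; fitting it is ill-posed, so generators
    emit this analytic stand-in instead of a point cloud.  Its arc-length rate
    is identically zero, which is exactly how the instant-radius formulas use
    it.
    """

    material_point: np.ndarray
    joint: str = "PIP"
    source: str = ""

    def __post_init__(self):
        self.material_point = np.asarray(self.material_point, dtype=float).reshape(2)


@dataclass
class CartesianContactCurve:
    """Piecewise-polynomial contact curve y = p(x).

    ``pieces`` is a list of ``(coefficients, (x_lo, x_hi))`` with coefficients
    in ascending powers of x (plain basis).  Head curves have exactly one
    piece; base curves may have several, continuous in value at breakpoints.
    """

    pieces: list
    side: str
    fit_residual_rms: float = 0.0

    def __post_init__(self):
        if self.side not in SIDES:
            raise InvalidParameterError(f"unknown side label {self.side!r}")
        if not self.pieces:
            raise FitError("curve has no pieces")
        if self.side == "head" and len(self.pieces) != 1:
            raise FitError("head curves must have exactly one piece")
        lo = [p[1][0] for p in self.pieces]
        hi = [p[1][1] for p in self.pieces]
        for a, b in zip(hi[:-1], lo[1:]):
            if abs(a - b) > 1e-9:
                raise FitError("pieces do not cover a contiguous domain")

    @property
    def domain(self) -> tuple:
        return (self.pieces[0][1][0], self.pieces[-1][1][1])

    def _piece_index(self, x: float) -> int:
        lo, hi = self.domain
        if x < lo - 1e-9 or x > hi + 1e-9:
            raise DomainError(f"x={x} outside curve domain [{lo}, {hi}]")
        for i, (_, (a, b)) in enumerate(self.pieces):
            if x <= b or i == len(self.pieces) - 1:
                return i
        return len(self.pieces) - 1

    def __call__(self, x):
        xs = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.empty_like(xs)
        for k, xv in enumerate(xs):
            coef, _ = self.pieces[self._piece_index(xv)]
            out[k] = np.polynomial.polynomial.polyval(xv, coef)
        return float(out[0]) if np.isscalar(x) or np.ndim(x) == 0 else out

    def derivative(self, x):
        xs = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.empty_like(xs)
        for k, xv in enumerate(xs):
            coef, _ = self.pieces[self._piece_index(xv)]
            dcoef = np.polynomial.polynomial.polyder(coef)
            out[k] = np.polynomial.polynomial.polyval(xv, dcoef)
        return float(out[0]) if np.isscalar(x) or np.ndim(x) == 0 else out

    def sample(self, n: int) -> np.ndarray:
        """(n, 2) points sampled uniformly in x over the domain."""
        lo, hi = self.domain
        xs = np.linspace(lo, hi, n)
        return np.column_stack([xs, self(xs)])


def _check_abscissae(x: np.ndarray, degree: int) -> None:
    uniq, counts = np.unique(x, return_counts=True)
    if len(uniq) <= degree:
        dup = uniq[np.argmax(counts)] if np.any(counts > 1) else uniq[0]
        raise FitError(
            f"rank-deficient design: only {len(uniq)} distinct abscissae for "
            f"degree {degree}; offending abscissa x={dup}"
        )


def fit_head_curve(points: ContactPointSet, degree: int = 4) -> CartesianContactCurve:
    """Least-squares polynomial fit of head-side contact points.

    Head contact points are regular enough for a single continuous function;
    degree 4 captures a shallow articular arc without oscillation.

    Raises
    ------
    FitError
        If the fit is underdetermined (``degree >= n_points``) or the design
        is rank deficient (too few distinct abscissae).
    """
    if points.side != "head":
        raise InvalidParameterError("fit_head_curve expects side='head'")
    pts = points.points
    if degree < 0:
        raise InvalidParameterError("degree must be >= 0")
    if degree >= len(pts):
        raise FitError(
            f"underdetermined fit: degree {degree} with only {len(pts)} points"
        )
    x, y = pts[:, 0], pts[:, 1]
    _check_abscissae(x, degree)
    series = np.polynomial.Polynomial.fit(x, y, degree)
    coef = series.convert().coef
    resid = np.polynomial.polynomial.polyval(x, coef) - y
    rms = float(np.sqrt(np.mean(resid**2)))
    return CartesianContactCurve(
        pieces=[(coef, (float(x.min()), float(x.max())))],
        side="head",
        fit_residual_rms=rms,
    )


def fit_base_curve(
    points: ContactPointSet,
    breakpoints: Sequence[float] | None = None,
    degree: int = 3,
) -> CartesianContactCurve:
    """Value-continuous piecewise polynomial fit of base-side contact points.

    Base-side contact points scatter more than head-side ones, so they are
    approximated piecewise.  Continuity is enforced at value level only: the
    instant-radius formulas need r and r', and derivative jumps at breakpoints
    reflect genuine scatter rather than fit artifacts.

    Parameters
    ----------
    breakpoints
        Interior x-breakpoints.  ``None`` selects the automatic convention:
        a single breakpoint splitting the points into two equal-count runs.
    degree
        Polynomial degree per piece (default cubic).
    """
    if points.side != "base":
        raise InvalidParameterError("fit_base_curve expects side='base'")
    pts = points.points[np.argsort(points.points[:, 0], kind="stable")]
    x, y = pts[:, 0], pts[:, 1]
    if breakpoints is None:
        breakpoints = [float(x[len(x) // 2])]
    edges = [float(x.min()), *sorted(float(b) for b in breakpoints), float(x.max())]
    n_pieces = len(edges) - 1
    masks = []
    for j in range(n_pieces):
        lo, hi = edges[j], edges[j + 1]
        m = (x >= lo) & (x <= hi) if j == n_pieces - 1 else (x >= lo) & (x < hi)
        if not np.any(m):
            raise FitError(f"empty segment [{lo}, {hi}] in piecewise fit")
        if np.count_nonzero(m) <= degree:
            raise FitError(
                f"segment [{lo}, {hi}] has {np.count_nonzero(m)} points; "
                f"needs more than degree={degree}"
            )
        masks.append(m)

    # Unknowns: shared left-edge value v0, then per piece the shifted-basis
    # coefficients a_{j,1..d}.  Chaining the piece values through the
    # breakpoints makes continuity structural rather than penalized.
    n_unknown = 1 + n_pieces * degree
    A = np.zeros((len(x), n_unknown))
    A[:, 0] = 1.0
    spans = np.diff(edges)
    for j, m in enumerate(masks):
        for i in range(j):
            col = 1 + i * degree
            for k in range(1, degree + 1):
                A[m, col + k - 1] += spans[i] ** k
        col = 1 + j * degree
        dx = x[m] - edges[j]
        for k in range(1, degree + 1):
            A[m, col + k - 1] = dx**k
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = A @ sol - y
    rms = float(np.sqrt(np.mean(resid**2)))

    pieces = []
    v = sol[0]
    for j in range(n_pieces):
        a = sol[1 + j * degree : 1 + (j + 1) * degree]
        shifted = np.concatenate([[v], a])  # powers of (x - edges[j])
        # expand to plain powers of x
        plain = np.zeros(degree + 1)
        t = edges[j]
        for k, c in enumerate(shifted):
            binom = np.polynomial.polynomial.polypow([-t, 1.0], k) if k else [1.0]
            plain[: len(binom)] += c * np.asarray(binom)
        pieces.append((plain, (edges[j], edges[j + 1])))
        v = float(np.polynomial.polynomial.polyval(edges[j + 1], plain))
    return CartesianContactCurve(pieces=pieces, side="base", fit_residual_rms=rms)


@dataclass
class PolarContactCurve:
    """Contact curve in polar form r(theta) about ``pole``.

    ``theta`` is measured counterclockwise from ``axis_angle`` (the phalanx
    axis).  ``r`` and ``r_prime`` are callables accepting scalars or arrays;
    ``r_second`` supports curvature-based normal directions.
    """

    r: Callable
    r_prime: Callable
    domain: tuple
    pole: np.ndarray
    axis_angle: float = 0.0
    r_second: Callable | None = None
    side: str = "head"
    _source: str = field(default="", repr=False)

    def __post_init__(self):
        self.pole = np.asarray(self.pole, dtype=float).reshape(2)
        lo, hi = self.domain
        if not hi > lo:
            raise InvalidParameterError("polar domain width must be > 0")
        self.domain = (float(lo), float(hi))
        probe = np.linspace(lo, hi, 33)
        if np.any(np.asarray(self.r(probe)) <= 0):
            raise InvalidParameterError("r(theta) must be positive on the domain")

    def check_theta(self, theta) -> None:
        t = np.atleast_1d(np.asarray(theta, dtype=float))
        lo, hi = self.domain
        if np.any(t < lo - 1e-9) or np.any(t > hi + 1e-9):
            raise DomainError(
                f"theta outside polar domain [{lo:.6g}, {hi:.6g}]"
            )

    def point_polar(self, theta) -> np.ndarray:
        """Curve point(s) in the polar frame (pole at origin, axis along +x)."""
        t = np.asarray(theta, dtype=float)
        return np.asarray(self.r(t))[..., None] * unit(t)

    def point_world(self, theta) -> np.ndarray:
        """Curve point(s) in world coordinates."""
        return self.pole + self.point_polar(theta) @ rot(self.axis_angle).T

    def arc_rate(self, theta):
        """sqrt(r^2 + r'^2): arc length per unit polar angle (mm/rad)."""
        r = np.asarray(self.r(theta), dtype=float)
        rp = np.asarray(self.r_prime(theta), dtype=float)
        out = np.sqrt(r * r + rp * rp)
        return float(out) if out.ndim == 0 else out

    @classmethod
    def from_points(
        cls,
        points,
        pole,
        axis_angle: float = 0.0,
        side: str = "head",
        joint_hint: str = "",
    ) -> "PolarContactCurve":
        """Interpolating polar curve through ordered contact points.

        Builds r(theta) as a cubic spline through the points' polar samples.
        This is the high-accuracy path used with noise-free or dense data;
        for scattered data fit a Cartesian curve first and use
        :func:`to_polar`.
        """
        if isinstance(points, ContactPointSet):
            pts = points.points
            side = points.side
        else:
            pts = np.asarray(points, dtype=float)
        pole = np.asarray(pole, dtype=float).reshape(2)
        rel = (pts - pole) @ rot(axis_angle)
        r = np.linalg.norm(rel, axis=1)
        if np.any(r <= 1e-12):
            raise InvalidParameterError("pole lies on the curve (r = 0)")
        theta = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
        d = np.diff(theta)
        if np.all(d < 0):
            theta, r = theta[::-1], r[::-1]
        elif not np.all(d > 0):
            raise AmbiguousMappingError(
                "contact points do not subtend a monotone polar angle about "
                "the pole; angle-to-contact mapping is ambiguous"
            )
        spline = CubicSpline(theta, r)
        return cls(
            r=spline,
            r_prime=spline.derivative(1),
            r_second=spline.derivative(2),
            domain=(float(theta[0]), float(theta[-1])),
            pole=pole,
            axis_angle=axis_angle,
            side=side,
            _source=f"spline through {len(r)} points {joint_hint}".strip(),
        )

    @classmethod
    def from_callable(
        cls,
        r: Callable,
        domain: tuple,
        pole,
        axis_angle: float = 0.0,
        r_prime: Callable | None = None,
        r_second: Callable | None = None,
        side: str = "head",
    ) -> "PolarContactCurve":
        """Polar curve from an analytic radius function.

        Missing derivatives fall back to central finite differences with a
        1e-6 rad step.
        """
        if r_prime is None:
            def r_prime(t, _r=r, h=1e-6):
                return (np.asarray(_r(np.asarray(t) + h)) - np.asarray(_r(np.asarray(t) - h))) / (2 * h)
        if r_second is None:
            def r_second(t, _r=r, h=1e-4):
                t = np.asarray(t, dtype=float)
                return (np.asarray(_r(t + h)) - 2 * np.asarray(_r(t)) + np.asarray(_r(t - h))) / h**2
        return cls(
            r=r,
            r_prime=r_prime,
            r_second=r_second,
            domain=domain,
            pole=pole,
            axis_angle=axis_angle,
            side=side,
            _source="analytic",
        )


def to_polar(
    curve: CartesianContactCurve,
    pole,
    axis_angle: float = 0.0,
    n_samples: int = 200,
) -> PolarContactCurve:
    """Transform a fitted Cartesian contact curve into polar form.

    The curve is sampled uniformly in x, converted with x = r cos(theta),
    y = r sin(theta) about ``pole`` (angles measured from ``axis_angle``),
    and re-interpolated as a cubic spline in theta so that r' is available
    analytically.

    Raises
    ------
    AmbiguousMappingError
        If the curve does not subtend a monotone angle about the pole, which
        would break the angle-to-contact-point mapping.
    InvalidParameterError
        If the pole lies on the curve.
    """
    if n_samples < 4:
        raise InvalidParameterError("n_samples must be >= 4")
    pts = curve.sample(n_samples)
    return PolarContactCurve.from_points(
        pts, pole=pole, axis_angle=axis_angle, side=curve.side,
        joint_hint="(from Cartesian fit)",
    )
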