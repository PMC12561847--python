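"""Validation metrics: cycle averaging, trajectory RMSE, pressure summaries.

Kinematic alignment is scored by the RMSE between an exoskeleton fingertip
trajectory and a physiological reference after both are resampled to a common
normalized phase; ergonomic benefit is scored on interface-pressure maps by
peak pressure, mean pressure over active cells, and pressure distribution
area.  A synthetic misalignment-to-pressure generator embodies the mechanism
under test: a misaligned rotation center increases relative sliding and
concentrates interface force, so larger misalignment yields a tighter, taller
pressure blob at constant total force.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from handicor.errors import (
    DegenerateTestError,
    DimensionError,
    EmptyInputError,
    InvalidParameterError,
    UndefinedBaselineError,
)

PRESSURE_REGIONS = ("MCP", "PIP")
PRESSURE_CONDITIONS = ("without_pairs", "with_pairs")


@dataclass
class Trajectory:
    """Ordered 2-D or 3-D positions with normalized phase in [0, 1]."""

    points: np.ndarray
    phase: np.ndarray | None = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] not in (2, 3):
            raise InvalidParameterError("points must be (n, 2) or (n, 3)")
        if len(pts) < 2:
            raise InvalidParameterError("a trajectory needs at least 2 points")
        if self.phase is None:
            self.phase = np.linspace(0.0, 1.0, len(pts))
        ph = np.asarray(self.phase, dtype=float)
        if len(ph) != len(pts):
            raise InvalidParameterError("phase and points lengths differ")
        if np.any(np.diff(ph) <= 0):
            raise InvalidParameterError("phase must be strictly increasing")
        self.points = pts
        self.phase = ph

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    def resample(self, n: int) -> "Trajectory":
        """Linear interpolation onto n phases uniform in [phase0, phase1]."""
        ph = np.linspace(self.phase[0], self.phase[-1], n)
        cols = [np.interp(ph, self.phase, self.points[:, k]) for k in range(self.dim)]
        return Trajectory(points=np.column_stack(cols), phase=ph)


def average_cycles(cycles: list, n_resample: int = 101) -> Trajectory:
    """Pointwise mean of repeated motion cycles on a common phase grid.

    Each cycle is resampled to ``n_resample`` phases uniform in [0, 1] by
    linear interpolation; the representative trajectory is the pointwise
    mean.  This is the 20-cycle averaging used to stabilize measured
    trajectories before RMSE scoring.
    """
    if not cycles:
        raise EmptyInputError("average_cycles needs at least one cycle")
    dims = {c.dim for c in cycles}
    if len(dims) != 1:
        raise DimensionError("cycles mix 2-D and 3-D points")
    stack = np.stack([c.resample(n_resample).points for c in cycles])
    return Trajectory(points=stack.mean(axis=0), phase=np.linspace(0.0, 1.0, n_resample))


def trajectory_rmse(a: Trajectory, b: Trajectory, n_resample: int = 101) -> float:
    """Root-mean-square point distance after phase-uniform resampling (mm).

    Correspondence is by normalized phase: both trajectories are resampled to
    the same ``n_resample`` uniform phases and compared pointwise.
    """
    if a.dim != b.dim:
        raise DimensionError(f"dimension mismatch: {a.dim}-D vs {b.dim}-D")
    pa = a.resample(n_resample).points
    pb = b.resample(n_resample).points
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


def nearest_point_rmse(a: Trajectory, b: Trajectory, n_resample: int = 101) -> float:
    """Alternative correspondence: RMS of each resampled point of ``a`` to its
    nearest resampled point of ``b``.  Reported separately from the phase
    correspondence; not symmetric."""
    if a.dim != b.dim:
        raise DimensionError(f"dimension mismatch: {a.dim}-D vs {b.dim}-D")
    pa = a.resample(n_resample).points
    pb = b.resample(n_resample).points
    d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2).min(axis=1)
    return float(np.sqrt(d2.mean()))


@dataclass
class PressureFrame:
    """One rectangular interface-pressure map (kPa) for a region/condition/cycle."""

    grid: np.ndarray
    cell_size: float  # mm
    region: str = "MCP"
    condition: str = "without_pairs"
    cycle_index: int = 0
    sample_rate: float = 100.0  # Hz

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 2 or g.size == 0:
            raise InvalidParameterError("pressure grid must be a nonempty 2-D array")
        if np.any(g < 0):
            raise InvalidParameterError("pressures must be >= 0")
        if self.cell_size <= 0:
            raise InvalidParameterError("cell_size must be > 0")
        if self.region not in PRESSURE_REGIONS:
            raise InvalidParameterError(f"unknown region {self.region!r}")
        if self.condition not in PRESSURE_CONDITIONS:
            raise InvalidParameterError(f"unknown condition {self.condition!r}")
        self.grid = g

    def total_force(self) -> float:
        """Sum of pressure x cell area; kPa * mm^2 = mN."""
        return float(self.grid.sum() * self.cell_size**2)


@dataclass
class PressureSummary:
    """Peak/mean pressure and active contact area of one pressure frame.

    ``mean_pressure`` is taken over active cells (above the threshold), the
    convention recorded in ``mean_convention``.
    """

    mean_pressure: float  # kPa
    peak_pressure: float  # kPa
    active_area: float  # mm^2
    threshold: float = 0.0
    mean_convention: str = "active-cells"

    def __post_init__(self):
        if not (self.peak_pressure >= self.mean_pressure >= 0.0):
            raise InvalidParameterError("requires peak >= mean >= 0")
        if self.active_area < 0:
            raise InvalidParameterError("active_area must be >= 0")


def summarize_pressure(frame: PressureFrame, activity_threshold: float = 0.1) -> PressureSummary:
    """Peak pressure, mean over active cells, and active area of a frame.

    ``activity_threshold`` (kPa) is the noise floor defining an active cell;
    the default 0.1 kPa suits thin-film sensor noise.  With no active cells
    the mean and area are zero while the peak still reports the grid maximum.
    """
    if activity_threshold < 0:
        raise InvalidParameterError("activity_threshold must be >= 0")
    g = frame.grid
    peak = float(g.max())
    active = g > activity_threshold
    n_active = int(active.sum())
    mean = float(g[active].mean()) if n_active else 0.0
    area = n_active * frame.cell_size**2
    return PressureSummary(
        mean_pressure=mean, peak_pressure=peak, active_area=float(area),
        threshold=float(activity_threshold),
    )


def percent_reduction(before: PressureSummary, after: PressureSummary) -> dict:
    """Percent reductions 100*(before - after)/before for mean and peak.

    Negative values indicate an increase.  Raises
    :class:`UndefinedBaselineError` on a zero baseline.
    """
    if before.mean_pressure <= 0 or before.peak_pressure <= 0:
        raise UndefinedBaselineError("percent reduction undefined for zero baseline")
    return {
        "mean": 100.0 * (before.mean_pressure - after.mean_pressure) / before.mean_pressure,
        "peak": 100.0 * (before.peak_pressure - after.peak_pressure) / before.peak_pressure,
    }


def paired_t_test(x, y):
    """Two-sided paired t-test on matched samples.

    Returns ``(t, p, df)`` with df = n - 1.  Differences with zero variance
    (including a constant offset with noise-free data) are flagged as
    degenerate rather than reported as an infinite statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("paired samples must be equal-length 1-D")
    if len(x) < 2:
        raise InvalidParameterError("need at least 2 pairs")
    d = x - y
    if np.std(d, ddof=1) == 0:
        raise DegenerateTestError(
            "zero-variance differences: paired t statistic is undefined "
            "(all pairs differ by the same constant)"
        )
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue), int(len(x) - 1)


def generate_pressure_frames(
    misalignment: float,
    total_force: float = 2000.0,
    grid_shape: tuple = (40, 40),
    cell_size: float = 1.0,
    concentration_gain: float = 0.065,
    noise_sd: float = 0.0,
    n_cycles: int = 20,
    seed: int = 0,
    region: str = "MCP",
    condition: str = "without_pairs",
    sigma0: float = 4.0,
) -> list:
    """Synthetic interface-pressure frames for a given pivot misalignment.

    Embodies the alignment hypothesis: misalignment between the exoskeleton
    pivot and the joint's equivalent ICOR increases relative sliding and
    concentrates interface force.  The pressure field is an isotropic
    Gaussian blob of fixed total force whose spread shrinks with misalignment
    ``m`` (mm):

        sigma(m) = sigma0 / (1 + concentration_gain * m)

    so peak pressure rises and active area falls as ``m`` grows, while total
    force (sum x cell area) is conserved exactly before noise.  The default
    gain 0.065/mm is calibrated in closed form so that reducing misalignment
    from 3 mm to 0.5 mm lowers the peak by 20-30% (the experimentally
    observed band); the default grid spans at least 5 sigma so the blob is
    not clipped at the sensor-patch edge.  See docs/methods.md.

    Returns ``n_cycles`` frames differing only in their additive noise draw.
    """
    if misalignment < 0:
        raise InvalidParameterError("misalignment must be >= 0")
    if total_force <= 0 or cell_size <= 0 or sigma0 <= 0:
        raise InvalidParameterError("total_force, cell_size and sigma0 must be > 0")
    if concentration_gain < 0:
        raise InvalidParameterError("concentration_gain must be >= 0")
    ny, nx = int(grid_shape[0]), int(grid_shape[1])
    if ny < 2 or nx < 2:
        raise InvalidParameterError("grid_shape must be at least 2x2")
    rng = np.random.default_rng(seed)
    sigma = sigma0 / (1.0 + concentration_gain * misalignment)
    ys = (np.arange(ny) - (ny - 1) / 2) * cell_size
    xs = (np.arange(nx) - (nx - 1) / 2) * cell_size
    X, Y = np.meshgrid(xs, ys)
    blob = np.exp(-(X**2 + Y**2) / (2.0 * sigma**2))
    blob *= total_force / (blob.sum() * cell_size**2)  # exact conservation
    frames = []
    for k in range(n_cycles):
        g = blob.copy()
        if noise_sd > 0:
            g = np.clip(g + rng.normal(0.0, noise_sd, g.shape), 0.0, None)
        frames.append(
            PressureFrame(
                grid=g, cell_size=cell_size, region=region,
                condition=condition, cycle_index=k,
            )
        )
    return frames
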