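"""File formats, run configuration and run manifests.

All distances are written in millimetres and all internal angles in radians;
units are embedded in column names (``x_mm``, ``theta_rad``) so files cannot
silently drift units.  Degrees appear only in configuration files and
human-facing summaries.  Numeric columns are written at full double
precision, so write -> read round trips reproduce values to better than
1e-9 mm and identical runs produce byte-identical data files.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from handicor import irm_core
from handicor.contact_curves import SIDES, CartesianContactCurve, ContactPointSet
from handicor.errors import ConfigError, EmptyInputError, ParseError
from handicor.evaluation import PressureFrame, Trajectory

_FMT = "%.17g"


def _fmt(v: float) -> str:
    return _FMT % float(v)


# ---------------------------------------------------------------------------
# Run configuration and manifest


_RUN_CONFIG_FIELDS = {
    "pole": None,
    "axis_angle_deg": 0.0,
    "head_degree": 4,
    "base_degree": 3,
    "direction_mode": "geometric",
    "sign_convention": "curvature_center",
    "n_resample": 101,
    "n_icor_samples": 200,
    "solver_tol": 1e-9,
    "activity_threshold_kpa": 0.1,
    "seed": 0,
    "out_dir": ".",
}


@dataclasses.dataclass
class RunConfig:
    """Validated run options shared by the CLI commands.

    Unknown keys are rejected; tolerances must be positive; the seed is
    recorded in every manifest so outputs are reproducible.
    """

    pole: tuple | None = None
    axis_angle_deg: float = 0.0
    head_degree: int = 4
    base_degree: int = 3
    direction_mode: str = "geometric"
    sign_convention: str = "curvature_center"
    n_resample: int = 101
    n_icor_samples: int = 200
    solver_tol: float = 1e-9
    activity_threshold_kpa: float = 0.1
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self):
        if self.solver_tol <= 0:
            raise ConfigError("solver_tol must be > 0")
        if self.n_resample < 2 or self.n_icor_samples < 2:
            raise ConfigError("resampling counts must be >= 2")
        if self.activity_threshold_kpa < 0:
            raise ConfigError("activity_threshold_kpa must be >= 0")

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        unknown = set(data) - set(_RUN_CONFIG_FIELDS)
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_mapping(data)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(out_dir, command: str, config: dict, inputs: list, outputs: list) -> Path:
    """Write a run manifest (tool version, config echo, input checksums).

    Emitted beside the outputs of every CLI invocation; data outputs stay
    byte-identical across identical runs, the manifest alone carries the
    timestamp.
    """
    from handicor import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "handicor",
        "version": __version__,
        "command": command,
        "config": config,
        "inputs": {str(p): file_checksum(p) for p in inputs if Path(p).exists()},
        "outputs": [str(p) for p in outputs],
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# Contact points


def write_contact_points(points: ContactPointSet, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("joint,side,sample_index,x_mm,y_mm\n")
        for i, (x, y) in enumerate(points.points):
            fh.write(f"{points.joint},{points.side},{i},{_fmt(x)},{_fmt(y)}\n")
    return path


def read_contact_points(path) -> ContactPointSet:
    """Read a ``joint,side,sample_index,x_mm,y_mm`` CSV.

    Raises :class:`ParseError` with a line number on missing columns,
    non-numeric coordinates, unknown labels, or duplicate sample indices; a
    ``z_mm`` column is rejected with a pointer to the planar-projection
    helper.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as err:
        raise ParseError(f"{path}: {err}") from err
    if "z_mm" in df.columns:
        raise ParseError(
            f"{path}: found a z_mm column; the instant-radius pipeline is "
            "planar -- project 3-D points first with "
            "handicor.synthetic_joint.project_points_to_plane"
        )
    required = ["joint", "side", "sample_index", "x_mm", "y_mm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")
    if df.empty:
        raise EmptyInputError(f"{path}: no contact points")
    joints = df["joint"].unique()
    sides = df["side"].unique()
    if len(joints) != 1 or len(sides) != 1:
        raise ParseError(f"{path}: expected a single joint/side per file")
    side = sides[0]
    if side not in SIDES:
        raise ParseError(f"{path} line 2: unknown side label {side!r}")
    rows = []
    seen = {}
    for k, row in df.iterrows():
        line = k + 2  # header is line 1
        try:
            idx = int(row["sample_index"])
            x = float(row["x_mm"])
            y = float(row["y_mm"])
        except (TypeError, ValueError) as err:
            raise ParseError(f"{path} line {line}: non-numeric value ({err})") from err
        if idx in seen:
            raise ParseError(
                f"{path} line {line}: duplicate sample_index {idx} "
                f"(first at line {seen[idx]})"
            )
        seen[idx] = line
        rows.append((idx, x, y))
    rows.sort(key=lambda r: r[0])
    pts = np.array([(x, y) for _, x, y in rows])
    try:
        return ContactPointSet(joint=joints[0], side=side, points=pts, source=str(path))
    except Exception as err:
        raise ParseError(f"{path}: {err}") from err


def write_truth_icor(t, icor, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("t,x_mm,y_mm\n")
        for ti, (x, y) in zip(np.asarray(t), np.asarray(icor)):
            fh.write(f"{_fmt(ti)},{_fmt(x)},{_fmt(y)}\n")
    return path


# ---------------------------------------------------------------------------
# Trajectories


def write_trajectory(traj: Trajectory, path) -> Path:
    """Write ``phase,x_mm,y_mm[,z_mm]``; refuses trajectories with < 2 points."""
    if len(traj.points) < 2:
        raise EmptyInputError("refusing to write a trajectory with < 2 points")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ["x_mm", "y_mm", "z_mm"][: traj.dim]
    with path.open("w") as fh:
        fh.write("phase," + ",".join(cols) + "\n")
        for ph, pt in zip(traj.phase, traj.points):
            fh.write(_fmt(ph) + "," + ",".join(_fmt(v) for v in pt) + "\n")
    return path


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as err:
        raise ParseError(f"{path}: {err}") from err
    cols = [c for c in ("x_mm", "y_mm", "z_mm") if c in df.columns]
    if "phase" not in df.columns or len(cols) < 2:
        raise ParseError(f"{path}: need columns phase,x_mm,y_mm[,z_mm]")
    try:
        return Trajectory(points=df[cols].to_numpy(dtype=float),
                          phase=df["phase"].to_numpy(dtype=float))
    except Exception as err:
        raise ParseError(f"{path}: {err}") from err


def write_linkage_trajectory(poses: list, path) -> Path:
    """Write solved finger poses: ``step,phase,x_mm,y_mm,z_mm,mcp_deg,pip_deg,dip_deg``."""
    if len(poses) < 2:
        raise EmptyInputError("refusing to write a trajectory with < 2 steps")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = len(poses)
    with path.open("w") as fh:
        fh.write("step,phase,x_mm,y_mm,z_mm,mcp_deg,pip_deg,dip_deg\n")
        for k, pose in enumerate(poses):
            ph = k / (n - 1)
            x, y, z = pose.fingertip
            fh.write(
                f"{k},{_fmt(ph)},{_fmt(x)},{_fmt(y)},{_fmt(z)},"
                f"{_fmt(pose.flexion_angles.get('MCP', 0.0))},"
                f"{_fmt(pose.flexion_angles.get('PIP', 0.0))},"
                f"{_fmt(pose.flexion_angles.get('DIP', 0.0))}\n"
            )
    return path


def write_icor_trajectory(traj: irm_core.ICORTrajectory, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("theta_rad,r_c_mm,x_mm,y_mm\n")
        for th, rc, (x, y) in zip(traj.theta, traj.r_c, traj.xy):
            fh.write(f"{_fmt(th)},{_fmt(rc)},{_fmt(x)},{_fmt(y)}\n")
    return path


def read_icor_trajectory(path) -> irm_core.ICORTrajectory:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as err:
        raise ParseError(f"{path}: {err}") from err
    required = ["theta_rad", "r_c_mm", "x_mm", "y_mm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")
    theta = df["theta_rad"].to_numpy(dtype=float)
    xy = df[["x_mm", "y_mm"]].to_numpy(dtype=float)
    pole = xy.mean(axis=0) * 0.0  # pole unknown from the file; radii are stored
    try:
        return irm_core.ICORTrajectory(
            theta=theta, r_c=df["r_c_mm"].to_numpy(dtype=float), xy=xy, pole=pole
        )
    except Exception as err:
        raise ParseError(f"{path}: {err}") from err


# ---------------------------------------------------------------------------
# Fitted curves and equivalent centers


def curve_to_json(curve: CartesianContactCurve, pole=None, axis_angle_deg=None) -> dict:
    return {
        "side": curve.side,
        "fit_residual_rms_mm": curve.fit_residual_rms,
        "pieces": [
            {"coefficients": [float(c) for c in coef], "x_interval_mm": [lo, hi]}
            for coef, (lo, hi) in curve.pieces
        ],
        "pole_mm": None if pole is None else [float(pole[0]), float(pole[1])],
        "axis_angle_deg": axis_angle_deg,
    }


def write_curve_json(curve, path, pole=None, axis_angle_deg=None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(curve_to_json(curve, pole, axis_angle_deg), indent=2) + "\n")
    return path


def write_equivalent_icor(eq: irm_core.EquivalentICOR, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "center_mm": [float(eq.center[0]), float(eq.center[1])],
        "sum_sq_residual_mm2": eq.sum_sq_residual,
        "n_samples": eq.n_samples,
        "weighting": eq.weighting,
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


# ---------------------------------------------------------------------------
# Pressure frames


def write_pressure_frame(frame: PressureFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("# region,condition,cycle,cell_size_mm,sample_rate_hz\n")
        fh.write(
            f"# {frame.region},{frame.condition},{frame.cycle_index},"
            f"{_fmt(frame.cell_size)},{_fmt(frame.sample_rate)}\n"
        )
        for row in frame.grid:
            fh.write(",".join(_fmt(v) for v in row) + "\n")
    return path


def read_pressure_frame(path) -> PressureFrame:
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3 or not lines[0].startswith("#") or not lines[1].startswith("#"):
        raise ParseError(f"{path}: expected two '#' header lines then grid rows")
    meta = [s.strip() for s in lines[1].lstrip("# ").split(",")]
    if len(meta) < 4:
        raise ParseError(f"{path} line 2: expected region,condition,cycle,cell_size_mm")
    try:
        grid = np.array([[float(v) for v in ln.split(",")] for ln in lines[2:] if ln.strip()])
        return PressureFrame(
            grid=grid,
            cell_size=float(meta[3]),
            region=meta[0],
            condition=meta[1],
            cycle_index=int(meta[2]),
            sample_rate=float(meta[4]) if len(meta) > 4 else 100.0,
        )
    except ParseError:
        raise
    except Exception as err:
        raise ParseError(f"{path}: {err}") from err
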