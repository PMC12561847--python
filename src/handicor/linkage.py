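"""Three-loop ten-linkage exoskeleton finger model in Lagrangian coordinates.

The flexion transmission of the exoskeleton finger is a planar mechanism of
nine moving links l1..l9 plus a frame of length f.  Links l1, l2, l5 and l7
are segmented (a front and a rear segment joined at a fixed bend), and links
l6 and l8 carry second rigid arms whose orientation coordinates phi6' and
phi8' are affinely dependent on phi6 and phi8.  Three closed loops are formed:
L1 (five bars including the frame), L2 (six bars) and L3 (five bars).  Each
link's orientation phi_k is measured counterclockwise from the +x axis
(horizontal rightward), giving 11 Lagrangian coordinates of which 9 are
independent -- the mechanism is underactuated.

The module provides loop-closure residuals and a damped-Newton closure
solver over a generic vector-loop system, structural DOF accounting, the
relocation of MCP/PIP pivots to equivalent ICORs (crossing-type pairs), a
lateral-swing expansion to a spatial two-DOF finger, and fingertip
trajectories for alignment studies.

The default geometry is synthetic and non-anatomical: the actual hardware
dimensions are not published, so a planar embedding was designed once (frozen
vertex layout below) and all lengths, bend angles and initial coordinates are
derived from it, guaranteeing an exactly closed initial configuration.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from handicor._geometry import rot, unit
from handicor.errors import (
    ConfigError,
    SingularConfigurationError,
    SolverError,
    UnsupportedJointError,
)
from handicor.irm_core import EquivalentICOR

MOVING_LINKS = tuple(f"l{i}" for i in range(1, 10))
SEGMENTED_LINKS = ("l1", "l2", "l5", "l7")
LOOP_BAR_COUNTS = {"L1": 5, "L2": 6, "L3": 5}

# ---------------------------------------------------------------------------
# Default synthetic embedding (mm).  Chosen once at design time; every length
# and angle in the default config derives from these vertices, so the initial
# state closes all three loops to machine precision.
_DEFAULT_VERTICES = {
    "A": (0.0, 0.0), "B": (30.0, 0.0),
    "M1": (2.0, 14.0), "C": (12.0, 20.0),
    "M2": (24.0, 24.0), "D": (36.0, 22.0),
    "E": (46.0, 12.0), "M5": (58.0, 16.0), "F": (66.0, 26.0),
    "G": (80.0, 20.0), "G2": (76.0, 34.0),
    "H": (88.0, 32.0), "K": (100.0, 24.0),
}

# piece -> (link, coordinate, from-node, to-node); "frame" has no coordinate.
_DEFAULT_PIECES = {
    "frame": (None, None, "A", "B"),
    "l1a": ("l1", "phi1", "A", "M1"), "l1b": ("l1", "phi1", "M1", "C"),
    "l2a": ("l2", "phi2", "C", "M2"), "l2b": ("l2", "phi2", "M2", "D"),
    "l3": ("l3", "phi3", "D", "E"),
    "l4": ("l4", "phi4", "E", "B"),
    "l5a": ("l5", "phi5", "E", "M5"), "l5b": ("l5", "phi5", "M5", "F"),
    "l6a": ("l6", "phi6", "F", "G"), "l6b": ("l6", "phi6p", "F", "G2"),
    "l7a": ("l7", "phi7", "G", "H"), "l7b": ("l7", "phi7", "H", "K"),
    "l8a": ("l8", "phi8", "H", "M2"), "l8b": ("l8", "phi8p", "H", "M5"),
    "l9": ("l9", "phi9", "G2", "K"),
}

_DEFAULT_LOOPS = {
    "L1": [("l1a", 1), ("l1b", 1), ("l2a", 1), ("l2b", 1), ("l3", 1),
           ("l4", 1), ("frame", -1)],
    "L2": [("l2b", 1), ("l3", 1), ("l5a", 1), ("l5b", 1), ("l6a", 1),
           ("l7a", 1), ("l8a", 1)],
    "L3": [("l5b", 1), ("l6b", 1), ("l9", 1), ("l7b", -1), ("l8b", 1)],
}

_DEFAULT_DRIVERS = ("phi1", "phi5", "phi9")

_DEFAULT_FINGERTIP_PATH = ("l1a", "l1b", "l2a", "l2b", "l3", "l5a", "l5b",
                           "l6a", "l7a", "l7b")


def _edge_angle_deg(a, b):
    d = np.asarray(_DEFAULT_VERTICES[b]) - np.asarray(_DEFAULT_VERTICES[a])
    return math.degrees(math.atan2(d[1], d[0]))


def _edge_length(a, b):
    d = np.asarray(_DEFAULT_VERTICES[b]) - np.asarray(_DEFAULT_VERTICES[a])
    return float(np.linalg.norm(d))


def default_config() -> dict:
    """The canonical synthetic finger configuration (deep-copied).

    Lengths in mm, angles in degrees.  Labeled non-anatomical: dimensions are
    a design-time synthetic embedding, not measured hardware.
    """
    pieces = {}
    coord_angle: dict = {}
    for name, (link, coord, a, b) in _DEFAULT_PIECES.items():
        ang = _edge_angle_deg(a, b)
        entry = {"link": link, "length": _edge_length(a, b)}
        if coord is None:
            entry["coordinate"] = None
            entry["angle_deg"] = ang
        else:
            entry["coordinate"] = coord
            if coord not in coord_angle:
                coord_angle[coord] = ang
            entry["offset_deg"] = ang - coord_angle[coord]
        pieces[name] = entry

    beta6 = coord_angle["phi6p"] - coord_angle["phi6"]
    beta8 = coord_angle["phi8p"] - coord_angle["phi8"]
    cfg = {
        "name": "default synthetic finger (non-anatomical)",
        "units": {"length": "mm", "angle": "deg"},
        "frame_length": _edge_length("A", "B"),
        "pieces": pieces,
        "coordinates": [f"phi{i}" for i in range(1, 10)] + ["phi6p", "phi8p"],
        "dependencies": {
            "phi6p": {"source": "phi6", "a": 1.0, "b_deg": beta6},
            "phi8p": {"source": "phi8", "a": 1.0, "b_deg": beta8},
        },
        "loops": {k: [list(e) for e in v] for k, v in _DEFAULT_LOOPS.items()},
        "initial_state_deg": {
            c: coord_angle[c] for c in coord_angle if not c.endswith("p")
        },
        "drivers": list(_DEFAULT_DRIVERS),
        # Flexion sweep of the driving coordinates, degrees relative to the
        # initial state; verified solvable by continuation at design time.
        "sweep_deg": {"phi1": -40.0, "phi5": -30.0, "phi9": -25.0},
        "fingertip_path": list(_DEFAULT_FINGERTIP_PATH),
        "ground_point": [0.0, 0.0],
        # Anatomical surrogate pivots for the alignment studies (mm): MCP at
        # the origin, proximal/middle/distal phalanx lengths 45/25/20.
        "joint_centers": {
            "MCP": {"point": [0.0, 0.0], "type": "fixed"},
            "PIP": {"point": [45.0, 0.0], "type": "fixed"},
            "DIP": {"point": [70.0, 0.0], "type": "fixed"},
            "TIP": {"point": [90.0, 0.0], "type": "marker"},
        },
        # Readout of finger flexion angles from mechanism coordinates:
        # flex_deg = scale * (ref_deg - phi_deg).  MCP/PIP track the two
        # drive coordinates, DIP the passive distal link; scales chosen at
        # design time so the default sweep spans the assisted ranges of
        # motion monotonically (MCP 0-75, PIP 0-103, DIP 0-74 degrees).
        "flexion_readouts": {
            "MCP": {"coordinate": "phi1", "scale": 1.875},
            "PIP": {"coordinate": "phi5", "scale": 103.0 / 30.0},
            "DIP": {"coordinate": "phi7", "scale": 0.845477},
        },
        "lateral_axis_point": [0.0, 0.0],
    }
    return copy.deepcopy(cfg)


# ---------------------------------------------------------------------------
# Generic vector-loop machinery


@dataclass
class LoopEdge:
    length: float
    coordinate: str | None  # None -> fixed angle
    offset: float  # rad; for fixed edges this is the absolute angle
    sign: int
    piece: str = ""
    link: str | None = None


@dataclass
class VectorLoopSystem:
    """Planar vector-loop equations over named angle coordinates.

    ``dependencies`` maps a dependent coordinate to ``(source, a, b)`` with
    value ``a * source + b`` (radians).  Loops are lists of
    :class:`LoopEdge`; the closure residual of a loop is the vector sum of
    its signed edges.
    """

    coordinates: list
    dependencies: dict
    loops: dict

    def __post_init__(self):
        for dep, (src, a, _b) in self.dependencies.items():
            if dep not in self.coordinates or src not in self.coordinates:
                raise ConfigError(f"dependency {dep} <- {src} names unknown coordinates")
            if src in self.dependencies:
                # only one level of chaining is meaningful here; walking
                # further would indicate a circular declaration
                seen = {dep}
                cur = src
                while cur in self.dependencies:
                    if cur in seen:
                        raise ConfigError(f"circular dependency through {cur}")
                    seen.add(cur)
                    cur = self.dependencies[cur][0]

    @property
    def independent(self) -> list:
        return [c for c in self.coordinates if c not in self.dependencies]

    def n_constraints(self) -> int:
        return 2 * len(self.loops)

    def resolve(self, values: dict) -> dict:
        """Complete a coordinate dict by applying the dependency maps."""
        out = dict(values)
        for dep, (src, a, b) in self.dependencies.items():
            if src in out:
                out[dep] = a * out[src] + b
        return out

    def _edge_angle(self, edge: LoopEdge, values: dict) -> float:
        if edge.coordinate is None:
            return edge.offset
        return values[edge.coordinate] + edge.offset

    def residuals(self, values: dict) -> np.ndarray:
        """(n_loops, 2) closure residual vectors (mm), loop order as declared."""
        values = self.resolve(values)
        out = np.zeros((len(self.loops), 2))
        for i, edges in enumerate(self.loops.values()):
            for e in edges:
                out[i] += e.sign * e.length * unit(self._edge_angle(e, values))
        return out

    def _coord_sensitivity(self, coordinate: str) -> dict:
        """d(coordinate)/d(independent coords): {indep: factor}."""
        a_total = 1.0
        cur = coordinate
        while cur in self.dependencies:
            src, a, _b = self.dependencies[cur]
            a_total *= a
            cur = src
        return {cur: a_total}

    def jacobian(self, values: dict, unknowns: list) -> np.ndarray:
        """(2*n_loops, len(unknowns)) Jacobian of stacked residuals."""
        values = self.resolve(values)
        cols = {u: k for k, u in enumerate(unknowns)}
        Jm = np.zeros((2 * len(self.loops), len(unknowns)))
        for i, edges in enumerate(self.loops.values()):
            for e in edges:
                if e.coordinate is None:
                    continue
                sens = self._coord_sensitivity(e.coordinate)
                ang = self._edge_angle(e, values)
                dvec = e.sign * e.length * np.array([-math.sin(ang), math.cos(ang)])
                for indep, factor in sens.items():
                    if indep in cols:
                        Jm[2 * i : 2 * i + 2, cols[indep]] += factor * dvec
        return Jm

    def solve(
        self,
        driving: dict,
        guess: dict,
        tol: float = 1e-9,
        max_iter: int = 100,
    ) -> dict:
        """Damped-Newton loop closure for the non-driven independent coordinates.

        Returns the resolved coordinate dict of the branch nearest the guess.

        Raises
        ------
        SolverError
            On non-convergence within ``max_iter`` iterations (message carries
            the final residual).
        SingularConfigurationError
            If the closure Jacobian becomes singular.
        """
        unknowns = [c for c in self.independent if c not in driving]
        n_eq = self.n_constraints()
        if len(driving) != len(self.independent) - n_eq:
            raise ConfigError(
                f"expected {len(self.independent) - n_eq} driving inputs "
                f"({len(self.independent)} independent coordinates, {n_eq} "
                f"closure constraints), got {len(driving)}"
            )
        values = self.resolve({**guess, **driving})
        x = np.array([values[u] for u in unknowns])
        for _ in range(max_iter):
            values.update(zip(unknowns, x))
            values = self.resolve(values)
            r = self.residuals(values).ravel()
            if np.max(np.abs(r)) < tol:
                return values
            Jm = self.jacobian(values, unknowns)
            try:
                cond = np.linalg.cond(Jm)
            except np.linalg.LinAlgError:  # pragma: no cover
                cond = np.inf
            if not np.isfinite(cond) or cond > 1e12:
                raise SingularConfigurationError(
                    f"singular closure Jacobian (cond={cond:.3g})"
                )
            step = np.linalg.lstsq(Jm, -r, rcond=None)[0]
            lam, r0 = 1.0, np.linalg.norm(r)
            for _bt in range(25):
                trial = dict(values)
                trial.update(zip(unknowns, x + lam * step))
                trial = self.resolve(trial)
                if np.linalg.norm(self.residuals(trial).ravel()) < r0:
                    break
                lam /= 2
            else:
                raise SolverError(
                    f"line search stalled; residual {r0:.3e} mm"
                )
            x = x + lam * step
        values.update(zip(unknowns, x))
        values = self.resolve(values)
        r = self.residuals(values)
        raise SolverError(
            f"no convergence in {max_iter} iterations; max residual "
            f"{np.max(np.abs(r)):.3e} mm"
        )


# ---------------------------------------------------------------------------
# Canonical finger topology


@dataclass
class LagrangianState:
    """Values of the 11 Lagrangian coordinates with their dependency maps."""

    values: dict
    dependencies: dict = field(default_factory=dict)

    def __post_init__(self):
        for dep, (src, a, b) in self.dependencies.items():
            if dep in self.values and src in self.values:
                expect = a * self.values[src] + b
                if abs(self.values[dep] - expect) > 1e-12:
                    raise ConfigError(
                        f"dependent coordinate {dep} inconsistent with its "
                        f"affine map ({self.values[dep]!r} vs {expect!r})"
                    )

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def as_dict(self) -> dict:
        return dict(self.values)


@dataclass
class LinkageTopology:
    """Validated three-loop ten-linkage finger topology."""

    config: dict
    system: VectorLoopSystem
    link_lengths: dict
    segmented_links: dict
    frame_length: float
    joint_centers: dict
    initial_state: LagrangianState

    @property
    def loops(self) -> dict:
        return self.system.loops

    def loop_bar_counts(self) -> dict:
        out = {}
        for name, edges in self.system.loops.items():
            bars = {e.link for e in edges if e.link is not None}
            nframe = sum(1 for e in edges if e.link is None)
            out[name] = len(bars) + nframe
        return out


@dataclass
class FingerPose:
    """One solved finger configuration with its 3-D fingertip position."""

    flexion_angles: dict  # {"MCP","PIP","DIP"} degrees
    abduction_angle: float  # degrees
    fingertip: np.ndarray  # (3,) mm
    state: LagrangianState | None = None

    def __post_init__(self):
        self.fingertip = np.asarray(self.fingertip, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.fingertip)):
            raise ConfigError("fingertip position must be finite")


@dataclass
class JointLimits:
    """Inclusive [min, max] ranges (degrees) per joint motion."""

    ranges: dict

    def __post_init__(self):
        for motion, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ConfigError(f"joint limit for {motion}: min must be < max")


#: Assisted ranges of motion (degrees) measured with the exoskeleton donned.
FOUR_FINGER_LIMITS = JointLimits(
    ranges={
        "mcp_abduction": (-20.0, 25.0),
        "mcp_flexion": (0.0, 75.0),
        "pip_flexion": (0.0, 103.0),
        "dip_flexion": (0.0, 74.0),
    }
)

THUMB_LIMITS = JointLimits(
    ranges={
        "mcp_abduction": (-30.0, 30.0),
        "mcp_flexion": (0.0, 75.0),
        "dip_flexion": (0.0, 78.0),
    }
)


def _build_system(cfg: dict) -> VectorLoopSystem:
    deps = {
        dep: (d["source"], float(d.get("a", 1.0)), math.radians(float(d.get("b_deg", 0.0))))
        for dep, d in cfg.get("dependencies", {}).items()
    }
    loops = {}
    for lname, edges in cfg["loops"].items():
        loop_edges = []
        for piece_name, sign in edges:
            if piece_name not in cfg["pieces"]:
                raise ConfigError(f"loop {lname} references unknown piece {piece_name!r}")
            p = cfg["pieces"][piece_name]
            if p["coordinate"] is None:
                edge = LoopEdge(
                    length=float(p["length"]), coordinate=None,
                    offset=math.radians(float(p["angle_deg"])),
                    sign=int(sign), piece=piece_name, link=p.get("link"),
                )
            else:
                edge = LoopEdge(
                    length=float(p["length"]), coordinate=p["coordinate"],
                    offset=math.radians(float(p.get("offset_deg", 0.0))),
                    sign=int(sign), piece=piece_name, link=p.get("link"),
                )
            loop_edges.append(edge)
        loops[lname] = loop_edges
    return VectorLoopSystem(
        coordinates=list(cfg["coordinates"]), dependencies=deps, loops=loops
    )


def build_topology(config: dict | None = None) -> LinkageTopology:
    """Validate a finger configuration and build the loop system.

    Raises :class:`ConfigError` naming the offending field on wrong link
    counts, non-positive lengths, unknown loop pieces, or unclosed initial
    loops.
    """
    cfg = copy.deepcopy(config) if config is not None else default_config()
    if "pieces" not in cfg or "loops" not in cfg:
        raise ConfigError("config must declare 'pieces' and 'loops'")

    link_lengths: dict = {}
    segmented: dict = {}
    for pname, p in cfg["pieces"].items():
        if float(p["length"]) <= 0:
            raise ConfigError(f"piece {pname!r}: length must be > 0")
        link = p.get("link")
        if link is not None:
            link_lengths.setdefault(link, 0.0)
            link_lengths[link] += float(p["length"])
            if link in SEGMENTED_LINKS:
                segmented.setdefault(link, []).append(pname)
    missing = [l for l in MOVING_LINKS if l not in link_lengths]
    if missing:
        raise ConfigError(f"config missing moving link(s): {', '.join(missing)}")
    extra = [l for l in link_lengths if l not in MOVING_LINKS]
    if extra:
        raise ConfigError(f"unknown moving link(s): {', '.join(extra)}")

    for lname in cfg["loops"]:
        if lname not in LOOP_BAR_COUNTS:
            raise ConfigError(f"unknown loop {lname!r}")
    for lname in LOOP_BAR_COUNTS:
        if lname not in cfg["loops"]:
            raise ConfigError(f"config missing loop {lname!r}")

    system = _build_system(cfg)
    state = LagrangianState(
        values=system.resolve(
            {c: math.radians(v) for c, v in cfg["initial_state_deg"].items()}
        ),
        dependencies=system.dependencies,
    )

    topo = LinkageTopology(
        config=cfg,
        system=system,
        link_lengths=link_lengths,
        segmented_links=segmented,
        frame_length=float(cfg.get("frame_length", 0.0)),
        joint_centers=copy.deepcopy(cfg.get("joint_centers", {})),
        initial_state=state,
    )

    counts = topo.loop_bar_counts()
    for lname, expect in LOOP_BAR_COUNTS.items():
        if counts[lname] != expect:
            raise ConfigError(
                f"loop {lname} has {counts[lname]} bars; expected {expect}"
            )
    resid = system.residuals(state.values)
    if np.max(np.abs(resid)) > 1e-6:
        raise ConfigError(
            f"initial state does not close the loops (max residual "
            f"{np.max(np.abs(resid)):.3g} mm): unclosed loop cycle"
        )
    return topo


def count_lagrangian_coordinates(topology) -> int:
    """Number of Lagrangian angle coordinates (one per moving link plus one
    per declared primed coordinate)."""
    system = topology.system if isinstance(topology, LinkageTopology) else topology
    return len(system.coordinates)


def independent_coordinate_count(state_or_system) -> int:
    """Total coordinates minus the rank of the affine dependency system."""
    if isinstance(state_or_system, LinkageTopology):
        coords, deps = state_or_system.system.coordinates, state_or_system.system.dependencies
    elif isinstance(state_or_system, VectorLoopSystem):
        coords, deps = state_or_system.coordinates, state_or_system.dependencies
    else:  # LagrangianState
        coords = list(state_or_system.values)
        deps = state_or_system.dependencies
    if not deps:
        return len(coords)
    for dep, (src, _a, _b) in deps.items():
        seen = {dep}
        cur = src
        while cur in deps:
            if cur in seen:
                raise ConfigError(f"circular dependency through {cur}")
            seen.add(cur)
            cur = deps[cur][0]
    idx = {c: i for i, c in enumerate(coords)}
    A = np.zeros((len(deps), len(coords)))
    for k, (dep, (src, a, _b)) in enumerate(deps.items()):
        A[k, idx[dep]] = 1.0
        A[k, idx[src]] = -a
    return len(coords) - int(np.linalg.matrix_rank(A))


def loop_closure_residuals(topology: LinkageTopology, state) -> np.ndarray:
    """(n_loops, 2) vector-loop closure residuals (mm) at ``state``."""
    values = state.values if isinstance(state, LagrangianState) else dict(state)
    return topology.system.residuals(values)


def solve_configuration(
    topology: LinkageTopology,
    driving_inputs: dict,
    initial_guess=None,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> LagrangianState:
    """Solve loop closure for the given driving coordinates (radians).

    The branch nearest the initial guess (default: the topology's initial
    state) is returned; sweeps should warm-start each step from the previous
    solution to follow a continuous physical motion.
    """
    guess = initial_guess.values if isinstance(initial_guess, LagrangianState) else (
        dict(initial_guess) if initial_guess is not None else topology.initial_state.values
    )
    values = topology.system.solve(driving_inputs, guess, tol=tol, max_iter=max_iter)
    return LagrangianState(values=values, dependencies=topology.system.dependencies)


def apply_crossing_pair(
    topology: LinkageTopology, joint: str, center
) -> LinkageTopology:
    """Relocate a joint pivot to an equivalent ICOR (crossing-type pair).

    Only the MCP and PIP joints accept crossing-type pairs; the DIP joint
    keeps a conventional revolute pair (limited space and motion range), so
    requesting it raises :class:`UnsupportedJointError`.  Effective phalanx
    segment lengths between adjacent centers are recomputed.
    """
    joint = joint.upper()
    if joint not in ("MCP", "PIP"):
        raise UnsupportedJointError(
            f"crossing-type pair not available at {joint}: only MCP and PIP "
            "carry biomimetic pairs (the DIP keeps a conventional revolute pair)"
        )
    pt = center.center if isinstance(center, EquivalentICOR) else np.asarray(center, dtype=float)
    new = copy.deepcopy(topology)
    if joint not in new.joint_centers:
        raise ConfigError(f"topology has no joint center {joint!r}")
    new.joint_centers[joint]["point"] = [float(pt[0]), float(pt[1])]
    new.joint_centers[joint]["type"] = "crossing"
    order = [j for j in ("MCP", "PIP", "DIP", "TIP") if j in new.joint_centers]
    segs = {}
    for a, b in zip(order[:-1], order[1:]):
        pa = np.asarray(new.joint_centers[a]["point"])
        pb = np.asarray(new.joint_centers[b]["point"])
        segs[f"{a}-{b}"] = float(np.linalg.norm(pb - pa))
    new.config["effective_segments_mm"] = segs
    return new


def joint_link_vectors(topology: LinkageTopology, joint: str) -> dict:
    """Vectors from adjacent joint centers to ``joint``'s center (mm)."""
    order = [j for j in ("MCP", "PIP", "DIP", "TIP") if j in topology.joint_centers]
    i = order.index(joint)
    p = np.asarray(topology.joint_centers[joint]["point"], dtype=float)
    out = {}
    if i > 0:
        out["incoming"] = p - np.asarray(topology.joint_centers[order[i - 1]]["point"])
    if i < len(order) - 1:
        out["outgoing"] = np.asarray(topology.joint_centers[order[i + 1]]["point"]) - p
    return out


def _fingertip_planar(topology: LinkageTopology, values: dict) -> np.ndarray:
    cfg = topology.config
    pos = np.asarray(cfg.get("ground_point", [0.0, 0.0]), dtype=float).copy()
    values = topology.system.resolve(values)
    for pname in cfg["fingertip_path"]:
        p = cfg["pieces"][pname]
        if p["coordinate"] is None:
            ang = math.radians(float(p["angle_deg"]))
        else:
            ang = values[p["coordinate"]] + math.radians(float(p.get("offset_deg", 0.0)))
        pos = pos + float(p["length"]) * unit(ang)
    return pos


def _flexion_readout(topology: LinkageTopology, values: dict) -> dict:
    cfg = topology.config
    ref = topology.initial_state.values
    out = {}
    for joint, spec in cfg["flexion_readouts"].items():
        c = spec["coordinate"]
        out[joint] = math.degrees(ref[c] - values[c]) * float(spec.get("scale", 1.0))
    return out


def _solve_with_continuation(
    topology: LinkageTopology,
    driving: dict,
    guess: dict,
    prev_driving: dict,
    depth: int = 0,
) -> LagrangianState:
    """Solve one sweep step, bisecting the driving increment on failure.

    Coarse sweeps can step outside the Newton basin; halving the driving
    increment (up to 10 levels) restores the warm-start continuation without
    changing the requested sample points.
    """
    try:
        return solve_configuration(topology, driving, initial_guess=guess)
    except SolverError:
        if depth >= 10:
            raise
        mid = {d: 0.5 * (prev_driving[d] + driving[d]) for d in driving}
        mid_state = _solve_with_continuation(topology, mid, guess, prev_driving, depth + 1)
        return _solve_with_continuation(topology, driving, mid_state.values, mid, depth + 1)


def default_flexion_sweep(topology: LinkageTopology, n_steps: int = 40) -> list:
    """Linear driving-coordinate schedule from the initial state through the
    configured sweep amplitudes (list of {driver: radians} dicts)."""
    cfg = topology.config
    ref = topology.initial_state.values
    sweep = []
    for frac in np.linspace(0.0, 1.0, n_steps):
        sweep.append(
            {
                drv: ref[drv] + math.radians(float(cfg["sweep_deg"][drv])) * frac
                for drv in cfg["drivers"]
            }
        )
    return sweep


def fingertip_trajectory(
    topology: LinkageTopology,
    flexion_sweep: list | None = None,
    abduction_angle: float = 0.0,
    n_steps: int = 40,
) -> list:
    """Solve the planar closure along a flexion sweep and lift it to 3-D.

    Each step is solved warm-started from the previous solution (branch
    continuity); the planar pose is then rotated by ``abduction_angle`` about
    the lateral-swing axis -- the vertical line through the configured MCP
    flexion-platform origin, perpendicular to the palm plane -- to give 3-D
    fingertip positions.  Solver failures propagate with the step index.
    """
    if flexion_sweep is None:
        flexion_sweep = default_flexion_sweep(topology, n_steps=n_steps)
    axis_pt = np.asarray(topology.config.get("lateral_axis_point", [0.0, 0.0]), dtype=float)
    a = math.radians(abduction_angle)
    poses = []
    guess = topology.initial_state.values
    prev_driving = {d: guess[d] for d in flexion_sweep[0]}
    for k, driving in enumerate(flexion_sweep):
        try:
            state = _solve_with_continuation(topology, driving, guess, prev_driving)
        except SolverError as err:
            raise SolverError(f"sweep step {k}: {err}") from err
        prev_driving = driving
        guess = state.values
        xy = _fingertip_planar(topology, state.values)
        rel = xy[0] - axis_pt[0]
        tip3 = np.array([axis_pt[0] + rel * math.cos(a), xy[1], rel * math.sin(a)])
        poses.append(
            FingerPose(
                flexion_angles=_flexion_readout(topology, state.values),
                abduction_angle=float(abduction_angle),
                fingertip=tip3,
                state=state,
            )
        )
    return poses


def dof_summary(hand_config: list | None = None) -> dict:
    """Per-finger and total DOF counts for a hand of linkage fingers.

    Default: five fingers, each with a flexion DOF and a lateral
    (abduction-adduction) DOF -- ten DOFs in total.
    """
    if hand_config is None:
        hand_config = [
            {"name": n, "flexion": True, "lateral": True}
            for n in ("thumb", "index", "middle", "ring", "little")
        ]
    per_finger = {
        f["name"]: int(bool(f.get("flexion", True))) + int(bool(f.get("lateral", False)))
        for f in hand_config
    }
    return {"per_finger": per_finger, "total": sum(per_finger.values())}


def check_joint_limits(pose: FingerPose, limits: JointLimits | None = None) -> list:
    """Violations of inclusive joint-angle ranges; empty list means in range."""
    limits = limits or FOUR_FINGER_LIMITS
    angles = {
        "mcp_flexion": pose.flexion_angles.get("MCP"),
        "pip_flexion": pose.flexion_angles.get("PIP"),
        "dip_flexion": pose.flexion_angles.get("DIP"),
        "mcp_abduction": pose.abduction_angle,
    }
    out = []
    for motion, value in angles.items():
        if value is None or motion not in limits.ranges:
            continue
        lo, hi = limits.ranges[motion]
        if value < lo or value > hi:
            out.append({"motion": motion, "value": float(value), "range": (lo, hi)})
    return out


# ---------------------------------------------------------------------------
# Hinge-surrogate finger for alignment studies


def surrogate_fingertip_trajectory(
    flexion_fractions,
    joint_centers: dict | None = None,
    max_flexion_deg: dict | None = None,
    pivot_offsets: dict | None = None,
) -> np.ndarray:
    """Fingertip path of a three-hinge surrogate finger (n, 2) mm.

    The surrogate flexes MCP/PIP/DIP simultaneously through their assisted
    ranges (default 75/103/74 degrees) as ``flexion_fractions`` runs over
    [0, 1].  ``pivot_offsets`` displaces individual pivots (e.g. a misaligned
    exoskeleton center) while keeping the same angle schedule; with zero
    offsets this is the physiological reference trajectory.
    """
    centers = {
        "MCP": np.array([0.0, 0.0]),
        "PIP": np.array([45.0, 0.0]),
        "DIP": np.array([70.0, 0.0]),
        "TIP": np.array([90.0, 0.0]),
    }
    if joint_centers:
        for k, v in joint_centers.items():
            centers[k] = np.asarray(v, dtype=float)
    maxf = {"MCP": 75.0, "PIP": 103.0, "DIP": 74.0}
    if max_flexion_deg:
        maxf.update(max_flexion_deg)
    offsets = {"MCP": np.zeros(2), "PIP": np.zeros(2), "DIP": np.zeros(2)}
    if pivot_offsets:
        for k, v in pivot_offsets.items():
            offsets[k] = np.asarray(v, dtype=float)

    tips = []
    for frac in np.atleast_1d(np.asarray(flexion_fractions, dtype=float)):
        p_mcp = centers["MCP"] + offsets["MCP"]
        p_pip = centers["PIP"] + offsets["PIP"]
        p_dip = centers["DIP"] + offsets["DIP"]
        th1 = -math.radians(maxf["MCP"]) * frac
        th2 = -math.radians(maxf["PIP"]) * frac
        th3 = -math.radians(maxf["DIP"]) * frac
        R1, R2, R3 = rot(th1), rot(th2), rot(th3)
        v_tip = centers["TIP"] - centers["DIP"]
        v_mid = p_dip - p_pip
        v_prox = p_pip - p_mcp
        tip = p_mcp + R1 @ (v_prox + R2 @ (v_mid + R3 @ v_tip))
        tips.append(tip)
    return np.asarray(tips)
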