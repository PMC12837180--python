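"""Weighted least-squares inverse kinematics for the leg linkage.

Per frame, the solver finds the generalized coordinates q minimizing

    sum_i  w_i * || x_i_observed - x_i_model(q) ||^2

over the observed markers, with box bounds on the angle coordinates.
Frames after the first are warm-started from the previous solution; the
first frame is solved from a multi-start over a coarse angle grid.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .containers import JointAngleSeries, MarkerTrajectorySet
from .model import (ANGLE_COORDS, COORD_NAMES, DEFAULT_JOINT_LIMITS,
                    PITCH_OBSERVING_MARKERS, LegLinkageModel, PoseVector,
                    forward_kinematics, required_markers)

#: Convergence tolerances (see least_squares): step max-norm and
#: objective-change stopping criteria, and the iteration cap.
XTOL = 1e-10
FTOL = 1e-12
MAX_ITER = 200

_COORD_INDEX = {n: i for i, n in enumerate(COORD_NAMES)}


class IKError(ValueError):
    """Raised when a frame or trajectory cannot be solved."""


@dataclass
class IKResult:
    """Trajectory IK output, one entry per input frame.

    ``poses`` holds a PoseVector per frame (None for gap frames);
    ``objective`` is the weighted residual sum (m^2) at the solution;
    ``marker_residuals`` maps marker name -> per-frame residual distance
    (m, NaN for gaps); ``converged`` / ``valid`` flag solver success and
    marker availability.
    """

    poses: list
    objective: np.ndarray
    marker_residuals: dict
    converged: np.ndarray
    valid: np.ndarray
    frame_rate: float

    def __post_init__(self):
        if (self.objective[self.valid] < -1e-15).any():
            raise ValueError("objective values must be nonnegative")

    @property
    def n_frames(self) -> int:
        return len(self.poses)

    def angle_array(self, coord: str) -> np.ndarray:
        out = np.full(self.n_frames, np.nan)
        for i, p in enumerate(self.poses):
            if p is not None:
                out[i] = getattr(p, coord)
        return out

    def to_joint_angle_series(self, side: str = "right") -> JointAngleSeries:
        """Extract one side's hip/knee/ankle angles as a uniformly
        sampled series (gap frames are NaN)."""
        s = side[0]
        t = np.arange(self.n_frames) / self.frame_rate
        angles = {
            "hip_flexion": self.angle_array(f"hip_{s}"),
            "knee_flexion": self.angle_array(f"knee_{s}"),
            "ankle_dorsiflexion": self.angle_array(f"ankle_{s}"),
        }
        return JointAngleSeries(time=t, angles=angles, frame_rate=self.frame_rate, side=side)


def _limits_for(coord: str) -> tuple:
    if coord.startswith("pelvis_pitch"):
        return DEFAULT_JOINT_LIMITS["pelvis_pitch"]
    for joint in ("hip", "knee", "ankle"):
        if coord.startswith(joint):
            return DEFAULT_JOINT_LIMITS[joint]
    return (-100.0, 100.0)  # pelvis translation, meters


def _pack(q: PoseVector, free: tuple) -> np.ndarray:
    """Interface degrees/meters -> internal radians/meters."""
    x = []
    for name in free:
        v = getattr(q, name)
        x.append(math.radians(v) if name in ANGLE_COORDS else v)
    return np.array(x, dtype=float)


def _unpack(x: np.ndarray, free: tuple, base: PoseVector) -> PoseVector:
    kwargs = {}
    for name, v in zip(free, x):
        kwargs[name] = math.degrees(v) if name in ANGLE_COORDS else float(v)
    return base.replace(**kwargs)


def _bounds(free: tuple, joint_limits: bool):
    lo, hi = [], []
    for name in free:
        if name in ANGLE_COORDS and joint_limits:
            a, b = _limits_for(name)
            lo.append(math.radians(a))
            hi.append(math.radians(b))
        elif name in ANGLE_COORDS:
            lo.append(-np.inf)
            hi.append(np.inf)
        else:
            lo.append(-np.inf)
            hi.append(np.inf)
    return np.array(lo), np.array(hi)


def _default_free(model: LegLinkageModel) -> tuple:
    free = ["pelvis_x", "pelvis_y", "pelvis_z", "pelvis_pitch"]
    for side in model.sides:
        s = side[0]
        free += [f"hip_{s}", f"knee_{s}", f"ankle_{s}"]
    return tuple(free)


def solve_frame_ik(model: LegLinkageModel,
                   observed: dict,
                   weights: dict | None = None,
                   q_init: PoseVector | None = None,
                   free: tuple | None = None,
                   joint_limits: bool = True,
                   check_determined: bool = True):
    """Solve one frame of weighted least-squares IK.

    Parameters
    ----------
    observed : dict
        Marker name -> observed 3-D position (m). Must cover at least
        the minimum marker set for each configured side unless a reduced
        ``free`` coordinate set is supplied.
    weights : dict, optional
        Per-marker weights w_i >= 0; missing markers default to the
        model's weights (uniform 1 unless configured).
    q_init : PoseVector, optional
        Starting pose; fixed (non-free) coordinates are taken from it.
    free : tuple of str, optional
        Coordinate names to optimize (default: pelvis + all configured
        sides).

    Returns
    -------
    (PoseVector, float)
        The solution and the objective value sum_i w_i ||d_i||^2 at it.
    """
    free = tuple(free) if free is not None else _default_free(model)
    q_init = q_init or PoseVector()
    w = {}
    for name in observed:
        wi = weights.get(name, model.weight(name)) if weights else model.weight(name)
        if wi < 0:
            raise IKError(f"marker weight for {name!r} must be nonnegative")
        if wi > 0:
            w[name] = wi
    # Pelvis pitch is a gauge freedom unless a pitch-observing marker is
    # present: hold it fixed at q_init in that case.
    if "pelvis_pitch" in free and not any(m in w for m in PITCH_OBSERVING_MARKERS):
        free = tuple(n for n in free if n != "pelvis_pitch")
    if check_determined:
        for side in model.sides:
            missing = [m for m in required_markers(side) if m not in w]
            if missing:
                raise IKError(
                    f"under-determined marker set: side {side!r} missing {missing}"
                )
    if 3 * len(w) < len(free):
        raise IKError(
            f"under-determined: {len(w)} weighted markers give {3 * len(w)} "
            f"residual components for {len(free)} free coordinates"
        )

    names = sorted(w)
    sqw = np.array([math.sqrt(w[n]) for n in names])
    obs = np.array([observed[n] for n in names], dtype=float)

    def residuals(x):
        q = _unpack(x, free, q_init)
        pred = forward_kinematics(model, q)
        d = obs - np.array([pred[n] for n in names])
        return (d * sqw[:, None]).ravel()

    x0 = _pack(q_init, free)
    lo, hi = _bounds(free, joint_limits)
    x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)
    sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                        xtol=XTOL, ftol=FTOL, gtol=None, max_nfev=MAX_ITER * (len(free) + 1))
    q = _unpack(sol.x, free, q_init)
    objective = float(np.sum(sol.fun ** 2))
    return q, objective


def _multistart_grid():
    for hip in (-20.0, 10.0, 40.0):
        for knee in (5.0, 35.0, 70.0):
            yield hip, knee


def _initial_pose(model: LegLinkageModel, observed: dict) -> PoseVector:
    pelvis = observed.get("pelvis")
    if pelvis is None:
        hips = [observed[m] for m in observed if m.startswith("hip_")]
        pelvis = np.mean(hips, axis=0) if hips else np.zeros(3)
    return PoseVector(pelvis_x=float(pelvis[0]), pelvis_y=float(pelvis[1]),
                      pelvis_z=float(pelvis[2]))


def solve_first_frame(model: LegLinkageModel, observed: dict,
                      weights: dict | None = None, free: tuple | None = None,
                      joint_limits: bool = True):
    """Multi-start IK over a coarse hip/knee angle grid for the first
    frame of a trajectory (no warm start available)."""
    base = _initial_pose(model, observed)
    best = None
    for hip, knee in _multistart_grid():
        kwargs = {}
        for side in model.sides:
            s = side[0]
            kwargs[f"hip_{s}"] = hip
            kwargs[f"knee_{s}"] = knee
        q0 = base.replace(**kwargs)
        q, obj = solve_frame_ik(model, observed, weights=weights, q_init=q0,
                                free=free, joint_limits=joint_limits)
        if best is None or obj < best[1]:
            best = (q, obj)
    return best


def solve_trajectory_ik(model: LegLinkageModel,
                        markers: MarkerTrajectorySet,
                        weights: dict | None = None,
                        joint_limits: bool = True) -> IKResult:
    """Solve IK for every frame of a marker trajectory set.

    Frame t > 0 is warm-started from the frame t-1 solution; frames
    missing any required marker yield a gap flag (NaN pose) rather than
    a fabricated pose.
    """
    req = set()
    for side in model.sides:
        req.update(required_markers(side))
    missing_names = req - set(markers.names)
    if missing_names:
        raise IKError(f"marker set lacks required markers: {sorted(missing_names)}")

    n = markers.n_frames
    poses = [None] * n
    objective = np.full(n, np.nan)
    converged = np.zeros(n, dtype=bool)
    valid = np.zeros(n, dtype=bool)
    residual_by_marker = {m: np.full(n, np.nan) for m in markers.names}

    req_idx = [markers.index(m) for m in sorted(req)]
    frame_ok = markers.valid[:, req_idx].all(axis=1)
    if not frame_ok.any():
        raise IKError("no solvable frames: every frame is missing required markers")

    prev = None
    for i in range(n):
        if not frame_ok[i]:
            continue
        observed = markers.frame(i)
        try:
            if prev is None:
                q, obj = solve_first_frame(model, observed, weights=weights,
                                           joint_limits=joint_limits)
            else:
                q, obj = solve_frame_ik(model, observed, weights=weights,
                                        q_init=prev, joint_limits=joint_limits)
        except IKError:
            continue
        poses[i] = q
        objective[i] = obj
        converged[i] = True
        valid[i] = True
        pred = forward_kinematics(model, q)
        for m in observed:
            residual_by_marker[m][i] = float(np.linalg.norm(observed[m] - pred[m]))
        prev = q

    if not valid.any():
        raise IKError("no solvable frames")
    return IKResult(poses=poses, objective=objective,
                    marker_residuals=residual_by_marker, converged=converged,
                    valid=valid, frame_rate=markers.frame_rate)
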