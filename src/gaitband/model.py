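"""Simplified parametric leg linkage and forward kinematics.

The linkage is a planar (sagittal) walker: a pelvis free to translate in
3-D and pitch about the mediolateral axis, carrying one hinged leg per
side (hip flexion, knee flexion, ankle dorsiflexion).  Legs sit at a
fixed half-pelvis-width offset in Z, which gives a realistic step width
while keeping the kinematics sagittal.  All sagittal rotations are about
the Z (rightward) axis; at the zero pose the leg hangs straight down and
the foot points forward.

This is a deliberately simplified linkage — segment lengths scale
linearly with subject height from a reference anthropometry — not a full
musculoskeletal model.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import SIDES

# Reference anthropometry as fractions of body height (standard
# segment-proportion tables used in gait biomechanics).
REFERENCE_HEIGHT_M = 1.70
_THIGH_FRAC = 0.245
_SHANK_FRAC = 0.246
_FOOT_FRAC = 0.152
_SOLE_DROP_FRAC = 0.039
_PELVIS_HALF_WIDTH_FRAC = 0.030

#: Free generalized coordinates, fixed order. Pelvis position in meters,
#: all angles in degrees at the interface.
COORD_NAMES = (
    "pelvis_x", "pelvis_y", "pelvis_z", "pelvis_pitch",
    "hip_r", "knee_r", "ankle_r",
    "hip_l", "knee_l", "ankle_l",
)
ANGLE_COORDS = COORD_NAMES[3:]

#: Default box bounds for angle coordinates, degrees.
DEFAULT_JOINT_LIMITS = {
    "pelvis_pitch": (-45.0, 45.0),
    "hip": (-30.0, 140.0),
    "knee": (0.0, 150.0),
    "ankle": (-50.0, 40.0),
}

MARKER_NAMES = (
    "pelvis", "sacrum", "torso",
    "hip_r", "knee_r", "ankle_r", "heel_r", "toe_r",
    "hip_l", "knee_l", "ankle_l", "heel_l", "toe_l",
)

#: Markers whose position depends on pelvis pitch. The pelvis origin and
#: the (purely mediolateral) hip offsets are invariant under a sagittal
#: pitch rotation, so without one of these the pitch coordinate is a
#: gauge freedom and must be held fixed.
PITCH_OBSERVING_MARKERS = ("sacrum", "torso")

#: Minimum marker set required to determine one side's pose.
def required_markers(side: str) -> tuple:
    s = side[0]
    return ("pelvis", f"hip_{s}", f"knee_{s}", f"ankle_{s}", f"heel_{s}", f"toe_{s}")


@dataclass(frozen=True)
class LegLinkageModel:
    """Segment lengths (m), virtual-marker placements and marker weights.

    ``height`` is the subject stature the segment lengths correspond to.
    ``marker_weights`` are the nonnegative per-marker weights ``w_i`` of
    the IK objective; uniform by default.
    """

    height: float = REFERENCE_HEIGHT_M
    pelvis_half_width: float = REFERENCE_HEIGHT_M * _PELVIS_HALF_WIDTH_FRAC
    thigh: float = REFERENCE_HEIGHT_M * _THIGH_FRAC
    shank: float = REFERENCE_HEIGHT_M * _SHANK_FRAC
    foot: float = REFERENCE_HEIGHT_M * _FOOT_FRAC
    heel_back: float = REFERENCE_HEIGHT_M * _FOOT_FRAC * 0.25
    sole_drop: float = REFERENCE_HEIGHT_M * _SOLE_DROP_FRAC
    sacrum_back: float = REFERENCE_HEIGHT_M * 0.05
    torso_up: float = REFERENCE_HEIGHT_M * 0.20
    sides: tuple = SIDES
    marker_weights: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("height", "pelvis_half_width", "thigh", "shank", "foot",
                     "heel_back", "sole_drop", "sacrum_back", "torso_up"):
            if getattr(self, name) <= 0:
                raise ValueError(f"segment parameter {name!r} must be > 0")
        for m, w in self.marker_weights.items():
            if w < 0:
                raise ValueError(f"marker weight for {m!r} must be >= 0")

    @property
    def leg_length(self) -> float:
        return self.thigh + self.shank + self.sole_drop

    def weight(self, marker: str) -> float:
        return float(self.marker_weights.get(marker, 1.0))

    def marker_names(self) -> tuple:
        names = ["pelvis", "sacrum", "torso"]
        for side in self.sides:
            s = side[0]
            names += [f"hip_{s}", f"knee_{s}", f"ankle_{s}", f"heel_{s}", f"toe_{s}"]
        return tuple(names)

    def virtual_markers(self) -> dict:
        """Marker name -> (segment name, offset in the segment frame).

        Segment frames: origin at the parent joint center, axes aligned
        with the world at the zero pose; the segment's sagittal rotation
        carries the offset.
        """
        out = {
            "pelvis": ("pelvis", np.zeros(3)),
            "sacrum": ("pelvis", np.array([-self.sacrum_back, 0.0, 0.0])),
            "torso": ("pelvis", np.array([0.0, self.torso_up, 0.0])),
        }
        for side in self.sides:
            s = side[0]
            zsign = 1.0 if side == "right" else -1.0
            w = zsign * self.pelvis_half_width
            out[f"hip_{s}"] = ("pelvis", np.array([0.0, 0.0, w]))
            out[f"knee_{s}"] = (f"thigh_{s}", np.array([0.0, -self.thigh, 0.0]))
            out[f"ankle_{s}"] = (f"shank_{s}", np.array([0.0, -self.shank, 0.0]))
            out[f"heel_{s}"] = (f"foot_{s}", np.array([-self.heel_back, -self.sole_drop, 0.0]))
            out[f"toe_{s}"] = (
                f"foot_{s}",
                np.array([self.foot - self.heel_back, -self.sole_drop, 0.0]),
            )
        return out


def scale_model(reference: LegLinkageModel, height: float,
                segment_overrides: dict | None = None) -> LegLinkageModel:
    """Scale a reference linkage to a subject's stature.

    Every segment length is multiplied by ``height / reference.height``
    unless a measured length is supplied in ``segment_overrides``
    (keys among pelvis_half_width, thigh, shank, foot, heel_back,
    sole_drop). Marker offsets scale with their segment by construction.
    """
    if height <= 0:
        raise ValueError(f"height must be > 0, got {height}")
    ratio = height / reference.height
    fields_ = {
        "pelvis_half_width": reference.pelvis_half_width * ratio,
        "thigh": reference.thigh * ratio,
        "shank": reference.shank * ratio,
        "foot": reference.foot * ratio,
        "heel_back": reference.heel_back * ratio,
        "sole_drop": reference.sole_drop * ratio,
        "sacrum_back": reference.sacrum_back * ratio,
        "torso_up": reference.torso_up * ratio,
    }
    for key, val in (segment_overrides or {}).items():
        if key not in fields_:
            raise ValueError(f"unknown segment override {key!r} (valid: {sorted(fields_)})")
        if val <= 0:
            raise ValueError(f"segment override {key!r} must be > 0, got {val}")
        fields_[key] = float(val)
    return replace(reference, height=float(height), **fields_)


def default_model(height: float = REFERENCE_HEIGHT_M) -> LegLinkageModel:
    """Reference-proportioned linkage scaled to ``height``."""
    return scale_model(LegLinkageModel(), height)


@dataclass
class PoseVector:
    """Generalized coordinates: pelvis position (m), pitch and joint
    angles (deg, flexion/dorsiflexion positive)."""

    pelvis_x: float = 0.0
    pelvis_y: float = 0.0
    pelvis_z: float = 0.0
    pelvis_pitch: float = 0.0
    hip_r: float = 0.0
    knee_r: float = 0.0
    ankle_r: float = 0.0
    hip_l: float = 0.0
    knee_l: float = 0.0
    ankle_l: float = 0.0

    def __post_init__(self):
        if not all(math.isfinite(getattr(self, n)) for n in COORD_NAMES):
            raise ValueError("all pose coordinates must be finite")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in COORD_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "PoseVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(COORD_NAMES),):
            raise ValueError(f"expected {len(COORD_NAMES)} coordinates, got {arr.shape}")
        return cls(**dict(zip(COORD_NAMES, arr)))

    def replace(self, **kwargs) -> "PoseVector":
        return replace(self, **kwargs)


def _sagittal_dirs(angle_rad: np.ndarray):
    """Down-pointing and forward-pointing unit vectors of a segment
    rotated by ``angle_rad`` about +Z (flexion carries the distal end
    forward)."""
    s, c = np.sin(angle_rad), np.cos(angle_rad)
    down = np.stack([s, -c, np.zeros_like(s)], axis=-1)
    fwd = np.stack([c, s, np.zeros_like(s)], axis=-1)
    return down, fwd


def forward_kinematics(model: LegLinkageModel, q: PoseVector) -> dict:
    """Map a pose to world positions of every virtual marker.

    Chained rigid transforms pelvis -> thigh -> shank -> foot. Returns
    ``{marker name: ndarray (3,)}`` in meters.
    """
    pelvis = np.array([q.pelvis_x, q.pelvis_y, q.pelvis_z])
    pitch = math.radians(q.pelvis_pitch)
    pelvis_down, pelvis_fwd = _sagittal_dirs(np.array(pitch))
    out = {"pelvis": pelvis,
           "sacrum": pelvis - model.sacrum_back * pelvis_fwd,
           "torso": pelvis - model.torso_up * pelvis_down}
    for side in model.sides:
        s = side[0]
        zsign = 1.0 if side == "right" else -1.0
        hip_a = math.radians(getattr(q, f"hip_{s}"))
        knee_a = math.radians(getattr(q, f"knee_{s}"))
        ankle_a = math.radians(getattr(q, f"ankle_{s}"))

        hip = pelvis + np.array([0.0, 0.0, zsign * model.pelvis_half_width])
        th_ang = pitch + hip_a
        sh_ang = th_ang - knee_a          # knee flexion folds the shank backward
        ft_ang = sh_ang + ankle_a         # dorsiflexion rotates the toes up

        th_down, _ = _sagittal_dirs(np.array(th_ang))
        sh_down, _ = _sagittal_dirs(np.array(sh_ang))
        ft_down, ft_fwd = _sagittal_dirs(np.array(ft_ang))

        knee = hip + model.thigh * th_down
        ankle = knee + model.shank * sh_down
        sole = ankle + model.sole_drop * ft_down
        heel = sole - model.heel_back * ft_fwd
        toe = sole + (model.foot - model.heel_back) * ft_fwd

        out[f"hip_{s}"] = hip
        out[f"knee_{s}"] = knee
        out[f"ankle_{s}"] = ankle
        out[f"heel_{s}"] = heel
        out[f"toe_{s}"] = toe
    return out


def forward_kinematics_batch(model: LegLinkageModel, q_arrays: dict) -> dict:
    """Vectorized forward kinematics over frames.

    ``q_arrays`` maps coordinate names (COORD_NAMES) to arrays of length
    n_frames; returns ``{marker: ndarray (n_frames, 3)}``.
    """
    n = len(next(iter(q_arrays.values())))
    get = lambda k: np.broadcast_to(np.asarray(q_arrays.get(k, 0.0), dtype=float), (n,))
    pelvis = np.stack([get("pelvis_x"), get("pelvis_y"), get("pelvis_z")], axis=-1)
    pitch = np.radians(get("pelvis_pitch"))
    pelvis_down, pelvis_fwd = _sagittal_dirs(pitch)
    out = {"pelvis": pelvis,
           "sacrum": pelvis - model.sacrum_back * pelvis_fwd,
           "torso": pelvis - model.torso_up * pelvis_down}
    for side in model.sides:
        s = side[0]
        zsign = 1.0 if side == "right" else -1.0
        th_ang = pitch + np.radians(get(f"hip_{s}"))
        sh_ang = th_ang - np.radians(get(f"knee_{s}"))
        ft_ang = sh_ang + np.radians(get(f"ankle_{s}"))
        hip = pelvis + np.array([0.0, 0.0, zsign * model.pelvis_half_width])
        th_down, _ = _sagittal_dirs(th_ang)
        sh_down, _ = _sagittal_dirs(sh_ang)
        ft_down, ft_fwd = _sagittal_dirs(ft_ang)
        knee = hip + model.thigh * th_down
        ankle = knee + model.shank * sh_down
        sole = ankle + model.sole_drop * ft_down
        out[f"hip_{s}"] = hip
        out[f"knee_{s}"] = knee
        out[f"ankle_{s}"] = ankle
        out[f"heel_{s}"] = sole - model.heel_back * ft_fwd
        out[f"toe_{s}"] = sole + (model.foot - model.heel_back) * ft_fwd
    return out
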