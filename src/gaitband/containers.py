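"""Shared in-memory containers for marker and joint-angle data.

Coordinate convention throughout the package: X forward (walking
direction), Y up, Z rightward; right-handed; positions in meters,
angles in degrees at every public interface.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

JOINTS = ("hip_flexion", "knee_flexion", "ankle_dorsiflexion")
SIDES = ("right", "left")


@dataclass
class MarkerTrajectorySet:
    """Timestamped 3-D positions of named joint centers / markers.

    Attributes
    ----------
    frame_rate : float
        Sampling rate in Hz (> 0).
    names : list of str
        Marker names, one per column of ``positions``.
    positions : ndarray, shape (n_frames, n_markers, 3)
        Positions in meters.
    valid : ndarray of bool, shape (n_frames, n_markers)
        Validity mask; False marks occluded / missing samples.
    """

    frame_rate: float
    names: list
    positions: np.ndarray
    valid: np.ndarray = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError(
                f"positions must have shape (n_frames, n_markers, 3), got {self.positions.shape}"
            )
        if self.positions.shape[1] != len(self.names):
            raise ValueError("number of markers does not match number of names")
        if self.valid is None:
            self.valid = np.ones(self.positions.shape[:2], dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.positions.shape[:2]:
                raise ValueError("valid mask shape does not match positions")
        if not np.isfinite(self.positions[self.valid]).all():
            raise ValueError("positions must be finite wherever the mask is true")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"marker {name!r} not present (have {self.names})") from None

    def marker(self, name: str) -> np.ndarray:
        """Return the (n_frames, 3) trajectory of one marker."""
        return self.positions[:, self.index(name), :]

    def marker_valid(self, name: str) -> np.ndarray:
        return self.valid[:, self.index(name)]

    def frame(self, i: int, only_valid: bool = True) -> dict:
        """Return ``{name: position}`` for frame *i* (valid markers only)."""
        out = {}
        for j, name in enumerate(self.names):
            if not only_valid or self.valid[i, j]:
                out[name] = self.positions[i, j]
        return out


@dataclass
class JointAngleSeries:
    """Uniformly sampled joint-angle time series for one side, in degrees."""

    time: np.ndarray
    angles: dict  # joint name -> ndarray (n,)
    frame_rate: float
    side: str = "right"

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or len(self.time) < 2:
            raise ValueError("time must be a 1-D array with at least 2 samples")
        dt = np.diff(self.time)
        if (dt <= 0).any():
            raise ValueError("time must be strictly increasing")
        if np.abs(dt - 1.0 / self.frame_rate).max() > 1e-6:
            raise ValueError("time must be uniformly sampled at the stated frame rate")
        self.angles = {k: np.asarray(v, dtype=float) for k, v in self.angles.items()}
        for k, v in self.angles.items():
            if v.shape != self.time.shape:
                raise ValueError(f"angle array {k!r} does not match time length")

    @property
    def joints(self):
        return list(self.angles)


@dataclass
class GaitEvents:
    """Heel-strike and toe-off times (s) per side.

    Within each side heel-strikes are strictly increasing and exactly one
    toe-off falls between consecutive heel-strikes.
    """

    heel_strikes: dict  # side -> ndarray of times (s)
    toe_offs: dict      # side -> ndarray of times (s)

    def __post_init__(self):
        self.heel_strikes = {s: np.asarray(v, dtype=float) for s, v in self.heel_strikes.items()}
        self.toe_offs = {s: np.asarray(v, dtype=float) for s, v in self.toe_offs.items()}
        for side, hs in self.heel_strikes.items():
            if len(hs) > 1 and (np.diff(hs) <= 0).any():
                raise ValueError(f"heel-strikes on side {side!r} must be strictly increasing")
            to = self.toe_offs.get(side, np.empty(0))
            for a, b in zip(hs[:-1], hs[1:]):
                n_inside = int(((to > a) & (to < b)).sum())
                if n_inside != 1:
                    raise ValueError(
                        f"expected exactly one toe-off between heel-strikes "
                        f"{a:.3f}s and {b:.3f}s on side {side!r}, found {n_inside}"
                    )

    @property
    def sides(self):
        return list(self.heel_strikes)


@dataclass
class NormalizedCycle:
    """A gait cycle time-normalized to stations 0..100% (101 samples).

    Station 0 corresponds to heel-strike of the cycle's side.
    """

    angles: dict  # joint -> ndarray (n_stations,)
    side: str = "right"
    cycle_id: str = "cycle0"
    n_stations: int = 101

    def __post_init__(self):
        self.angles = {k: np.asarray(v, dtype=float) for k, v in self.angles.items()}
        for k, v in self.angles.items():
            if v.ndim != 1 or len(v) != self.n_stations:
                raise ValueError(
                    f"joint {k!r}: expected {self.n_stations} stations, got {v.shape}"
                )

    @property
    def stations(self) -> np.ndarray:
        """Stations in % gait cycle: 0, 1, ..., 100 for the default 101."""
        return np.linspace(0.0, 100.0, self.n_stations)

    @property
    def joints(self):
        return list(self.angles)

    def copy(self) -> "NormalizedCycle":
        return replace(self, angles={k: v.copy() for k, v in self.angles.items()})
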