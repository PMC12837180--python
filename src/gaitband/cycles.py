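"""Joint-angle filtering, gait-event detection, cycle extraction, QC,
time normalization and peak metrics.

Filtering is zero-phase (forward-backward) so that peak-timing metrics
carry no phase lag.  Gait events are detected with the coordinate-based
method: heel-strike at local maxima of the heel marker's forward
position relative to the pelvis, toe-off at local minima of the toe
marker's relative forward position.  Cycles span consecutive same-side
heel-strikes and are normalized to 101 stations (0, 1, ..., 100 % of
the gait cycle).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .containers import GaitEvents, JointAngleSeries, MarkerTrajectorySet, NormalizedCycle

#: Angle plausibility bounds (deg) used by cycle QC.
DEFAULT_QC_BOUNDS = {
    "hip_flexion": (-40.0, 150.0),
    "knee_flexion": (-10.0, 160.0),
    "ankle_dorsiflexion": (-60.0, 50.0),
}
#: Maximum physiological frame-to-frame jump, deg per frame at 60 Hz.
DEFAULT_MAX_JUMP_DEG = 15.0


class EventDetectionError(ValueError):
    """Raised when no analyzable gait cycle can be found."""


def lowpass_filter(series: JointAngleSeries, cutoff: float = 6.0,
                   order: int = 4) -> JointAngleSeries:
    """Zero-phase Butterworth low-pass filter of every joint channel.

    The filter of the given order is applied forward and backward
    (reflection-padded), so the passband-edge amplitude gain is the
    square of the single-pass gain (0.5 at the cutoff) and the phase
    response is identically zero.
    """
    nyquist = series.frame_rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below the Nyquist frequency {nyquist} Hz"
        )
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    b, a = butter(order, cutoff / nyquist)
    filtered = {j: filtfilt(b, a, v) for j, v in series.angles.items()}
    return JointAngleSeries(time=series.time.copy(), angles=filtered,
                            frame_rate=series.frame_rate, side=series.side)


def _walking_direction(pelvis: np.ndarray) -> np.ndarray:
    """Unit forward direction from net pelvis displacement (auto-detects
    reversed walking direction)."""
    disp = pelvis[-1] - pelvis[0]
    disp[1] = 0.0  # horizontal progression only
    norm = np.linalg.norm(disp)
    if norm < 1e-9:
        raise EventDetectionError("no analyzable gait cycle: pelvis does not progress")
    return disp / norm


def detect_gait_events(markers: MarkerTrajectorySet,
                       min_stride_s: float = 0.4,
                       min_progression_m: float = 0.2) -> GaitEvents:
    """Coordinate-based gait-event detection from heel/toe markers.

    Heel-strike: local maximum of heel position along the walking
    direction, relative to the pelvis.  Toe-off: local minimum of the
    toe's relative forward position, searched within each same-side
    stride so that exactly one toe-off falls between consecutive
    heel-strikes.
    """
    try:
        pelvis = markers.marker("pelvis")
    except KeyError:
        raise EventDetectionError("event detection requires a pelvis marker") from None
    disp = np.linalg.norm((pelvis[-1] - pelvis[0]) * np.array([1.0, 0.0, 1.0]))
    if disp < min_progression_m:
        raise EventDetectionError(
            "no analyzable gait cycle: insufficient forward progression "
            f"({disp:.3f} m)"
        )
    fwd = _walking_direction(pelvis)
    t = markers.time
    sides = [s for s in ("right", "left") if f"heel_{s[0]}" in markers.names]
    if not sides:
        raise EventDetectionError("event detection requires heel markers")

    hs, to = {}, {}
    for side in sides:
        s = side[0]
        heel_rel = (markers.marker(f"heel_{s}") - pelvis) @ fwd
        toe_rel = (markers.marker(f"toe_{s}") - pelvis) @ fwd
        span = float(np.ptp(heel_rel))
        if span < 0.05:
            raise EventDetectionError(
                f"no analyzable gait cycle: heel excursion too small on side {side!r}"
            )
        distance = max(1, int(round(min_stride_s * markers.frame_rate)))
        peaks, _ = find_peaks(heel_rel, distance=distance, prominence=0.25 * span)
        if len(peaks) < 2:
            raise EventDetectionError(
                f"no analyzable gait cycle: fewer than 2 heel-strikes on side {side!r}"
            )
        hs[side] = t[peaks]
        offs = []
        for a, b in zip(peaks[:-1], peaks[1:]):
            seg = toe_rel[a + 1:b]
            offs.append(t[a + 1 + int(np.argmin(seg))])
        to[side] = np.array(offs)
    return GaitEvents(heel_strikes=hs, toe_offs=to)


@dataclass
class RawCycle:
    """One stride of a joint-angle series, heel-strike to next same-side
    heel-strike (start inclusive, end exclusive; the end frame is kept
    for interpolation of station 100%)."""

    time: np.ndarray
    angles: dict
    side: str
    cycle_id: str
    start_time: float
    end_time: float

    @property
    def n_frames(self) -> int:
        return len(self.time)


def extract_cycles(series: JointAngleSeries, events: GaitEvents,
                   side: str | None = None) -> list:
    """Slice a joint-angle series into strides between consecutive
    same-side heel-strikes."""
    side = side or series.side
    hs = events.heel_strikes.get(side)
    if hs is None or len(hs) < 2:
        raise EventDetectionError(
            f"need at least 2 heel-strikes on side {side!r} to extract a cycle"
        )
    cycles = []
    for k, (a, b) in enumerate(zip(hs[:-1], hs[1:])):
        i0 = int(np.searchsorted(series.time, a - 1e-9))
        i1 = int(np.searchsorted(series.time, b + 1e-9))  # exclusive
        sl = slice(i0, min(i1, len(series.time)))
        cycles.append(RawCycle(
            time=series.time[sl].copy(),
            angles={j: v[sl].copy() for j, v in series.angles.items()},
            side=side, cycle_id=f"{side}_{k}", start_time=float(a), end_time=float(b),
        ))
    return cycles


@dataclass
class CycleQCReport:
    """Pass/fail screen for one gait cycle; ``passed`` is true iff
    ``reasons`` is empty."""

    passed: bool
    reasons: list = field(default_factory=list)
    max_jump_deg: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must be true exactly when reasons is empty")


def qc_cycle(cycle: RawCycle,
             markers: MarkerTrajectorySet | None = None,
             required: tuple = (),
             bounds: dict | None = None,
             max_jump_deg: float = DEFAULT_MAX_JUMP_DEG,
             frame_rate: float | None = None) -> CycleQCReport:
    """Screen one cycle for tracking gaps, implausible angles and
    discontinuities.

    ``max_jump_deg`` is referenced to 60 Hz sampling and rescaled to the
    cycle's actual frame rate.  If ``markers`` is given, the validity
    mask of the ``required`` markers is checked over the cycle's span.
    """
    bounds = bounds or DEFAULT_QC_BOUNDS
    reasons = []
    if markers is not None:
        tm = markers.time
        in_span = (tm >= cycle.start_time - 1e-9) & (tm <= cycle.end_time + 1e-9)
        names = required or tuple(markers.names)
        for name in names:
            if name in markers.names and not markers.marker_valid(name)[in_span].all():
                reasons.append("gap detected")
                break
    if len(cycle.time) > 1:
        fr = frame_rate or 1.0 / np.median(np.diff(cycle.time))
    else:
        fr = frame_rate or 60.0
    jump_limit = max_jump_deg * (60.0 / fr)
    max_jumps = {}
    for joint, v in cycle.angles.items():
        finite = np.isfinite(v)
        if not finite.all():
            if "gap detected" not in reasons:
                reasons.append("gap detected")
            v = v[finite]
            if v.size == 0:
                max_jumps[joint] = np.nan
                continue
        lo, hi = bounds.get(joint, (-np.inf, np.inf))
        if (v < lo).any() or (v > hi).any():
            if "implausible angle" not in reasons:
                reasons.append("implausible angle")
        jump = float(np.max(np.abs(np.diff(v)))) if v.size > 1 else 0.0
        max_jumps[joint] = jump
        if jump > jump_limit and "discontinuity" not in reasons:
            reasons.append("discontinuity")
    return CycleQCReport(passed=not reasons, reasons=reasons, max_jump_deg=max_jumps)


def time_normalize(cycle, n_points: int = 101) -> NormalizedCycle:
    """Linearly interpolate a cycle onto ``n_points`` evenly spaced
    stations from 0% to 100% of the stride; endpoints are preserved
    exactly.  Accepts a RawCycle or an already-normalized cycle (on
    which the operation is idempotent)."""
    if isinstance(cycle, NormalizedCycle):
        src_t = cycle.stations
        angles = cycle.angles
        side, cycle_id = cycle.side, cycle.cycle_id
    else:
        if cycle.n_frames < 4:
            raise ValueError(
                f"cycle too short to normalize: {cycle.n_frames} frames (need >= 4)"
            )
        src_t = (cycle.time - cycle.time[0]) / (cycle.time[-1] - cycle.time[0]) * 100.0
        angles = cycle.angles
        side, cycle_id = cycle.side, cycle.cycle_id
    stations = np.linspace(0.0, 100.0, n_points)
    out = {j: np.interp(stations, src_t, v) for j, v in angles.items()}
    return NormalizedCycle(angles=out, side=side, cycle_id=cycle_id, n_stations=n_points)


@dataclass
class PeakMetrics:
    """Per-joint peak (max), minimum, range of motion and timing of the
    global maximum in % cycle (ties break to the earliest station)."""

    peak: dict
    minimum: dict
    rom: dict
    peak_timing: dict

    def __post_init__(self):
        for j in self.rom:
            if self.rom[j] < 0:
                raise ValueError("ROM must be nonnegative")
            if not (0.0 <= self.peak_timing[j] <= 100.0):
                raise ValueError("peak timing must lie in [0, 100] %")


def peak_metrics(cycle: NormalizedCycle) -> PeakMetrics:
    """Peak flexion, minimum, ROM and peak timing per joint."""
    stations = cycle.stations
    peak, minimum, rom, timing = {}, {}, {}, {}
    for j, v in cycle.angles.items():
        peak[j] = float(v.max())
        minimum[j] = float(v.min())
        rom[j] = peak[j] - minimum[j]
        timing[j] = float(stations[int(np.argmax(v))])  # argmax -> earliest tie
    return PeakMetrics(peak=peak, minimum=minimum, rom=rom, peak_timing=timing)


def representative_cycle(cycles: list) -> NormalizedCycle:
    """The cycle minimizing mean RMS distance to the pointwise mean of
    all given normalized cycles (the 'representative' stride)."""
    if not cycles:
        raise ValueError("no cycles to choose from")
    if len(cycles) == 1:
        return cycles[0]
    joints = cycles[0].joints
    mean = {j: np.mean([c.angles[j] for c in cycles], axis=0) for j in joints}
    best, best_d = None, np.inf
    for c in cycles:
        d = np.mean([np.sqrt(np.mean((c.angles[j] - mean[j]) ** 2)) for j in joints])
        if d < best_d:
            best, best_d = c, d
    return best
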