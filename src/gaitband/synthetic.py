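"""Ground-truthed synthetic walking trials and normative cohorts.

Joint-angle waveforms are built from sums of wrapped Gaussian bumps on
the 0-100% gait-cycle circle: smooth, exactly periodic, and with
landmarks (peak amplitude, peak timing, width) exposed as parameters.
Trials are produced by driving the leg linkage's forward kinematics
with the time-varying template angles while the pelvis advances at the
configured speed, then adding isotropic Gaussian marker noise.

The default templates are synthetic stand-ins with physiologic sagittal
landmarks (swing-phase hip and knee flexion peaks, a push-off
plantarflexion trough); they are not measured normative data.  The
cycle phase is anchored so that 0% coincides with the heel-forward
extremum the event detector defines as heel-strike.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .containers import JOINTS, SIDES, GaitEvents, MarkerTrajectorySet, NormalizedCycle
from .model import LegLinkageModel, default_model, forward_kinematics_batch

DEVIATION_MODES = ("scale_peak", "offset", "delay_peak")

#: Smooth transition margin at deviation-window edges, % gait cycle.
DEVIATION_EDGE_MARGIN = 2.0


@dataclass(frozen=True)
class GaussianBump:
    """One wrapped Gaussian component: amplitude (deg), center and width
    (% gait cycle)."""

    amplitude: float
    center: float
    width: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError(f"bump width must be > 0, got {self.width}")


@dataclass(frozen=True)
class DeviationSpec:
    """A parameterized gait deficit applied inside a cycle window.

    Modes
    -----
    scale_peak : scale the excursion above the window baseline by
        ``magnitude`` (0.6 blunts a peak to 60%).
    offset : add ``magnitude`` degrees inside the window.
    delay_peak : shift the waveform later by ``magnitude`` % cycle
        inside the window.
    """

    joint: str
    window: tuple
    mode: str
    magnitude: float

    def __post_init__(self):
        if self.mode not in DEVIATION_MODES:
            raise ValueError(
                f"unknown deviation mode {self.mode!r}; valid modes: {DEVIATION_MODES}"
            )
        start, end = self.window
        if not (0 <= start < end <= 100):
            raise ValueError(f"deviation window must satisfy 0 <= start < end <= 100, got {self.window}")
        if self.mode == "scale_peak" and self.magnitude < 0:
            raise ValueError("scale_peak magnitude must be >= 0")


@dataclass(frozen=True)
class _AppliedDeviation:
    spec: DeviationSpec
    baseline: float  # window baseline frozen at application time (scale_peak)


def _window_weight(t, start, end, margin):
    """1 everywhere inside [start, end], smoothstep down to 0 over
    ``margin`` % of cycle just outside each edge, computed on the
    0-100 circle so windows touching 100% stay periodic."""
    tw = np.mod(np.asarray(t, dtype=float), 100.0)
    inside = (tw >= start) & (tw <= end)

    def cdist(a, b):
        d = np.abs(a - b)
        return np.minimum(d, 100.0 - d)

    d = np.minimum(cdist(tw, start), cdist(tw, end))
    d = np.where(inside, 0.0, d)
    u = np.clip(1.0 - d / margin, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


@dataclass(frozen=True)
class AngleTemplate:
    """Smooth periodic joint-angle waveform on the 0-100% cycle."""

    joint: str
    bumps: tuple
    offset: float = 0.0
    applied: tuple = ()  # _AppliedDeviation, in application order

    def _base(self, t):
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.offset, dtype=float)
        for b in self.bumps:
            d = np.mod(t - b.center + 50.0, 100.0) - 50.0
            out += b.amplitude * np.exp(-0.5 * (d / b.width) ** 2)
        return out

    def _eval_upto(self, k, t):
        t = np.asarray(t, dtype=float)
        if k == 0:
            return self._base(t)
        dev = self.applied[k - 1]
        start, end = dev.spec.window
        taper = _window_weight(t, start, end, DEVIATION_EDGE_MARGIN)
        if dev.spec.mode == "delay_peak":
            return self._eval_upto(k - 1, t - taper * dev.spec.magnitude)
        prev = self._eval_upto(k - 1, t)
        if dev.spec.mode == "offset":
            return prev + taper * dev.spec.magnitude
        # scale_peak: scale excursion above the frozen window baseline
        scale = 1.0 + (dev.spec.magnitude - 1.0) * taper
        return dev.baseline + (prev - dev.baseline) * scale

    def __call__(self, t):
        """Evaluate the waveform at ``t`` (% gait cycle, any real; the
        waveform is 100-periodic)."""
        return self._eval_upto(len(self.applied), t)

    def sample(self, n_stations: int = 101) -> np.ndarray:
        """Evaluate on n evenly spaced stations spanning 0-100%."""
        return self(np.linspace(0.0, 100.0, n_stations))

    def shifted(self, delta: float) -> "AngleTemplate":
        """Rotate the waveform by ``delta`` % cycle (centers move by
        +delta); only valid before deviations are applied."""
        if self.applied:
            raise ValueError("shift the template before applying deviations")
        bumps = tuple(replace(b, center=np.mod(b.center + delta, 100.0)) for b in self.bumps)
        return replace(self, bumps=bumps)


def apply_deviation(template: AngleTemplate, spec: DeviationSpec) -> AngleTemplate:
    """Return a new template with the deficit applied inside its window.

    Outside the window (beyond the smooth ±2% transition margin) the
    waveform is unchanged; the window baseline used by ``scale_peak`` is
    the minimum of the incoming waveform over the window.
    """
    if spec.joint != template.joint:
        raise ValueError(
            f"deviation targets joint {spec.joint!r} but template is {template.joint!r}"
        )
    start, end = spec.window
    grid = np.linspace(start, end, 2001)
    baseline = float(template(grid).min())
    return replace(template, applied=template.applied + (_AppliedDeviation(spec, baseline),))


# ---------------------------------------------------------------------------
# Default normative templates (synthetic stand-ins, see module docstring)

def _raw_default_templates() -> dict:
    return {
        "hip_flexion": AngleTemplate(
            "hip_flexion",
            bumps=(
                GaussianBump(amplitude=24.0, center=97.0, width=12.0),
                GaussianBump(amplitude=-16.0, center=50.0, width=12.0),
            ),
            offset=6.0,
        ),
        "knee_flexion": AngleTemplate(
            "knee_flexion",
            bumps=(
                GaussianBump(amplitude=55.0, center=66.0, width=12.0),
                GaussianBump(amplitude=14.0, center=15.0, width=8.0),
            ),
            offset=4.0,
        ),
        "ankle_dorsiflexion": AngleTemplate(
            "ankle_dorsiflexion",
            bumps=(
                GaussianBump(amplitude=12.0, center=35.0, width=14.0),
                GaussianBump(amplitude=-18.0, center=56.0, width=5.5),
                GaussianBump(amplitude=-5.0, center=3.0, width=4.0),
            ),
            offset=0.0,
        ),
    }


def _heel_strike_phase(templates: dict, model: LegLinkageModel) -> float:
    """Phase (% cycle) of the heel-forward-extremum heel-strike event
    implied by the templates, from noise-free forward kinematics."""
    phases = np.linspace(0.0, 100.0, 4001)[:-1]
    q = {
        "hip_r": templates["hip_flexion"](phases),
        "knee_r": templates["knee_flexion"](phases),
        "ankle_r": templates["ankle_dorsiflexion"](phases),
        "pelvis_y": np.full_like(phases, model.leg_length),
    }
    mk = forward_kinematics_batch(model, q)
    rel_x = mk["heel_r"][:, 0] - mk["pelvis"][:, 0]
    return float(phases[np.argmax(rel_x)])


def _toe_off_phase(templates: dict, model: LegLinkageModel) -> float:
    """Phase (% cycle) of the toe-rearward-extremum toe-off event."""
    phases = np.linspace(0.0, 100.0, 4001)[:-1]
    q = {
        "hip_r": templates["hip_flexion"](phases),
        "knee_r": templates["knee_flexion"](phases),
        "ankle_r": templates["ankle_dorsiflexion"](phases),
        "pelvis_y": np.full_like(phases, model.leg_length),
    }
    mk = forward_kinematics_batch(model, q)
    rel_x = mk["toe_r"][:, 0] - mk["pelvis"][:, 0]
    return float(phases[np.argmin(rel_x)])


def make_default_templates(model: LegLinkageModel | None = None) -> dict:
    """Default hip / knee / ankle templates, phase-anchored to heel-strike.

    The raw waveforms are rotated so that 0% of the cycle coincides with
    the heel-strike event (heel-forward extremum under the linkage's
    forward kinematics), making template phase, ground-truth events and
    marker-based event detection mutually consistent.
    """
    model = model or default_model()
    templates = _raw_default_templates()
    delta = _heel_strike_phase(templates, model)
    return {j: t.shifted(-delta) for j, t in templates.items()}


# ---------------------------------------------------------------------------
# Trial synthesis

@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic walking trial / cohort.

    Defaults follow a self-selected-speed overground protocol recorded
    at 60 Hz: adult stature, ~1.2 m/s, ~110 steps/min.
    """

    speed: float = 1.2                 # m/s
    cadence: float = 110.0             # steps/min
    height: float = 1.70               # m
    frame_rate: float = 60.0           # Hz
    marker_noise_sd: float = 0.0       # m, isotropic per marker per frame
    amplitude_sd: float = 4.0          # deg, inter-subject bump-amplitude SD
    timing_sd: float = 1.5             # % cycle, inter-subject timing SD
    within_subject_sd: float = 0.5     # deg, within-subject cycle noise
    n_strides: int = 4
    phase_asymmetry: float = 0.0       # % cycle added to the left 50% offset
    seed: int = 0

    def __post_init__(self):
        for name in ("speed", "cadence", "height", "frame_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("marker_noise_sd", "amplitude_sd", "timing_sd", "within_subject_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def stride_time(self) -> float:
        """Stride duration in s (two steps per stride)."""
        return 120.0 / self.cadence

    @property
    def stride_length(self) -> float:
        return self.speed * self.stride_time


@dataclass
class GroundTruth:
    """Generator-side truth for a synthetic trial."""

    time: np.ndarray
    angles: dict          # side -> joint -> ndarray (n_frames,), deg
    events: GaitEvents
    spatiotemporal: dict  # speed, stride_length, step_length_{left,right},
                          # step_width, cadence, double_support_s, ...
    stance_fraction: float  # toe-off phase, % of cycle


def _side_phases(config: SyntheticConfig, t: np.ndarray) -> dict:
    base = t / config.stride_time * 100.0
    return {
        "right": np.mod(base, 100.0),
        "left": np.mod(base + 50.0 + config.phase_asymmetry, 100.0),
    }


def synthesize_trial(config: SyntheticConfig,
                     templates: dict | None = None,
                     deviations: tuple = (),
                     model: LegLinkageModel | None = None):
    """Generate one walking trial.

    Returns ``(MarkerTrajectorySet, GroundTruth)``.  Marker positions
    are the forward-kinematics joint centers of the true time-varying
    angles plus isotropic Gaussian noise; the pelvis translates forward
    at the configured speed.  Identical config (including seed) gives
    bit-identical output.
    """
    if config.n_strides < 1:
        raise ValueError("at least 1 full stride is required")
    model = model or default_model(config.height)
    templates = templates if templates is not None else make_default_templates(model)

    per_joint = dict(templates)
    for spec in deviations:
        per_joint[spec.joint] = apply_deviation(per_joint[spec.joint], spec)

    T = config.stride_time
    duration = config.n_strides * T
    n_frames = int(round(duration * config.frame_rate)) + 1
    t = np.arange(n_frames) / config.frame_rate
    phases = _side_phases(config, t)

    joint_to_coord = {"hip_flexion": "hip", "knee_flexion": "knee", "ankle_dorsiflexion": "ankle"}
    q = {
        "pelvis_x": config.speed * t,
        "pelvis_y": np.full(n_frames, model.leg_length),
        "pelvis_z": np.zeros(n_frames),
        "pelvis_pitch": np.zeros(n_frames),
    }
    angles = {}
    for side in SIDES:
        angles[side] = {j: per_joint[j](phases[side]) for j in JOINTS}
        for j in JOINTS:
            q[f"{joint_to_coord[j]}_{side[0]}"] = angles[side][j]

    clean = forward_kinematics_batch(model, q)
    names = list(model.marker_names())
    positions = np.stack([clean[n] for n in names], axis=1)

    rng = np.random.default_rng(config.seed)
    if config.marker_noise_sd > 0:
        positions = positions + rng.normal(0.0, config.marker_noise_sd, positions.shape)

    markers = MarkerTrajectorySet(frame_rate=config.frame_rate, names=names,
                                  positions=positions)

    # --- ground-truth events: heel strikes at phase 0, toe-offs at the
    # toe-rearward-extremum phase implied by the (possibly deviated)
    # waveforms.
    p_to = _toe_off_phase(per_joint, model)
    hs, to = {}, {}
    offsets = {"right": 0.0, "left": (50.0 + config.phase_asymmetry) % 100.0}
    for side in SIDES:
        # phase(t) = (t/T*100 + offset) mod 100 ; heel strike when phase == 0
        first_hs = ((-offsets[side]) % 100.0) / 100.0 * T
        hs_side = first_hs + T * np.arange(0, config.n_strides + 1)
        hs_side = hs_side[hs_side <= duration + 1e-9]
        to_side = hs_side[:-1] + (p_to / 100.0) * T
        hs[side], to[side] = hs_side, to_side
    events = GaitEvents(heel_strikes=hs, toe_offs=to)

    truth_spt = _true_spatiotemporal(config, model, per_joint, p_to)
    truth = GroundTruth(time=t, angles=angles, events=events,
                        spatiotemporal=truth_spt, stance_fraction=p_to)
    return markers, truth


def _rel_heel_forward(per_joint: dict, model: LegLinkageModel, phase) -> np.ndarray:
    """Heel forward position relative to the pelvis at the given cycle
    phase(s), from noise-free forward kinematics (same for both legs up
    to the mediolateral offset)."""
    phase = np.atleast_1d(np.asarray(phase, dtype=float))
    q = {
        "hip_r": per_joint["hip_flexion"](phase),
        "knee_r": per_joint["knee_flexion"](phase),
        "ankle_r": per_joint["ankle_dorsiflexion"](phase),
        "pelvis_y": np.full(phase.shape, model.leg_length),
    }
    mk = forward_kinematics_batch(model, q)
    return mk["heel_r"][:, 0] - mk["pelvis"][:, 0]


def _true_spatiotemporal(config, model, per_joint, p_to) -> dict:
    """Analytic spatiotemporal truth implied by the construction.

    Heel-strike step geometry is evaluated exactly at the event phases
    (no resampling to the frame grid), so a symmetric configuration
    yields exactly equal left and right step lengths.
    """
    T = config.stride_time
    asym = config.phase_asymmetry
    rel0 = float(_rel_heel_forward(per_joint, model, 0.0)[0])
    # at a right heel-strike the left leg is at phase 50+asym, and vice versa
    rel_l_at_r = float(_rel_heel_forward(per_joint, model, (50.0 + asym) % 100.0)[0])
    rel_r_at_l = float(_rel_heel_forward(per_joint, model, (50.0 - asym) % 100.0)[0])
    step_right = rel0 - rel_l_at_r
    step_left = rel0 - rel_r_at_l
    ds = 2.0 * (p_to - 50.0) / 100.0 * T  # symmetric-timing double support per cycle
    return {
        "speed": config.speed,
        "stride_length": config.stride_length,
        "step_length_left": step_left,
        "step_length_right": step_right,
        "step_width": 2.0 * model.pelvis_half_width,
        "cadence": config.cadence,
        "double_support_s": ds,
        "double_support_pct": 100.0 * ds / T,
    }


def mask_occlusions(markers: MarkerTrajectorySet, rate: float, mean_run: float,
                    seed: int = 0) -> MarkerTrajectorySet:
    """Simulate tracking loss: mask runs of frames per marker.

    ``rate`` is the probability per frame that an occlusion run starts;
    run lengths are geometric with the given mean. Off by default in all
    generation paths.
    """
    rng = np.random.default_rng(seed)
    valid = markers.valid.copy()
    n_frames, n_markers = valid.shape
    p_run = 1.0 / max(mean_run, 1.0)
    for j in range(n_markers):
        starts = np.flatnonzero(rng.random(n_frames) < rate)
        for s in starts:
            run = 1 + rng.geometric(p_run)
            valid[s:s + run, j] = False
    return MarkerTrajectorySet(frame_rate=markers.frame_rate, names=list(markers.names),
                               positions=markers.positions.copy(), valid=valid)


# ---------------------------------------------------------------------------
# Cohort synthesis

def _perturb_templates(templates: dict, rng, amplitude_sd: float, timing_sd: float) -> dict:
    out = {}
    for joint, tpl in templates.items():
        shift = rng.normal(0.0, timing_sd) if timing_sd > 0 else 0.0
        bumps = tuple(
            replace(b,
                    amplitude=b.amplitude + rng.normal(0.0, amplitude_sd),
                    center=np.mod(b.center + shift, 100.0))
            for b in tpl.bumps
        )
        out[joint] = replace(tpl, bumps=bumps)
    return out


def synthesize_cohort(n_subjects: int,
                      cycles_per_subject: int | None,
                      config: SyntheticConfig,
                      seed: int | None = None,
                      templates: dict | None = None) -> list:
    """Generate a normative cohort of time-normalized cycles.

    Each subject's templates are the defaults perturbed by the
    configured inter-subject amplitude / timing distributions; the
    subject's cycles then differ only by within-cycle noise.  When
    ``cycles_per_subject`` is None each subject contributes a random 3-5
    cycles, emulating a consecutive-cycles recording protocol.

    Returns ``[(subject_id, [NormalizedCycle, ...]), ...]``.
    """
    if n_subjects < 2:
        raise ValueError("a normative cohort needs n_subjects >= 2")
    if cycles_per_subject is not None and cycles_per_subject < 1:
        raise ValueError("cycles_per_subject must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    templates = templates if templates is not None else make_default_templates(
        default_model(config.height))
    cohort = []
    for i in range(n_subjects):
        subj_templates = _perturb_templates(
            templates, rng, config.amplitude_sd, config.timing_sd)
        n_cycles = cycles_per_subject if cycles_per_subject is not None else int(rng.integers(3, 6))
        cycles = []
        for c in range(n_cycles):
            ang = {}
            for joint, tpl in subj_templates.items():
                wave = tpl.sample(101)
                if config.within_subject_sd > 0:
                    wave = wave + rng.normal(0.0, config.within_subject_sd, wave.shape)
                ang[joint] = wave
            cycles.append(NormalizedCycle(angles=ang, side="right",
                                          cycle_id=f"S{i:02d}_c{c}"))
        cohort.append((f"S{i:02d}", cycles))
    return cohort
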