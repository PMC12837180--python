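# Methods

This note documents the models, defaults and numerical choices behind
`gaitband`, and what the synthetic validation does and does not show.

## Leg linkage model

The skeleton is a deliberately simplified planar walker, not a full
musculoskeletal model. A pelvis segment translates freely in 3-D and
pitches about the mediolateral (Z) axis; each leg hangs from a hip offset
±`pelvis_half_width` in Z and articulates through three sagittal hinges:
hip flexion, knee flexion (0 = full extension, positive = flexed) and ankle
dorsiflexion (positive = toes up). All angles are degrees at every public
interface (radians internally); coordinates are X forward, Y up, Z
rightward, meters.

Segment lengths default to standard stature fractions (thigh 0.245 H, shank
0.246 H, foot 0.152 H, ankle height 0.039 H for a reference stature
H = 1.70 m) and scale linearly with subject height; measured segment
lengths may override any of them. Virtual markers sit at the joint centers
plus heel and toe points on the foot segment.

Two pelvis-fixed markers beyond the pelvis origin — a sacrum point (0.05 H
behind) and a torso point (0.20 H above) — exist because sagittal pelvis
pitch is otherwise unobservable from joint centers alone: the pelvis origin
and the purely mediolateral hip offsets are invariant under a pitch
rotation, so pitch and hip flexion would form a redundant gauge pair. The
torso point plays the role of the trunk keypoint that markerless pose
estimators track; its long lever is what keeps pitch (and therefore hip
flexion) well-conditioned under marker noise. When no pitch-observing
marker is present in a frame, the solver holds pitch fixed at its initial
value rather than letting it drift.

## Inverse kinematics

Per frame, `scipy.optimize.least_squares` (trust-region reflective)
minimizes Σᵢ wᵢ‖xᵢᵉˣᵖ − xᵢᵐᵒᵈᵉˡ(q)‖² with box bounds on angles (hip
−30…140°, knee 0…150°, ankle −50…40°, pitch ±45°; configurable). The
bounds exist to exclude mirror-pose solutions. Weights are uniform (1.0)
unless configured per marker. Convergence uses step tolerance 1e-10,
objective-change tolerance 1e-12 and an iteration cap of 200.

Frame 0 is solved from a 3×3 multi-start grid over hip/knee angles with the
pelvis initialized at the observed pelvis marker; each later frame is
warm-started from its predecessor. Frames missing any required marker
(pelvis, hip, knee, ankle, heel, toe per side) are flagged as gaps — the
result carries no fabricated pose there. An under-determined marker set
(fewer weighted residual components than free coordinates) is an error,
not a silent pseudo-solution.

Validation (test suite): on noise-free synthetic trials the per-joint RMS
angle error is at machine precision (< 0.5° required); with 5 mm isotropic
marker noise the median per-joint RMSE over 10 seeds stays ≤ 2°. A 2-DOF
planar sub-chain agrees with an exhaustive 0.01° grid search within 0.02°.

## Synthetic gait generator

Waveform basis: each joint's cycle-normalized angle is a constant offset
plus a sum of wrapped Gaussian bumps on the 0–100% circle — smooth, exactly
periodic, with amplitude/center/width exposed. The default landmarks (hip
flexion peak ≈ 30° around terminal swing, knee flexion peak ≈ 59° near 69%,
plantarflexion trough ≈ −15° near 60%, stance knee flexion wave ≈ 15%) are
**synthetic stand-ins with physiologic shape, not measured normative
data**. Cycle phase is anchored so that 0% coincides with the heel-forward
extremum under the linkage's forward kinematics — the same event definition
the detector uses — which makes template phase, ground-truth events and
marker-based event detection mutually consistent. The bump parameters were
chosen once so that, after anchoring, the knee peak falls in the 60–80%
window, the push-off trough in 50–70% and the implied toe-off in the
55–65% stance band.

Trials: the pelvis translates at the configured speed (default 1.2 m/s,
cadence 110 steps/min, 60 Hz, stature 1.70 m — a self-selected-speed
overground protocol); the left leg is the right leg phase-shifted by 50%
plus a configurable asymmetry; marker positions are forward kinematics of
the true angles plus i.i.d. isotropic Gaussian noise (default 0). Occlusion
is simulated, off by default, by masking runs of frames. Identical
configuration and seed give bit-identical output.

Deficits (`DeviationSpec`) act inside a cycle window: `scale_peak` scales
the excursion above the window minimum, `offset` shifts by degrees,
`delay_peak` shifts the waveform later in the cycle. The full effect covers
the window interior; a 2%-of-cycle smoothstep transition just *outside*
each edge (wrapped on the circle) keeps waveforms smooth and periodic.

Cohorts: each subject perturbs bump amplitudes by N(0, 4°) and waveform
timing by a shared N(0, 1.5%) per joint (inter-subject variability);
within-subject cycles differ only by N(0, 0.5°) white noise. Cohort size
and 3–5 cycles per subject mirror a typical normative recording protocol.

Ground truth: the sidecar carries per-frame true angles, event times and
spatiotemporal values. Step geometry is evaluated analytically at the event
phases (not resampled to the frame grid), so a symmetric configuration has
exactly equal left/right step lengths. Note that in this generator the feet
are not ground-constrained during stance, so the sum of step lengths is not
forced to equal the stride length; all quantities are defined from marker
positions at events, identically in the truth and in the measurement path.

What passing tests do *not* show about real data: no soft-tissue artifact,
no pose-estimation bias or outliers (noise is Gaussian and isotropic), no
trunk–pelvis articulation, no stance-foot rolling contact, planar-only
kinematics, and adult waveform shapes only. Results on synthetic data bound
algorithmic errors, not sensor errors.

## Cycle processing

Filtering: 4th-order Butterworth, 6 Hz cutoff, applied forward–backward
(`filtfilt`, reflection-type padding). Zero-phase filtering is required
because peak-timing metrics cannot tolerate group delay; the cost is that
the passband-edge amplitude gain is 0.5 (the single-pass −3 dB gain
squared), verified analytically in the tests.

Events: heel-strike = local maximum of heel forward position relative to
the pelvis; toe-off = local minimum of toe relative forward position within
each same-side stride (which structurally guarantees exactly one toe-off
between consecutive heel-strikes). The walking direction is the horizontal
pelvis net-displacement axis, so reversed walking is handled
automatically. A trial with < 0.2 m progression or < 2 heel-strikes raises
"no analyzable gait cycle".

QC: a cycle fails on (a) any invalid required marker sample in its span
("gap detected"), (b) angles outside plausibility bounds (hip −40…150°,
knee −10…160°, ankle −60…50°; configurable) ("implausible angle"), or
(c) any frame-to-frame jump above 15°/frame referenced to 60 Hz and
rescaled to the actual rate ("discontinuity").

Normalization: linear interpolation onto 101 stations 0,1,…,100%
(cubic is deliberately not the default: linear is deterministic and
shape-preserving); endpoints are preserved exactly and the operation is
idempotent. The "representative" cycle of a trial is the QC-passing cycle
minimizing mean RMS distance to the per-trial mean cycle — a deterministic,
configurable rule chosen because no standard definition exists.

Peak metrics: peak = max, minimum = min, ROM = max − min, timing = station
of the global maximum with ties broken to the earliest station.

## Normative band and deviation profiles

Cycles are averaged within subject first, then the band is the pointwise
mean and sample SD (n−1) across subjects — so the band reflects
between-subject variability, not cycle-to-cycle noise. Z-scores divide by
σ(t) station-wise; a zero σ at any station is a hard `DegenerateBandError`
(never a silent infinity), with an optional σ-floor in the band builder
(off by default). Flagging is inclusive (|Z| ≥ 1.96).

No multiple-comparison correction is applied across the 101 stations or 3
joints; under the null ~5% of stations per joint are expected to flag
(≈ 5 stations), and single-station regions should be read accordingly. The
null coverage is verified by simulation: ≥ 1000 null waveforms scored
against their own generating mean/SD leave 95.0 ± 0.5% of stations
unflagged (`scripts/acceptance.py` recomputes this end to end).

Phase localization: stance/swing boundary at 60% (configurable). A region
starting exactly at the boundary is labeled swing (toe-off begins swing); a
region ending at or before it is stance; a region spanning it is
stance-to-swing. Sub-phase labels (terminal stance 50–60%, pre-swing
50–65%, early-mid swing 60–85%, terminal swing 85–100%) attach when the
region midpoint falls inside the window. No minimum-region-length rule is
imposed.

The band carries a provenance string (e.g. an adult reference cohort used
for a pediatric patient) that reports echo, because reference-population
mismatch is a first-order caveat when interpreting Z-profiles.

## Spatiotemporal parameters

All forward quantities project onto the walking direction. Stride length is
the forward heel displacement between consecutive same-side heel-strikes;
step length is the instantaneous forward heel separation at each
heel-strike of the leading side; step width is the mediolateral heel
separation at heel-strikes; cadence counts heel-strikes over the
first-to-last event window; speed is pelvis displacement over that window.
Double support is computed per right-side cycle from the four-event
sequence (HS_R → TO_L and HS_L → TO_R), reported in seconds and % cycle.

Step-length symmetry is 100·min(L,R)/max(L,R) — bounded, interpretable,
100 = perfect symmetry. Published symmetry percentages from other sources
may use different (often unstated) formulas and are therefore not directly
comparable; this is a documented limitation. Percent change between
sessions is 100·(post−pre)/pre, signed; improvement direction is annotated
per parameter (speed/stride/cadence/symmetry up; double support down; step
width context-dependent).

## Numerical and testing choices

- Tests that assert *exact* left/right symmetry use cadence 112.5 at 60 Hz
  so each stride is exactly 64 frames and heel-strikes fall on sampling
  instants; with incommensurate cadences the frame-grid interpolation
  introduces a benign ~1% left/right wobble.
- Monte-Carlo checks use 3–10 seeds and trials of 2–4 strides — sizes at
  which every stage's statistical tolerance in the suite is already met.
- TRC/MOT files are written with 10-significant-digit numbers so that
  write→read round trips are faithful to 1e-9; CSV reports use 6
  significant digits. All writers are deterministic.
- The filter requires the cutoff strictly below Nyquist; configuration
  validation aggregates all offending keys into one error.

## Known limitations

- Sagittal plane only; no frontal/transverse kinematics, kinetics or EMG.
- The linkage is rigid and planar: no pelvic list/rotation, no trunk
  articulation, no foot rollover model.
- Default waveforms are synthetic; bands built from them must not be
  presented as measured normative data.
- The deficit vocabulary (scale/offset/delay within a window) covers the
  common clinical patterns (reduced swing flexion, delayed peaks, blunted
  push-off) but not arbitrary pathological shapes.
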