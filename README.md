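# gaitband

**Markerless gait analysis for clinical use:** from 3-D joint-center
trajectories (as produced by smartphone/video markerless motion capture) to
joint kinematics, normative-band deviation profiles and spatiotemporal gait
reports.

The package is aimed at clinical-biomechanics and rehabilitation researchers
who want a tested, scriptable version of the standard markerless gait
pipeline: inverse kinematics on a scaled leg linkage, gait-cycle extraction
and time normalization, comparison of a patient's waveforms against a
normative cohort, and pre/post treatment comparison of spatiotemporal
parameters. A ground-truthed synthetic gait generator stands in for patient
recordings, so every stage of the pipeline can be validated against known
truth.

## The method

**Inverse kinematics.** Given observed joint-center positions
$x_i^{\mathrm{exp}}(t)$ and a leg linkage whose virtual markers sit at
$x_i^{\mathrm{model}}(q)$, each frame solves the weighted least-squares
problem

$$\min_{q_t}\; \sum_i w_i \,\lVert x_i^{\mathrm{exp}}(t) - x_i^{\mathrm{model}}(q_t)\rVert^2$$

over pelvis position/pitch and sagittal hip, knee and ankle angles, with
uniform weights by default, box joint limits, warm starts between frames and
a multi-start for the first frame. Segment lengths scale linearly with
subject stature.

**Cycle processing.** Joint angles are zero-phase low-pass filtered
(4th-order Butterworth, 6 Hz cutoff). Heel-strike and toe-off are detected
from the extrema of heel/toe forward position relative to the pelvis; each
stride is quality-screened (tracking gaps, implausible angles,
discontinuities) and time-normalized to 101 stations, 0–100% of the gait
cycle.

**Normative deviation.** Cohort cycles are averaged per subject; the band is
the pointwise mean $\mu(t)$ and sample SD $\sigma(t)$ across subjects.
A patient cycle is scored station-by-station,

$$Z(t) = \frac{x_{\mathrm{patient}}(t) - \mu_{\mathrm{norm}}(t)}{\sigma_{\mathrm{norm}}(t)},$$

flagged where $|Z(t)| \ge 1.96$ (the 95% two-sided normal critical value),
and flagged runs are merged into regions labeled stance / swing /
stance-to-swing (60% boundary) with sub-phase labels (e.g. pre-swing,
terminal swing).

**Spatiotemporal report.** Gait speed, stride and step lengths, step width,
cadence, double-support duration and step-length symmetry
($100\cdot\min(L,R)/\max(L,R)$), plus signed percent changes between paired
pre/post sessions.

## Worked example

Simulate a patient with a blunted swing-phase knee peak (scaled to 60%) and
reduced push-off plantarflexion, run the full pipeline, and compare against
a 30-subject synthetic normative cohort:

```python
from gaitband import *

cfg = SyntheticConfig(marker_noise_sd=0.003, n_strides=4, seed=42)
deficits = (DeviationSpec("knee_flexion", (55.0, 95.0), "scale_peak", 0.6),
            DeviationSpec("ankle_dorsiflexion", (50.0, 70.0), "offset", 7.0))
markers, truth = synthesize_trial(cfg, deviations=deficits)

model = default_model(cfg.height)
series = lowpass_filter(solve_trajectory_ik(model, markers).to_joint_angle_series("right"))
events = detect_gait_events(markers)
patient = representative_cycle(
    [time_normalize(c) for c in extract_cycles(series, events, "right")])

cohort = synthesize_cohort(30, None, SyntheticConfig(), seed=1)
band = build_normative_band([subject_average(c) for _, c in cohort])
profile = localize_phases(flag_deviations(zscore_waveform(patient, band)))
```

Printed deviation regions and spatiotemporal summary:

```
ankle_dorsiflexion      61- 75%  swing           extreme Z +5.30  early-mid swing
knee_flexion            57- 84%  stance-to-swing extreme Z -5.09  early-mid swing

speed 1.20 m/s   stride 1.31 m   cadence 110.2 steps/min
step-length symmetry 99.2%   double support 17.6% of cycle
knee peak 39.6 deg at 69% of cycle
```

Both injected deficits are recovered: the knee region spans the swing-phase
flexion peak with a strongly negative extreme Z (flexion below the band),
and the ankle region marks the raised (blunted) plantarflexion around
push-off and early swing. The spatiotemporal block recovers the configured
walking speed (1.2 m/s) and cadence (110 steps/min) to within a fraction of
a percent.

The same pipeline is available from the shell:

```bash
gaitband simulate --seed 42 --strides 4 --out-dir trial/
gaitband ik --trc trial/trial.trc --out trial/angles.mot
gaitband events --trc trial/trial.trc --out trial/events.json
gaitband normalize --mot trial/angles.mot --events trial/events.json --out trial/cycles.csv
gaitband deviations --band band.csv --patient trial/cycles.csv --out-dir report/
```

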