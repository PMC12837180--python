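"""Filtering, event detection, cycle extraction, QC, normalization and
peak metrics."""
import numpy as np
import pytest

from gaitband.containers import GaitEvents, JointAngleSeries, MarkerTrajectorySet
from gaitband.cycles import (EventDetectionError, detect_gait_events,
                             extract_cycles, lowpass_filter, peak_metrics,
                             qc_cycle, representative_cycle, time_normalize)
from gaitband.synthetic import AngleTemplate, GaussianBump


def make_series(angles, fr=60.0, side="right"):
    n = len(next(iter(angles.values())))
    return JointAngleSeries(time=np.arange(n) / fr, angles=angles,
                            frame_rate=fr, side=side)


class TestLowpassFilter:
    def test_constant_series_unchanged(self):
        s = make_series({"knee_flexion": np.full(240, 12.0)})
        out = lowpass_filter(s)
        assert np.max(np.abs(out.angles["knee_flexion"] - 12.0)) < 1e-9

    def test_cutoff_sinusoid_attenuated_to_half(self):
        """Forward-backward filtering squares the single-pass -3 dB gain:
        a 6 Hz sinusoid at 60 Hz sampling comes out at 0.5 amplitude."""
        fr, n = 60.0, 1800
        t = np.arange(n) / fr
        s = make_series({"knee_flexion": 10.0 * np.sin(2 * np.pi * 6.0 * t)}, fr)
        out = lowpass_filter(s, cutoff=6.0, order=4).angles["knee_flexion"]
        mid = slice(n // 4, 3 * n // 4)
        # amplitude by quadrature demodulation (immune to sampling phase)
        c = 2.0 * np.mean(out[mid] * np.sin(2 * np.pi * 6.0 * t[mid]))
        d = 2.0 * np.mean(out[mid] * np.cos(2 * np.pi * 6.0 * t[mid]))
        assert np.hypot(c, d) == pytest.approx(5.0, rel=0.02)

    def test_stopband_sinusoid_suppressed(self):
        fr, n = 60.0, 1800
        t = np.arange(n) / fr
        s = make_series({"knee_flexion": 10.0 * np.sin(2 * np.pi * 25.0 * t)}, fr)
        out = lowpass_filter(s).angles["knee_flexion"]
        assert np.max(np.abs(out[n // 4: 3 * n // 4])) < 0.1

    def test_zero_phase(self):
        fr, n = 60.0, 600
        t = np.arange(n) / fr
        s = make_series({"knee_flexion": np.sin(2 * np.pi * 1.0 * t)}, fr)
        out = lowpass_filter(s).angles["knee_flexion"]
        mid = slice(n // 4, 3 * n // 4)
        lag = np.argmax(np.correlate(out[mid], s.angles["knee_flexion"][mid], "full"))
        assert lag == len(out[mid]) - 1  # zero-lag peak

    @pytest.mark.parametrize("cutoff", [30.0, 40.0])
    def test_cutoff_at_or_above_nyquist_rejected(self, cutoff):
        s = make_series({"knee_flexion": np.zeros(100)})
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(s, cutoff=cutoff)


class TestDetectGaitEvents:
    def test_events_match_ground_truth_within_two_frames(self, clean_trial):
        markers, truth = clean_trial
        events = detect_gait_events(markers)
        tol = 2.0 / markers.frame_rate
        for side in ("right", "left"):
            for kind in ("heel_strikes", "toe_offs"):
                detected = getattr(events, kind)[side]
                true = getattr(truth.events, kind)[side]
                assert len(detected) >= 2 if kind == "heel_strikes" else len(detected) >= 1
                for d in detected:
                    assert np.min(np.abs(true - d)) <= tol, (side, kind, d)

    def test_static_standing_is_not_analyzable(self, model):
        from gaitband.model import PoseVector, forward_kinematics
        mk = forward_kinematics(model, PoseVector(pelvis_y=0.9))
        names = list(mk)
        positions = np.tile(np.stack([mk[n] for n in names]), (120, 1, 1))
        markers = MarkerTrajectorySet(frame_rate=60.0, names=names, positions=positions)
        with pytest.raises(EventDetectionError, match="no analyzable gait cycle"):
            detect_gait_events(markers)

    def test_direction_reversal_gives_identical_events(self, clean_trial):
        markers, _ = clean_trial
        flipped = MarkerTrajectorySet(
            frame_rate=markers.frame_rate, names=list(markers.names),
            positions=markers.positions * np.array([-1.0, 1.0, 1.0]),
            valid=markers.valid.copy())
        a = detect_gait_events(markers)
        b = detect_gait_events(flipped)
        for side in ("right", "left"):
            np.testing.assert_allclose(a.heel_strikes[side], b.heel_strikes[side])
            np.testing.assert_allclose(a.toe_offs[side], b.toe_offs[side])

    def test_stance_fraction_of_detected_cycles(self, clean_trial):
        markers, _ = clean_trial
        ev = detect_gait_events(markers)
        for side in ("right", "left"):
            hs = ev.heel_strikes[side]
            to = ev.toe_offs[side]
            for a, b, t in zip(hs[:-1], hs[1:], to):
                stance = 100.0 * (t - a) / (b - a)
                assert 55.0 <= stance <= 65.0


class TestExtractCycles:
    @staticmethod
    def events_from(hs, fr=60.0):
        hs = np.asarray(hs, dtype=float)
        to = hs[:-1] + 0.6 * np.diff(hs)
        return GaitEvents(heel_strikes={"right": hs}, toe_offs={"right": to})

    def test_five_heel_strikes_give_four_cycles(self):
        s = make_series({"knee_flexion": np.sin(np.linspace(0, 20, 300))})
        events = self.events_from([0.5, 1.5, 2.5, 3.5, 4.5])
        assert len(extract_cycles(s, events, "right")) == 4

    def test_single_heel_strike_rejected(self):
        s = make_series({"knee_flexion": np.zeros(300)})
        events = GaitEvents(heel_strikes={"right": np.array([1.0])},
                            toe_offs={"right": np.array([])})
        with pytest.raises(EventDetectionError, match="2 heel-strikes"):
            extract_cycles(s, events, "right")

    def test_cycle_boundaries_at_heel_strike_frames(self):
        s = make_series({"knee_flexion": np.arange(300.0)})
        events = self.events_from([1.0, 2.0, 3.0])
        cycles = extract_cycles(s, events, "right")
        assert cycles[0].time[0] == pytest.approx(1.0)
        assert cycles[0].start_time == 1.0 and cycles[0].end_time == 2.0
        assert cycles[1].time[0] == pytest.approx(2.0)


def make_cycle(angles, fr=60.0):
    n = len(next(iter(angles.values())))
    from gaitband.cycles import RawCycle
    t = np.arange(n) / fr
    return RawCycle(time=t, angles={k: np.asarray(v, float) for k, v in angles.items()},
                    side="right", cycle_id="c0", start_time=0.0, end_time=t[-1])


class TestQC:
    def test_clean_synthetic_cycle_passes(self, clean_trial, clean_ik):
        markers, _ = clean_trial
        series = clean_ik.to_joint_angle_series("right")
        events = detect_gait_events(markers)
        for cycle in extract_cycles(series, events, "right"):
            report = qc_cycle(cycle, markers=markers)
            assert report.passed, report.reasons

    def test_spike_fails_as_discontinuity(self):
        v = np.full(60, 20.0)
        v[30] += 20.0
        report = qc_cycle(make_cycle({"knee_flexion": v}))
        assert not report.passed
        assert "discontinuity" in report.reasons

    def test_implausible_angle_fails(self):
        v = np.linspace(190.0, 200.0, 60)
        report = qc_cycle(make_cycle({"knee_flexion": v}))
        assert "implausible angle" in report.reasons

    def test_masked_required_marker_fails_as_gap(self, clean_trial):
        markers, _ = clean_trial
        masked = MarkerTrajectorySet(
            frame_rate=markers.frame_rate, names=list(markers.names),
            positions=markers.positions.copy(), valid=markers.valid.copy())
        masked.valid[70, masked.index("knee_r")] = False
        cycle = make_cycle({"knee_flexion": np.full(120, 20.0)})
        report = qc_cycle(cycle, markers=masked, required=("knee_r",))
        assert "gap detected" in report.reasons

    def test_jump_threshold_scales_with_frame_rate(self):
        # a 10 deg/frame jump: fine at 60 Hz, a discontinuity at 120 Hz
        v = np.full(60, 20.0)
        v[30:] += 10.0
        assert qc_cycle(make_cycle({"knee_flexion": v}, fr=60.0)).passed
        assert not qc_cycle(make_cycle({"knee_flexion": v}, fr=120.0)).passed


class TestTimeNormalize:
    def test_output_has_exactly_101_stations(self, clean_trial, clean_ik):
        markers, _ = clean_trial
        series = clean_ik.to_joint_angle_series("right")
        events = detect_gait_events(markers)
        for cycle in extract_cycles(series, events, "right"):
            nc = time_normalize(cycle)
            for v in nc.angles.values():
                assert len(v) == 101
            assert nc.stations[0] == 0.0 and nc.stations[-1] == 100.0

    def test_constant_input_constant_output(self):
        nc = time_normalize(make_cycle({"knee_flexion": np.full(50, 12.0)}))
        np.testing.assert_allclose(nc.angles["knee_flexion"], 12.0, atol=1e-12)

    def test_linear_ramp_exact(self):
        nc = time_normalize(make_cycle({"knee_flexion": np.linspace(0.0, 10.0, 201)}))
        expected = np.arange(101) * 10.0 / 100.0
        np.testing.assert_allclose(nc.angles["knee_flexion"], expected, atol=1e-9)

    def test_endpoints_preserved_exactly(self):
        v = np.r_[3.25, np.random.default_rng(0).normal(size=48), -7.5]
        nc = time_normalize(make_cycle({"knee_flexion": v}))
        assert nc.angles["knee_flexion"][0] == v[0]
        assert nc.angles["knee_flexion"][-1] == v[-1]

    def test_too_short_cycle_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            time_normalize(make_cycle({"knee_flexion": np.zeros(3)}))

    def test_idempotent_on_normalized_cycle(self):
        nc = time_normalize(make_cycle({"knee_flexion": np.random.default_rng(1).normal(size=80)}))
        again = time_normalize(nc)
        assert np.max(np.abs(again.angles["knee_flexion"] - nc.angles["knee_flexion"])) < 1e-12

    def test_filter_normalize_commutation(self, clean_trial, clean_ik):
        """Filtering then normalizing approximately equals normalizing
        then filtering for band-limited gait signals."""
        markers, _ = clean_trial
        series = clean_ik.to_joint_angle_series("right")
        events = detect_gait_events(markers)
        filtered_first = time_normalize(
            extract_cycles(lowpass_filter(series), events, "right")[0])
        raw_cycle = extract_cycles(series, events, "right")[0]
        nc = time_normalize(raw_cycle)
        # filter the normalized waveform at the equivalent per-cycle rate
        duration = raw_cycle.end_time - raw_cycle.start_time
        station_series = JointAngleSeries(
            time=np.linspace(0, duration, 101),
            angles=nc.angles, frame_rate=100.0 / duration, side="right")
        normalized_first = lowpass_filter(station_series)
        for j in nc.joints:
            rms = np.sqrt(np.mean((filtered_first.angles[j]
                                   - normalized_first.angles[j]) ** 2))
            assert rms < 0.5, j


class TestPeakMetrics:
    def test_sinusoid_closed_form(self):
        t = np.arange(101)
        cycle = time_normalize(make_cycle({"knee_flexion": 30.0 * np.sin(2 * np.pi * t / 100.0)}))
        m = peak_metrics(cycle)
        assert m.peak["knee_flexion"] == pytest.approx(30.0, abs=0.05)
        assert m.minimum["knee_flexion"] == pytest.approx(-30.0, abs=0.05)
        assert m.rom["knee_flexion"] == pytest.approx(60.0, abs=0.1)
        assert m.peak_timing["knee_flexion"] == pytest.approx(25.0, abs=1.0)

    def test_constant_waveform_tie_breaks_to_earliest(self):
        cycle = time_normalize(make_cycle({"knee_flexion": np.full(101, 5.0)}))
        m = peak_metrics(cycle)
        assert m.rom["knee_flexion"] == 0.0
        assert m.peak_timing["knee_flexion"] == 0.0

    def test_recovers_configured_template_peak(self):
        tpl = AngleTemplate("knee_flexion",
                            bumps=(GaussianBump(55.0, 70.0, 9.0),), offset=4.0)
        cycle = time_normalize(make_cycle({"knee_flexion": tpl.sample(101)}))
        m = peak_metrics(cycle)
        assert m.peak_timing["knee_flexion"] == pytest.approx(70.0, abs=1.0)


class TestRepresentativeCycle:
    def test_picks_cycle_closest_to_mean(self):
        rng = np.random.default_rng(4)
        base = 30.0 * np.sin(2 * np.pi * np.arange(101) / 100.0)
        cycles = []
        for k, scale in enumerate([0.2, 0.1, 3.0]):
            c = time_normalize(make_cycle(
                {"knee_flexion": base + scale * rng.normal(size=101)}, fr=60.0))
            c.cycle_id = f"c{k}"
            cycles.append(c)
        assert representative_cycle(cycles).cycle_id in ("c0", "c1")

    def test_single_cycle_returned_unchanged(self):
        c = time_normalize(make_cycle({"knee_flexion": np.zeros(50)}))
        assert representative_cycle([c]) is c

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            representative_cycle([])
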