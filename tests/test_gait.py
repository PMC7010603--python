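"""Acceleration pipeline: filtering, events, segmentation, mirroring, QC."""

import warnings

import numpy as np
import pytest

from tibload import SimulationConfig, generate_cohort
from tibload.gait import (
    DEFAULT_FILTER,
    FilterConfig,
    GaitEvents,
    StrideWindow,
    bandpass_filter,
    derive_channels,
    detect_gait_events,
    extract_impact_window,
    filter_grid,
    ground_contact_time,
    mirror_strides,
    quality_screen,
    segment_strides,
    tune_filter,
)
from tibload.trial import TrialRecording

FS = 1000.0


def _stride(accel_lead, accel_trail=None, ic=0, **kw):
    lead = np.asarray(accel_lead, dtype=float)
    trail = lead.copy() if accel_trail is None else np.asarray(accel_trail, dtype=float)
    base = dict(
        subject_id="s",
        trial_id="t",
        lead_foot="left",
        original_foot="left",
        mirrored=False,
        sampling_rate=FS,
        accel={"lead": lead, "trail": trail},
        ic_index=ic,
        to_index=len(lead) - 1,
        start_ms=0.0,
        stance_ms=250.0,
    )
    base.update(kw)
    return StrideWindow(**base)


class TestBandpass:
    def test_default_config_is_order2_butterworth_08_45(self):
        assert DEFAULT_FILTER == FilterConfig(2, 0.8, 45.0, "butterworth")

    def test_dc_rejected(self):
        x = np.ones((3000, 3))
        y = bandpass_filter(x, sampling_rate=FS)
        assert np.max(np.abs(y)) < 1e-6

    def test_passband_gain_and_zero_lag(self):
        # long signal: the 0.8 Hz high-pass edge transient decays over ~1 s,
        # so the steady-state gain is read from the middle
        t = np.arange(20_000) / FS
        x = np.column_stack([np.sin(2 * np.pi * 10.0 * t)] * 3)
        y = bandpass_filter(x, sampling_rate=FS)
        gain = np.abs(y[8000:12000, 0]).max()
        assert 0.9 <= gain <= 1.0
        lags = np.arange(-30, 31)
        xc = [np.dot(x[3000:-3000, 0], np.roll(y[:, 0], lag)[3000:-3000]) for lag in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_invalid_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(2, 45.0, 0.8)
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros((100, 3)), FilterConfig(2, 0.8, 600.0), FS)


class TestDerivedChannels:
    def test_constant_signal_has_zero_jerk(self):
        d = derive_channels(np.ones((50, 3)) * 2.5, FS)
        assert np.allclose(d.jerk, 0.0)

    def test_pure_anteroposterior_gives_zero_pitch(self):
        x = np.tile([0.0, 1.0, 0.0], (10, 1))
        d = derive_channels(x, FS)
        assert np.allclose(d.pitch, 0.0)
        assert np.allclose(d.roll, np.arctan2(1.0, 0.0))

    def test_jerk_matches_brute_force_differences(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 3))
        d = derive_channels(x, FS)
        brute = np.array([(x[i + 1] - x[i]) * FS for i in range(9)])
        assert np.allclose(d.jerk[:-1], brute)
        assert len(d.jerk) == len(x)


class TestGaitEvents:
    def test_flat_signal_yields_no_events(self):
        n = 3000
        trial = TrialRecording(
            "s", "t", FS, np.zeros((n, 3)), np.zeros((n, 3)), np.zeros(n),
            3.2, 3.2, 70.0, "neutral",
        )
        events = detect_gait_events(trial)
        assert events.n_stances == 0
        assert segment_strides(trial, events) == []

    def test_events_match_truth_on_zero_noise_trials(self, zero_noise_cohort):
        for trial in zero_noise_cohort:
            events = detect_gait_events(trial)
            truth = sorted(trial.ground_truth, key=lambda g: g.ic_time)
            detected = events.merged()
            assert len(detected) == len(truth)
            for (ic, to, foot), g in zip(detected, truth):
                assert foot == g.landing_foot
                assert abs(ic - g.ic_time) <= 10.0
                assert 160.0 <= to - ic <= 350.0

    def test_ground_contact_time_vs_truth(self, zero_noise_cohort):
        trial = zero_noise_cohort[0]
        events = detect_gait_events(trial)
        gct = ground_contact_time(events)
        truth = sorted(trial.ground_truth, key=lambda g: g.ic_time)
        detected = events.merged()
        for (ic, to, foot), g in zip(detected, truth):
            assert abs((to - ic) - (g.to_time - g.ic_time)) <= 15.0
        assert len(gct["left"]) + len(gct["right"]) == len(truth)

    def test_ground_contact_time_arithmetic(self):
        events = GaitEvents(left=[(1000.0, 1250.0)], right=[])
        assert ground_contact_time(events) == {"left": [250.0], "right": []}
        assert ground_contact_time(GaitEvents()) == {"left": [], "right": []}


class TestSegmentation:
    def test_window_spans_opposite_foot_takeoffs(self):
        # L-TO@100, R-IC@150, R-TO@400, L-IC@450, L-TO@700: the only stance
        # with surrounding opposite take-offs is the right one -> [100, 700]
        n = 1000
        rng = np.random.default_rng(1)
        trial = TrialRecording(
            "s", "t", FS, rng.normal(0, 0.01, (n, 3)), rng.normal(0, 0.01, (n, 3)),
            np.zeros(n), 3.2, 3.2, 70.0, "neutral",
        )
        events = GaitEvents(left=[(0.0, 100.0), (450.0, 700.0)], right=[(150.0, 400.0)])
        windows = segment_strides(trial, events, boundary_margin_ms=0.0)
        right = [w for w in windows if w.lead_foot == "right"]
        assert len(right) == 1
        assert right[0].start_ms == pytest.approx(100.0)
        assert right[0].n_samples == pytest.approx(600, abs=1)
        assert right[0].ic_index == 50  # 150 ms within a window starting at 100 ms

    def test_stride_count_matches_truth(self, zero_noise_cohort):
        for trial in zero_noise_cohort:
            events = detect_gait_events(trial)
            windows = segment_strides(trial, events)
            assert len(windows) == len(trial.ground_truth)

    def test_three_stance_trial_gives_three_windows(self):
        config = SimulationConfig(
            n_subjects=1, trials_per_subject=1, strides_per_trial=3,
            noise_sd_accel=0.0, noise_sd_force=0.0, rng_seed=4,
        )
        (trial,) = generate_cohort(config)
        windows = segment_strides(trial, detect_gait_events(trial))
        assert len(windows) == 3


class TestMirroring:
    def test_empty_input(self):
        assert mirror_strides([]) == []

    def test_left_lead_transform(self):
        rng = np.random.default_rng(2)
        lead, trail = rng.normal(size=(20, 3)), rng.normal(size=(20, 3))
        s = _stride(lead, trail, lead_foot="left", original_foot="left")
        (m,) = mirror_strides([s])
        assert m.lead_foot == "right" and m.mirrored and m.original_foot == "left"
        assert np.allclose(m.accel["lead"][:, :2], lead[:, :2])  # axial, AP unchanged
        assert np.allclose(m.accel["lead"][:, 2], -lead[:, 2])  # ML negated

    def test_involution_on_signal_content(self):
        rng = np.random.default_rng(3)
        s = _stride(rng.normal(size=(20, 3)), rng.normal(size=(20, 3)), lead_foot="left")
        (m,) = mirror_strides([s])
        m.lead_foot = "left"  # force a second application of the transform
        (mm,) = mirror_strides([m])
        assert np.allclose(mm.accel["lead"], s.accel["lead"])

    def test_both_feet_stances_all_become_right_lead(self):
        rng = np.random.default_rng(4)
        strides = [
            _stride(rng.normal(size=(20, 3)), lead_foot=f, original_foot=f)
            for f in ("left", "right", "left", "right")
        ]
        out = mirror_strides(strides)
        assert len(out) == 4
        assert all(s.lead_foot == "right" for s in out)


class TestImpactWindow:
    def test_no_crossing_truncates_with_warning(self):
        s = _stride(np.column_stack([np.ones(30), np.zeros(30), np.zeros(30)]))
        with pytest.warns(UserWarning, match="truncated"):
            start, end = extract_impact_window(s)
        assert (start, end) == (0, 30)

    def test_crossing_rule_inclusive(self):
        axial = np.array([5.0, 3.0, 1.0, -1.0, 4.0, 2.0])
        s = _stride(np.column_stack([axial, np.zeros(6), np.zeros(6)]))
        start, end = extract_impact_window(s)
        assert (start, end) == (0, 4)  # first non-positive sample included

    def test_window_ends_before_toe_off_on_simulation(self, zero_noise_cohort):
        trial = zero_noise_cohort[0]
        events = detect_gait_events(trial)
        strides = mirror_strides(segment_strides(trial, events))
        for s in strides:
            start, end = extract_impact_window(s)
            assert end - start >= 4
            assert end <= s.to_index


class TestQualityScreen:
    def test_clean_trial_passes(self, small_cohort):
        ok, reason = quality_screen(small_cohort[0])
        assert ok and reason is None

    def test_nan_fails(self, small_cohort):
        import dataclasses

        trial = dataclasses.replace(small_cohort[0], accel_left=small_cohort[0].accel_left.copy())
        trial.accel_left[100, 1] = np.nan
        ok, reason = quality_screen(trial)
        assert not ok and reason == "non-finite"


class TestFilterTuning:
    def test_paper_grid_enumerates_35_configs(self):
        grid = filter_grid()
        assert len(grid) == 35
        lows = sorted({c.low_cut for c in grid})
        highs = sorted({c.high_cut for c in grid})
        assert lows == [0.2, 0.4, 0.6, 0.8, 1.0]
        assert highs == [40.0, 45.0, 50.0, 55.0, 60.0, 65.0, 70.0]

    def test_single_cell_grid_returned(self, small_cohort):
        cfg = FilterConfig(2, 0.5, 50.0)
        assert tune_filter(small_cohort[:8], [cfg], seed=0) == cfg

    def test_recovers_prefilter_high_cut(self):
        # signals pre-filtered at (0.8, 45) with out-of-band noise (above
        # 48 Hz, amplitude varying per trial) added afterwards: wider
        # high-cuts admit pure noise the model cannot absorb, so the
        # selected high-cut should stay within 10 Hz of 45
        import dataclasses

        from scipy import signal as sg

        from tibload.simulate import SimulationConfig, SubjectProfile, generate_trial

        config = SimulationConfig(noise_sd_accel=0.0, noise_sd_force=0.0)
        rng = np.random.default_rng(11)
        trials = []
        for i in range(12):
            prof = SubjectProfile(
                f"S{i:02d}", float(rng.uniform(55, 90)), 3.4, "neutral",
                float(rng.uniform(0.6, 1.7)), 1.0, 83.0, accel_gain=1.0,
            )
            for j in range(6):
                speed = (2.55, 3.2, 5.1, 3.4)[j % 4]
                trials.append(generate_trial(prof, f"T{j}", speed, config, rng))
        sos_hp = sg.butter(4, 48.0, btype="high", fs=1000.0, output="sos")
        noisy = []
        for t in trials:
            la = bandpass_filter(t.accel_left, DEFAULT_FILTER, t.sampling_rate)
            ra = bandpass_filter(t.accel_right, DEFAULT_FILTER, t.sampling_rate)
            scale = rng.uniform(0.5, 4.0)
            noisy.append(
                dataclasses.replace(
                    t,
                    accel_left=la + sg.sosfilt(sos_hp, rng.normal(0, scale, la.shape), axis=0),
                    accel_right=ra + sg.sosfilt(sos_hp, rng.normal(0, scale, ra.shape), axis=0),
                )
            )
        grid = [FilterConfig(2, 0.8, h) for h in (40.0, 50.0, 60.0, 70.0)]
        chosen = tune_filter(noisy, grid, seed=1)
        assert abs(chosen.high_cut - 45.0) <= 10.0

    def test_degenerate_split_rejected(self, small_cohort):
        one_subject = [t for t in small_cohort if t.subject_id == small_cohort[0].subject_id]
        with pytest.raises(ValueError):
            tune_filter(one_subject, [FilterConfig(2, 0.5, 50.0)], seed=0)
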