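"""Tests of the trajectory / intensity-profile analysis operations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from congression import analysis
from congression.analysis import (
    FFT_MIN_SAMPLES,
    IntensityProfile,
    InvalidFrameError,
    TrackedTrajectory,
    assign_and_project,
    center_distance_timecourse,
    cross_check_methods,
    drift_amplitudes,
    extrema_oscillation_metrics,
    fft_oscillation_metrics,
    klp5_profile_stats,
    lagging_time,
    max_poleward_speed,
    missegregation_flag,
    normalized_distance,
    summarize_groups,
    track_frames,
)


def _tracked(t, pole1, pole2, cenA, cenB, **kw):
    return TrackedTrajectory(
        np.asarray(t, float), np.asarray(pole1, float), np.asarray(pole2, float),
        np.asarray(cenA, float), np.asarray(cenB, float), **kw
    )


class TestAssignAndProject:
    def test_collinear_hand_geometry(self):
        out = assign_and_project([[0.0, 0], [3.0, 0], [1.4, 0], [1.6, 0]])
        assert out["pole1"] == pytest.approx(-1.5)
        assert out["pole2"] == pytest.approx(1.5)
        assert out["cenA"] == pytest.approx(-0.1)
        assert out["cenB"] == pytest.approx(0.1)

    def test_assignment_is_distance_based_not_order_based(self):
        # one centromere beyond a pole on the axis: the max-distance pair
        # still wins the pole assignment
        out = assign_and_project([[0.0, 0], [3.0, 0], [3.1, 0], [1.5, 0]])
        assert out["pole2"] - out["pole1"] == pytest.approx(3.1)
        assert out["cenB"] == pytest.approx(3.0 - 1.55)

    def test_off_axis_spots_project_orthogonally(self):
        out = assign_and_project([[0, 0], [4, 0], [2.0, 0.3], [1.8, -0.2]])
        assert out["pole1"] == pytest.approx(-2.0)
        assert out["cenA"] == pytest.approx(-0.2)
        assert out["cenB"] == pytest.approx(0.0)

    def test_wrong_spot_count_flags_frame(self):
        with pytest.raises(InvalidFrameError):
            assign_and_project([[0, 0], [1, 0], [2, 0]])

    def test_track_frames_skips_invalid(self):
        frames = [
            [[0, 0], [3, 0], [1.4, 0], [1.6, 0]],
            [[0, 0], [3, 0], [1.5, 0]],          # dropped
            [[0, 0], [3, 0], [1.3, 0], [1.7, 0]],
        ]
        traj = track_frames([0.0, 1.0, 2.0], frames)
        assert len(traj) == 2
        np.testing.assert_allclose(traj.t, [0.0, 2.0])


class TestNormalizedDistance:
    def test_anchor_values(self):
        assert normalized_distance(0.0, -1.5, 1.5) == 0.0
        assert normalized_distance(1.5, -1.5, 1.5) == pytest.approx(0.5)
        assert normalized_distance(0.33, -1.5, 1.5) == pytest.approx(0.11)

    def test_zero_spindle_length_rejected(self):
        with pytest.raises(ValueError):
            normalized_distance(0.0, 1.0, 1.0)

    @given(
        mid=st.floats(-2, 2), half=st.floats(0.2, 5),
        shift=st.floats(-10, 10),
    )
    @settings(max_examples=100, deadline=None)
    def test_invariance_translation_reflection_relabeling(self, mid, half, shift):
        base = normalized_distance(mid, -half, half)
        assert normalized_distance(mid + shift, -half + shift, half + shift) == (
            pytest.approx(base, abs=1e-9)
        )
        assert normalized_distance(-mid, -half, half) == pytest.approx(base, abs=1e-9)
        assert normalized_distance(mid, half, -half) == pytest.approx(base, abs=1e-9)


class TestCenterDistanceTimecourse:
    def test_identical_constant_trajectories(self):
        t = np.arange(0, 50, 1.0)
        trajs = [
            _tracked(t, -1.5 + 0 * t, 1.5 + 0 * t, 0.2 + 0 * t, 0.4 + 0 * t,
                     anaphase_onset=25.0)
            for _ in range(4)
        ]
        out = center_distance_timecourse(trajs)
        np.testing.assert_allclose(out["mean_cen"], 0.3)
        np.testing.assert_allclose(out["sd_cen"], 0.0, atol=1e-12)
        np.testing.assert_allclose(out["mean_pole"], 1.5)

    def test_mirrored_pair_averages_absolute_distance(self):
        t = np.arange(0, 30, 1.0)
        a = _tracked(t, -1.5 + 0 * t, 1.5 + 0 * t, 0.3 + 0 * t, 0.5 + 0 * t,
                     anaphase_onset=10.0)
        b = _tracked(t, -1.5 + 0 * t, 1.5 + 0 * t, -0.5 + 0 * t, -0.3 + 0 * t,
                     anaphase_onset=10.0)
        out = center_distance_timecourse([a, b])
        np.testing.assert_allclose(out["mean_cen"], 0.4)
        np.testing.assert_allclose(out["sd_cen"], 0.0, atol=1e-12)

    def test_requires_onset_annotation_and_nonempty(self):
        t = np.arange(0, 10, 1.0)
        with pytest.raises(ValueError):
            center_distance_timecourse([])
        traj = _tracked(t, -1 + 0 * t, 1 + 0 * t, 0 * t, 0 * t)
        with pytest.raises(ValueError):
            center_distance_timecourse([traj])


class TestFFTOscillationMetrics:
    def test_pure_sinusoid_recovered(self):
        t = np.arange(0, 600, 0.1)
        m = fft_oscillation_metrics(0.23 * np.sin(2 * np.pi * t / 126), 0.1)
        assert m.amplitude == pytest.approx(0.23, rel=0.05)
        # frequency within 2 spectral bins of the truth
        assert abs(m.frequency - 1 / 126) < 2 / 600
        assert m.half_period == pytest.approx(63, rel=0.05)

    def test_constant_series_has_no_peak(self):
        assert fft_oscillation_metrics(np.full(1000, 0.7), 0.1) is None

    def test_slow_component_excluded_by_highpass(self):
        t = np.arange(0, 600, 0.1)
        x = 0.2 * np.sin(2 * np.pi * t / 300)  # f ~ 3.3e-3 Hz < 5e-3 Hz
        assert fft_oscillation_metrics(x, 0.1) is None

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            fft_oscillation_metrics(np.zeros(FFT_MIN_SAMPLES - 1), 0.1)

    def test_non_uniform_sampling_rejected(self):
        t = np.concatenate([np.arange(0, 50, 0.1), np.arange(50, 100, 0.2)])
        with pytest.raises(ValueError):
            fft_oscillation_metrics(np.sin(t), 0.1, t=t)

    def test_amplitude_linear_in_scale_half_period_invariant(self):
        t = np.arange(0, 600, 0.1)
        x = np.sin(2 * np.pi * t / 100)
        m1 = fft_oscillation_metrics(0.1 * x, 0.1)
        m2 = fft_oscillation_metrics(0.4 * x, 0.1)
        assert m2.amplitude == pytest.approx(4 * m1.amplitude, rel=1e-6)
        assert m2.half_period == pytest.approx(m1.half_period, rel=1e-9)


class TestExtremaOscillationMetrics:
    def test_triangle_wave_geometry(self):
        t = np.arange(0, 600, 0.5)
        x = 0.2 * sps.sawtooth(2 * np.pi * t / 120, 0.5)
        m = extrema_oscillation_metrics(x, t)
        assert m.half_period == pytest.approx(60, rel=0.05)
        assert m.amplitude == pytest.approx(0.2, rel=0.05)
        assert len(m.segments) >= 3

    def test_monotone_ramp_yields_empty_result(self):
        assert extrema_oscillation_metrics(
            np.linspace(0, 1, 200), np.arange(200.0)
        ) is None

    def test_agrees_with_fft_on_sinusoid(self):
        t = np.arange(0, 600, 0.1)
        x = 0.23 * np.sin(2 * np.pi * t / 126)
        mf = fft_oscillation_metrics(x, 0.1)
        me = extrema_oscillation_metrics(x, t)
        assert me.amplitude == pytest.approx(mf.amplitude, rel=0.10)
        assert me.half_period == pytest.approx(mf.half_period, rel=0.15)

    def test_cross_check_flags_nothing_on_clean_signal(self):
        t = np.arange(0, 600, 0.1)
        x = 0.23 * np.sin(2 * np.pi * t / 126)
        mf, me, flag = cross_check_methods(x, t)
        assert mf is not None and me is not None
        assert not flag


class TestDriftAmplitudes:
    def test_stationary_oscillation_has_negligible_drift(self):
        t = np.arange(0, 600, 0.5)
        x = 0.2 * sps.sawtooth(2 * np.pi * t / 120, 0.5)
        m = extrema_oscillation_metrics(x, t)
        drifts = drift_amplitudes(x, t, m.segments)
        assert drifts and max(drifts) < 0.01  # noise floor of the smoother

    def test_constructed_midline_step_recovered(self):
        t = np.arange(0, 120.5, 0.5)
        x = np.where(t >= 60, 0.2, 0.0)
        drifts = drift_amplitudes(x, t, [(0.0, 60.0, 0.0), (60.0, 120.0, 0.2)])
        assert drifts == [pytest.approx(0.2, abs=1e-6)]

    def test_single_segment_gives_empty_list(self):
        assert drift_amplitudes(np.zeros(10), np.arange(10.0), [(0, 9, 0)]) == []


class TestLaggingTime:
    def _anaphase_traj(self, delay=0.0, stall_B=False):
        t = np.arange(0.0, 200.0, 1.0)
        v = 1.5 / 60
        cenA = np.clip(-0.25 - v * t, -1.5, None)
        startB = 0.25
        if stall_B:
            cenB = np.full_like(t, startB)
        else:
            cenB = np.clip(startB + v * np.maximum(t - delay, 0), None, 1.5)
        return _tracked(t, np.full_like(t, -1.5), np.full_like(t, 1.5),
                        cenA, cenB, anaphase_onset=0.0)

    def test_simultaneous_arrival_zero_lag(self):
        lag, censored, _ = lagging_time(self._anaphase_traj(0.0))
        assert lag == 0.0 and not censored

    def test_constructed_delay_recovered(self):
        lag, censored, _ = lagging_time(self._anaphase_traj(30.0))
        assert lag == pytest.approx(30.0, abs=1.01)

    def test_never_arriving_sister_censored(self):
        lag, censored, arrivals = lagging_time(self._anaphase_traj(stall_B=True))
        assert censored and np.isnan(lag)

    def test_symmetric_in_sister_labels(self):
        traj = self._anaphase_traj(30.0)
        swapped = _tracked(traj.t, traj.pole1, traj.pole2, traj.cenB, traj.cenA,
                           anaphase_onset=0.0)
        assert lagging_time(traj)[0] == lagging_time(swapped)[0]

    def test_missing_onset_rejected(self):
        traj = self._anaphase_traj(0.0)
        traj.anaphase_onset = None
        with pytest.raises(ValueError):
            lagging_time(traj)


class TestMissegregation:
    def _end_state(self, a, b):
        t = np.arange(3.0)
        return _tracked(t, np.full(3, -1.5), np.full(3, 1.5),
                        np.array([0, a / 2, a]), np.array([0, b / 2, b]))

    def test_opposite_poles_ok(self):
        assert not missegregation_flag(self._end_state(-1.4, 1.3))

    def test_same_pole_flagged(self):
        assert missegregation_flag(self._end_state(1.2, 1.4))

    def test_sister_at_center_tie_breaks_benign(self):
        assert not missegregation_flag(self._end_state(0.0, 1.4))


class TestMaxPolewardSpeed:
    def test_linear_motion(self):
        t = np.arange(0, 60.5, 0.5)
        x = 2.0 * t / 60.0
        assert max_poleward_speed(x, t) == pytest.approx(2.0, rel=1e-6)

    def test_static_trace_zero(self):
        t = np.arange(0, 60.0, 0.5)
        assert max_poleward_speed(np.full_like(t, 0.3), t) == 0.0

    def test_sawtooth_slope_recovered(self):
        t = np.arange(0, 600, 0.5)
        # triangle of period 60 s: slope = 2*amp / (period/2); amp = 0.3 um
        # gives |slope| = 0.02 um/s = 1.2 um/min
        x = 0.3 * sps.sawtooth(2 * np.pi * t / 60, 0.5)
        assert max_poleward_speed(x, t, window=3) == pytest.approx(1.2, rel=0.05)

    def test_window_validation(self):
        t = np.arange(10.0)
        with pytest.raises(ValueError):
            max_poleward_speed(t, t, window=4)
        with pytest.raises(ValueError):
            max_poleward_speed(t[:3], t[:3], window=5)


class TestProfileStats:
    def test_flat_profile_identity(self):
        profs = [IntensityProfile(np.ones(20), 1.2)]
        tips, mean_profiles = klp5_profile_stats(profs, [1.0, 1.5])
        assert tips["tip_mean"].iloc[0] == pytest.approx(1.0)
        np.testing.assert_allclose(mean_profiles[0]["mean"], 1.0)

    def test_last_decile_tip(self):
        profs = [IntensityProfile(np.array([1, 1, 1, 1, 3.0]), 1.2)]
        tips, _ = klp5_profile_stats(profs, [1.0, 1.5])
        # median 1 leaves the profile unchanged; 5 samples -> tip = last one
        assert tips["tip_mean"].iloc[0] == pytest.approx(3.0)

    def test_median_normalization_scale_invariance(self):
        rng = np.random.default_rng(0)
        values = 1.0 + 0.1 * rng.random(30)
        profs_a = [IntensityProfile(values, 2.0),
                   IntensityProfile(values * 0.9, 3.0)]
        profs_b = [IntensityProfile(values * 7.3, 2.0),
                   IntensityProfile(values * 0.9, 3.0)]
        tips_a, prof_a = klp5_profile_stats(profs_a, [1.5, 2.5, 3.5])
        tips_b, prof_b = klp5_profile_stats(profs_b, [1.5, 2.5, 3.5])
        np.testing.assert_allclose(tips_a["tip_mean"], tips_b["tip_mean"])
        for k in prof_a:
            np.testing.assert_allclose(prof_a[k]["mean"], prof_b[k]["mean"])

    def test_zero_median_profile_excluded(self):
        profs = [IntensityProfile(np.zeros(10), 2.0),
                 IntensityProfile(np.ones(10), 2.0)]
        tips, _ = klp5_profile_stats(profs, [1.5, 2.5])
        assert tips["n"].iloc[0] == 1

    def test_empty_bin_absent(self):
        profs = [IntensityProfile(np.ones(10), 1.0)]
        tips, _ = klp5_profile_stats(profs, [0.5, 1.5, 2.5])
        assert list(tips["bin"]) == [0]


class TestSummarizeGroups:
    def test_identical_groups(self):
        summary, tests = summarize_groups(
            {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}
        )
        assert tests["t"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert tests["p"].iloc[0] == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(1)
        a = 0.0 + 1e-6 * rng.random(4)
        b = 1.0 + 1e-6 * rng.random(4)
        _, tests = summarize_groups({"a": a, "b": b})
        assert tests["p"].iloc[0] < 1e-3

    def test_sem_hand_value(self):
        summary, _ = summarize_groups({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert summary["sem"].iloc[0] == pytest.approx(0.5774, abs=1e-4)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="b"):
            summarize_groups({"a": [1, 2], "b": [1.0]})
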