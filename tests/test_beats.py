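"""Beat anatomy: derivative, segmentation, anchors, parameter recovery.

The analytic single beat used throughout is c(t) = sin^2(pi t / T): its
rectified derivative |c'| = (pi/T) |sin(2 pi t / T)| peaks at T/4 and 3T/4,
so t[theta_c-r] = T/2 exactly, and c decays to 5 % of its peak on the
descending limb at t = T (1 - arcsin(sqrt(0.05)) / pi) ~= 0.9283 T.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiokin.beats import (
    beat_parameters,
    beats_table,
    derivative,
    segment_beats,
    summarize_beats,
    time_to_peak,
)
from cardiokin.errors import EmptySummaryError
from cardiokin.pipeline import track_clip
from cardiokin.profiles import ContractionProfile

T_MS = 400.0
FS = 1000.0  # dense 1 kHz sampling for the analytic beat
# descending-limb solution of sin^2(pi t / T) = 0.05
E_TRUE_MS = T_MS * (1.0 - math.asin(math.sqrt(0.05)) / math.pi)


@pytest.fixture(scope="module")
def sin2_profiles():
    """One sin^2 beat padded with 100 ms of diastole on each side."""
    n = int(0.6 * FS)
    t_ms = np.arange(n) / FS * 1000.0
    c = np.zeros(n)
    inside = (t_ms >= 100.0) & (t_ms <= 100.0 + T_MS)
    c[inside] = np.sin(np.pi * (t_ms[inside] - 100.0) / T_MS) ** 2
    prof = ContractionProfile(c, fps=FS, source="marker", units="um")
    return derivative(prof), prof


class TestDerivative:
    def test_hand_arithmetic(self):
        prof = ContractionProfile([0.0, 1.0, 0.0], fps=10.0, source="marker",
                                  units="um")
        speed = derivative(prof)
        assert speed.values == pytest.approx([10.0, 10.0])
        assert speed.rectified

    def test_constant_profile_zero_speed(self):
        prof = ContractionProfile(np.full(10, 3.3), fps=10.0, source="marker",
                                  units="um")
        assert np.all(derivative(prof).values == 0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(slope=st.floats(0.01, 5.0), fps=st.floats(10, 200))
    def test_linear_ramp_gives_constant_slope_times_fps(self, slope, fps):
        prof = ContractionProfile(slope * np.arange(20), fps=fps,
                                  source="marker", units="um")
        assert derivative(prof).values == pytest.approx(
            np.full(19, slope * fps), rel=1e-9
        )

    def test_forward_scheme_anticipates_central(self, sin2_profiles):
        _, prof = sin2_profiles
        fwd = derivative(prof, "forward")
        cen = derivative(prof, "central")
        # the forward difference is timestamped half a sample earlier
        peak_fwd = fwd.times_ms[np.argmax(fwd.values)]
        peak_cen = cen.times_ms[np.argmax(cen.values)]
        assert peak_fwd <= peak_cen


class TestAnalyticBeat:
    def test_speed_peaks_at_quarter_periods(self, sin2_profiles):
        speed, prof = sin2_profiles
        beats = segment_beats(speed, prof, onset_epsilon=1e-4)
        assert len(beats) == 1
        p = beat_parameters(beats[0], speed, prof)
        assert p.t_theta_cr == pytest.approx(T_MS / 2.0, abs=2.0)
        assert p.t_theta_c == pytest.approx(T_MS / 4.0, abs=4.0)

    def test_end_solves_five_percent_decay(self, sin2_profiles):
        speed, prof = sin2_profiles
        beats = segment_beats(speed, prof, onset_epsilon=1e-4)
        e_rel = beats[0].E_ms - 100.0
        assert e_rel == pytest.approx(E_TRUE_MS, abs=1000.0 / FS)  # 1 sample

    def test_symmetric_beat_equal_peak_magnitudes(self, sin2_profiles):
        speed, prof = sin2_profiles
        beats = segment_beats(speed, prof, onset_epsilon=1e-4)
        p = beat_parameters(beats[0], speed, prof)
        assert p.contraction_peak_magnitude == pytest.approx(
            p.relaxation_peak_magnitude, rel=0.02
        )

    def test_anchor_ordering(self, sin2_profiles):
        speed, prof = sin2_profiles
        b = segment_beats(speed, prof, onset_epsilon=1e-4)[0]
        assert b.A_ms < b.B_ms <= b.C_ms < b.D_ms <= b.E_ms

    def test_time_to_peak_interpolation(self, sin2_profiles):
        speed, prof = sin2_profiles
        b = segment_beats(speed, prof, onset_epsilon=1e-4)[0]
        ttp = time_to_peak(prof, b, onset_epsilon=1e-4)
        assert ttp == pytest.approx(T_MS / 2.0, abs=3.0)


class TestSegmentation:
    def test_all_zero_profiles_give_empty_list(self):
        prof = ContractionProfile(np.zeros(50), fps=100.0, source="marker",
                                  units="um")
        assert segment_beats(derivative(prof), prof) == []

    def test_synthetic_beat_count_and_onsets(self, cells_clip_clean):
        clip, truth = cells_clip_clean
        speed, contraction = track_clip(clip, "marker")
        beats = segment_beats(speed, contraction, pacing_hint=1.0,
                              onset_epsilon=0.001)
        assert len(beats) == len(truth.onsets_ms)
        frame_ms = 1000.0 / clip.fps
        for b, onset in zip(beats, truth.onsets_ms):
            assert abs(b.A_ms - onset) <= 2 * frame_ms + 3.0


class TestParameterRecovery:
    @pytest.mark.parametrize("tracker", ["intensity", "marker"])
    def test_time_to_peak_recovery(self, cells_clip_clean, tracker):
        # the measured onset is the 5 % crossing of the raised-cosine rise,
        # which sits at (1 - arccos(0.9)/pi) of the true time-to-peak; the
        # recovered interval must match that analytic value within 1 frame
        clip, truth = cells_clip_clean
        speed, contraction = track_clip(clip, tracker)
        beats = segment_beats(speed, contraction, pacing_hint=1.0)
        expected = 120.0 * (1.0 - math.acos(1.0 - 2 * 0.05) / math.pi)
        frame_ms = 1000.0 / clip.fps
        mid = beats[1:-1]
        est = np.mean([time_to_peak(contraction, b) for b in mid])
        assert est == pytest.approx(expected, abs=frame_ms)

    def test_beat_duration_recovery(self, cells_clip_clean):
        # true onset -> 5 % decay spans time_to_peak + relaxation_time; the
        # measured A sits at the 5 % onset crossing, so subtract that offset
        clip, truth = cells_clip_clean
        speed, contraction = track_clip(clip, "marker")
        beats = segment_beats(speed, contraction, pacing_hint=1.0)
        onset_offset = 120.0 * (math.acos(1.0 - 2 * 0.05) / math.pi)
        expected = (120.0 + 200.0) - onset_offset
        frame_ms = 1000.0 / clip.fps
        durations = [b.E_ms - b.A_ms for b in beats[1:-1]]
        assert np.mean(durations) == pytest.approx(expected, abs=2 * frame_ms + 5)


class TestSummaries:
    def test_single_beat_mean_is_itself(self, sin2_profiles):
        speed, prof = sin2_profiles
        b = segment_beats(speed, prof, onset_epsilon=1e-4)[0]
        p = beat_parameters(b, speed, prof)
        table = summarize_beats([p])
        assert table.loc["beat_duration_ms", "mean"] == pytest.approx(p.beat_duration)
        assert table.loc["beat_duration_ms", "sd"] == 0.0

    def test_mean_and_sd_arithmetic(self, sin2_profiles):
        speed, prof = sin2_profiles
        b = segment_beats(speed, prof, onset_epsilon=1e-4)[0]
        p = beat_parameters(b, speed, prof)
        from dataclasses import replace

        p1 = replace(p, beat_duration=900.0)
        p2 = replace(p, beat_duration=1100.0)
        table = summarize_beats([p1, p2])
        assert table.loc["beat_duration_ms", "mean"] == pytest.approx(1000.0)
        assert table.loc["beat_duration_ms", "sd"] == pytest.approx(141.42, abs=0.01)

    def test_empty_input_rejected(self):
        with pytest.raises(EmptySummaryError):
            summarize_beats([])

    def test_beats_table_schema(self, sin2_profiles):
        speed, prof = sin2_profiles
        beats = segment_beats(speed, prof, onset_epsilon=1e-4)
        table = beats_table(beats, speed, prof, video_id="v0", tracker="marker")
        assert list(table.columns[:3]) == ["video_id", "tracker", "beat_index"]
        assert len(table) == 1
        assert (table.t_theta_cr_ms <= table.beat_duration_ms).all()
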