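"""Waveform sampling, rendering geometry, benchmark protocol, determinism."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiokin.errors import InvalidProtocolError, RenderError
from cardiokin.synthetic import (
    CONTROL,
    SyntheticSpec,
    WaveformParams,
    cardioid_spec,
    cells_protocol,
    cells_spec,
    generate_benchmark,
    iter_benchmark,
    make_waveform,
    preset_effect,
    render_clip,
    sample_beat_features,
)


class TestWaveform:
    def test_one_beat_per_pacing_period(self):
        wf = WaveformParams(amplitude=0.1, time_to_peak=100, relaxation_time=200,
                            pacing_frequency=2.0)
        d, truth = make_waveform(wf, 5.0, 143.0)
        assert len(truth.onsets_ms) == 10  # f x T

    def test_peak_lands_at_onset_plus_time_to_peak(self):
        wf = WaveformParams(amplitude=0.1, time_to_peak=100, relaxation_time=200,
                            pacing_frequency=1.0)
        d, truth = make_waveform(wf, 5.0, 1000.0)  # 1 ms sampling
        assert len(truth.onsets_ms) == 5
        for onset in truth.onsets_ms:
            peak_idx = int(onset + 100)
            assert d[peak_idx] == pytest.approx(0.1, abs=1e-6)

    def test_decays_to_five_percent_at_relaxation_time(self):
        wf = WaveformParams(amplitude=0.2, time_to_peak=80, relaxation_time=150,
                            pacing_frequency=1.0)
        d, truth = make_waveform(wf, 1.0, 1000.0)
        onset = truth.onsets_ms[0]
        idx_5pct = int(onset + 80 + 150)
        assert d[idx_5pct] == pytest.approx(0.05 * 0.2, rel=1e-3)

    def test_time_variant_condition_keeps_amplitude(self):
        # doubling time-to-peak at constant amplitude: peak value unchanged,
        # peak time doubled (relative to onset)
        base = WaveformParams(amplitude=0.1, time_to_peak=100, relaxation_time=200,
                              pacing_frequency=1.0)
        double = replace(base, time_to_peak=200)
        db, tb = make_waveform(base, 1.0, 1000.0)
        dd, td = make_waveform(double, 1.0, 1000.0)
        assert db.max() == pytest.approx(dd.max(), rel=1e-6)
        assert td.beats.peak_ms[0] - td.onsets_ms[0] == pytest.approx(
            2 * (tb.beats.peak_ms[0] - tb.onsets_ms[0])
        )

    def test_capture_violation_rejected(self):
        with pytest.raises(InvalidProtocolError):
            WaveformParams(amplitude=0.1, time_to_peak=400, relaxation_time=700,
                           pacing_frequency=1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        amplitude=st.floats(0.01, 0.3),
        ttp=st.floats(50, 150),
        tr=st.floats(100, 250),
        freq=st.sampled_from([0.5, 1.0]),
    )
    def test_waveform_bounds_and_monotone_rise(self, amplitude, ttp, tr, freq):
        wf = WaveformParams(amplitude=amplitude, time_to_peak=ttp,
                            relaxation_time=tr, pacing_frequency=freq)
        d, truth = make_waveform(wf, 2.0 / freq, 1000.0)
        assert d.min() >= 0 and d.max() <= amplitude + 1e-9
        onset = int(truth.onsets_ms[0])
        rise = d[onset : onset + int(ttp)]
        assert np.all(np.diff(rise) >= -1e-12)


class TestRendering:
    def test_same_seed_bit_identical(self):
        spec = cells_spec(seed=5, duration_s=0.5)
        a, _ = render_clip(spec)
        b, _ = render_clip(spec)
        assert np.array_equal(a.frames, b.frames)

    def test_different_seed_differs(self):
        a, _ = render_clip(cells_spec(seed=5, duration_s=0.5))
        b, _ = render_clip(cells_spec(seed=6, duration_s=0.5))
        assert not np.array_equal(a.frames, b.frames)

    def test_zero_amplitude_means_static_frames(self):
        wf = WaveformParams(amplitude=0.0)
        spec = cells_spec(seed=3, duration_s=0.3, noise_sd=0.0, waveform=wf)
        clip, truth = render_clip(spec)
        assert np.all(truth.d == 0)
        assert np.abs(clip.frames - clip.frames[0]).max() < 1e-7

    def test_rod_tip_excursion_matches_scaling_about_centroid(self):
        # 400 px rod at amplitude 0.1: each tip travels d * L/2 = 20 px at
        # peak; the rendered boundary must follow within the 0.5 px
        # sub-pixel rendering tolerance
        wf = WaveformParams(amplitude=0.1, time_to_peak=150, relaxation_time=250,
                            pacing_frequency=0.5)
        spec = SyntheticSpec(
            geometry="banded_rod", length_um=400, width_um=30,
            frame_shape=(60, 460), pixel_size=1.0, noise_sd=0.0,
            background_texture=0.0, waveform=wf, duration_s=0.9,
            fps=100.0, seed=4,
        )
        clip, truth = render_clip(spec)
        peak_frame = int(np.argmax(truth.d))
        assert truth.d[peak_frame] == pytest.approx(0.1, abs=1e-3)

        def tip_x(frame):
            cols = np.where(frame.max(axis=0) > spec.background + 0.15)[0]
            return cols.max()

        excursion = tip_x(clip.frames[0]) - tip_x(clip.frames[peak_frame])
        assert abs(excursion - truth.d[peak_frame] * 200.0) <= 0.5 + 1.0

    def test_cardioid_radius_shrinks_by_d_times_radius(self):
        # 454.13 um diameter at 1 um/px, amplitude 0.05 -> radius shrinks by
        # ~11.35 px at peak
        wf = WaveformParams(amplitude=0.05, time_to_peak=250, relaxation_time=350,
                            pacing_frequency=0.5)
        spec = SyntheticSpec(
            geometry="cardioid", diameter_um=454.13, frame_shape=(480, 480),
            pixel_size=1.0, noise_sd=0.0, background_texture=0.0,
            waveform=wf, duration_s=0.9, fps=20.0, seed=9,
        )
        clip, truth = render_clip(spec)
        peak_frame = int(np.argmax(truth.d))

        def radius(frame):
            row = frame[240, :]
            cols = np.where(row > spec.background + 0.1)[0]
            return (cols.max() - cols.min()) / 2.0

        shrink = radius(clip.frames[0]) - radius(clip.frames[peak_frame])
        assert shrink == pytest.approx(truth.d[peak_frame] * 227.065, abs=1.5)

    def test_geometry_must_fit_frame(self):
        with pytest.raises(RenderError):
            render_clip(cells_spec(frame_shape=(30, 60), duration_s=0.2))

    @pytest.mark.parametrize("geometry", ["banded_rod", "fog_rod", "cardioid"])
    def test_all_geometries_render_within_intensity_range(self, geometry):
        maker = cardioid_spec if geometry == "cardioid" else cells_spec
        clip, _ = render_clip(maker(geometry=geometry, duration_s=0.2, seed=1))
        assert clip.frames.min() >= 0 and clip.frames.max() <= 1

    def test_ground_truth_boundary_speed_units(self):
        spec = cells_spec(seed=1, duration_s=1.0, noise_sd=0.0)
        _, truth = render_clip(spec)
        speeds = truth.boundary_speed_um_s()
        disp = truth.tip_displacement_um()
        assert speeds.shape == (truth.d.size - 1,)
        assert speeds[0] == pytest.approx(abs(disp[1] - disp[0]) * spec.fps)


class TestTreatments:
    def test_control_is_identity(self):
        wf = WaveformParams()
        assert CONTROL.apply(wf) == wf

    def test_caffeine_like_scales_amplitude(self):
        wf = WaveformParams(amplitude=0.1)
        out = preset_effect("caffeine_like").apply(wf)
        assert out.amplitude == pytest.approx(0.13)
        assert out.time_to_peak == wf.time_to_peak

    def test_kcl_like_lengthens_duration_ten_percent(self):
        wf = WaveformParams(time_to_peak=120, relaxation_time=200)
        out = preset_effect("kcl_like", wf).apply(wf)
        assert (out.time_to_peak + out.relaxation_time) == pytest.approx(
            1.1 * 320.0
        )
        assert out.time_to_peak == wf.time_to_peak  # upstroke untouched


@pytest.fixture(scope="module")
def tiny_protocol():
    wf = WaveformParams(amplitude=0.1, time_to_peak=100, relaxation_time=150)
    return cells_protocol(
        replicates=3, master_seed=17,
        duration_s=2.0, fps=30.0, frame_shape=(40, 64),
        length_um=40.0, width_um=12.0, waveform=wf,
    )


class TestBenchmark:
    def test_grid_counting_and_labels(self, tiny_protocol):
        items = generate_benchmark(tiny_protocol)
        assert len(items) == 3 * 2 * 3  # freq x arm x replicate
        freqs = {it.label["frequency"] for it in items}
        assert freqs == {0.5, 1.0, 2.0}
        labels = {(it.label["arm"], it.label["label"]) for it in items}
        assert labels == {("control", 0), ("caffeine_like", 1)}

    def test_master_seed_reproducibility(self, tiny_protocol):
        first = next(iter_benchmark(tiny_protocol))
        second = next(iter_benchmark(tiny_protocol))
        assert np.array_equal(first.clip.frames, second.clip.frames)


class TestFeatureSimulation:
    def test_null_classes_identically_distributed(self):
        df = sample_beat_features(50, effect_sd=0.0, seed=1)
        assert len(df) == 100
        a = df[df.label == 0]["beat_duration_ms"]
        b = df[df.label == 1]["beat_duration_ms"]
        # same generating distribution: means within a few SEM
        sem = a.std() / math.sqrt(len(a))
        assert abs(a.mean() - b.mean()) < 4 * sem * math.sqrt(2)

    def test_effect_shifts_targeted_features_only(self):
        df = sample_beat_features(300, effect_sd=3.0, seed=2)
        g = df.groupby("label").mean()
        shifted = g.loc[1, "beat_duration_ms"] - g.loc[0, "beat_duration_ms"]
        untouched = g.loc[1, "t_theta_r_ms"] - g.loc[0, "t_theta_r_ms"]
        assert shifted > 100  # 3 x 60 ms SD, minus sampling noise
        assert abs(untouched) < 10
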