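"""Ground-truthed synthetic beating-sample videos.

This module stands in for all recorded data: it renders (i) a grey, banded
rod-shaped cardiomyocyte, (ii) a "fog" diffuse phase-contrast rod, and (iii)
a round cardioid (cardiac spheroid), each driven by a parametric contraction
waveform, and returns alongside every clip the exact per-frame deformation
and per-beat anchor times the renderer used.  Recovery tests and the
acceptance suite compare tracker output against this ground truth.

Model
-----
The scalar deformation d(t) is a fractional shortening in [0, amplitude]:
each beat rises as a raised cosine ``A/2 (1 - cos(pi s / ttp))`` over the
time-to-peak and then decays as ``A cos^2(pi s / (2 Td))``, with the decay
span Td fixed so that d crosses 5 % of the amplitude exactly
``relaxation_time`` after the peak.  Rods shorten longitudinally about
their centroid by the factor ``1 - d(t)`` (width unchanged); cardioids
shrink radially by the same factor.  Textures deform with the geometry.
Rasterization is supersampled 4x and box-downsampled so sub-pixel motion
survives; i.i.d. Gaussian pixel noise is added per frame and intensities
are clipped to [0, 1].

Defaults mirror the acquisition conditions this package targets: 143 fps,
5 s clips for single cells paced at 0.5/1/2 Hz, 10 s clips for cardioids
paced at 0.5/0.75/1 Hz (1 Hz being the highest rate with 1:1 capture),
a 454 um cardioid diameter and a ~113 um cell length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .errors import InvalidProtocolError, RenderError
from .io import VideoClip

__all__ = [
    "WaveformParams",
    "TreatmentEffect",
    "SyntheticSpec",
    "GroundTruth",
    "BenchmarkProtocol",
    "make_waveform",
    "render_clip",
    "generate_benchmark",
    "iter_benchmark",
    "preset_effect",
    "cells_spec",
    "cardioid_spec",
    "cells_protocol",
    "cardioid_protocol",
    "sample_beat_features",
    "benchmark_feature_tables",
]

# decay span multiplier: cos^2(pi*t_r/(2*Td)) = 0.05  =>  Td = c * t_r
_DECAY_SPAN = math.pi / (2.0 * math.acos(math.sqrt(0.05)))


@dataclass(frozen=True)
class WaveformParams:
    """Parametric contraction waveform for one pacing condition.

    amplitude        peak fractional shortening (0.08 = 8 % length change)
    time_to_peak     ms, onset -> peak
    relaxation_time  ms, peak -> decay to 5 % of amplitude
    pacing_frequency Hz
    baseline_jitter  ms SD of per-beat onset jitter (0 = field-stimulated)
    """

    amplitude: float = 0.08
    time_to_peak: float = 120.0
    relaxation_time: float = 200.0
    pacing_frequency: float = 1.0
    baseline_jitter: float = 0.0

    def __post_init__(self):
        # amplitude 0 is allowed as the degenerate no-motion case
        if not 0 <= self.amplitude <= 0.5:
            raise InvalidProtocolError("amplitude must lie in [0, 0.5]")
        if self.time_to_peak <= 0 or self.relaxation_time <= 0:
            raise InvalidProtocolError("time_to_peak and relaxation_time must be > 0")
        if self.pacing_frequency <= 0:
            raise InvalidProtocolError("pacing_frequency must be > 0")
        period_ms = 1000.0 / self.pacing_frequency
        if self.time_to_peak + self.relaxation_time >= period_ms:
            raise InvalidProtocolError(
                f"1:1 capture violated: time_to_peak + relaxation_time = "
                f"{self.time_to_peak + self.relaxation_time:.1f} ms >= pacing period "
                f"{period_ms:.1f} ms"
            )
        if self.time_to_peak + _DECAY_SPAN * self.relaxation_time > period_ms:
            raise InvalidProtocolError(
                "decay tail overlaps the next beat; shorten relaxation_time or pace slower"
            )

    @property
    def decay_span_ms(self) -> float:
        """Full peak-to-zero decay duration (the 5 % point sits inside it)."""
        return _DECAY_SPAN * self.relaxation_time


@dataclass(frozen=True)
class TreatmentEffect:
    """Signed perturbation of the waveform, emulating a bath treatment.

    ``duration_shift`` lengthens the beat without touching the upstroke, so
    it is applied to the relaxation limb.  ``control`` is the identity.
    """

    name: str = "control"
    amplitude_scale: float = 1.0
    time_to_peak_shift: float = 0.0  # ms
    relaxation_shift: float = 0.0  # ms
    duration_shift: float = 0.0  # ms

    def apply(self, params: WaveformParams) -> WaveformParams:
        return replace(
            params,
            amplitude=params.amplitude * self.amplitude_scale,
            time_to_peak=params.time_to_peak + self.time_to_peak_shift,
            relaxation_time=params.relaxation_time
            + self.relaxation_shift
            + self.duration_shift,
        )


CONTROL = TreatmentEffect()


def preset_effect(name: str, params: WaveformParams | None = None) -> TreatmentEffect:
    """Named treatment presets.

    ``caffeine_like`` scales amplitude by 1.3 (positive inotropy);
    ``kcl_like`` lengthens the beat by 10 % of the untreated duration.
    These defaults are fixtures for sensitivity testing, not claims about
    the pharmacology; both are freely configurable via TreatmentEffect.
    """
    if name == "control":
        return CONTROL
    if name == "caffeine_like":
        return TreatmentEffect(name=name, amplitude_scale=1.3)
    if name == "kcl_like":
        base = params if params is not None else WaveformParams()
        dur = base.time_to_peak + base.relaxation_time
        return TreatmentEffect(name=name, duration_shift=0.10 * dur)
    raise ValueError(f"unknown treatment preset {name!r}")


@dataclass
class GroundTruth:
    """Exactly what the renderer did, for recovery tests.

    d            per-frame fractional shortening, in [0, amplitude]
    onsets_ms    one onset per pacing period
    beats        per-beat table: onset, peak, 5 %-decay end, time_to_peak,
                 relaxation_time, beat_duration (all ms), complete flag
    half_extent_px / pixel_size  set by the renderer, enabling physical
                 boundary displacement and speed
    """

    fps: float
    d: np.ndarray
    onsets_ms: np.ndarray
    beats: pd.DataFrame
    amplitude: float
    half_extent_px: float | None = None
    pixel_size: float | None = None

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.d.size) / self.fps * 1000.0

    @property
    def n_complete_beats(self) -> int:
        return int(self.beats["complete"].sum())

    def tip_displacement_um(self) -> np.ndarray:
        if self.half_extent_px is None or self.pixel_size is None:
            raise ValueError("geometry not attached to this ground truth")
        return self.d * self.half_extent_px * self.pixel_size

    def boundary_speed_um_s(self) -> np.ndarray:
        """|frame-to-frame boundary displacement| x fps, um/s."""
        disp = self.tip_displacement_um()
        return np.abs(np.diff(disp)) * self.fps

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"frame": np.arange(self.d.size), "time_ms": self.times_ms, "d": self.d}
        ).to_csv(path, index=False)


def _rise(s: np.ndarray, ttp: float, amp: float) -> np.ndarray:
    return 0.5 * amp * (1.0 - np.cos(np.pi * s / ttp))


def _decay(s: np.ndarray, span: float, amp: float) -> np.ndarray:
    return amp * np.cos(np.pi * s / (2.0 * span)) ** 2


def make_waveform(
    params: WaveformParams,
    duration: float,
    fps: float,
    seed: int | None = None,
    first_onset_s: float = 0.05,
) -> tuple[np.ndarray, GroundTruth]:
    """Sample d(t) on the frame grid and record the true per-beat anchors."""
    n = int(round(duration * fps))
    if n < 2:
        raise InvalidProtocolError("duration x fps must give at least 2 frames")
    t_ms = np.arange(n) / fps * 1000.0
    period_ms = 1000.0 / params.pacing_frequency
    rng = np.random.default_rng(seed)

    onsets = []
    k = 0
    while True:
        onset = first_onset_s * 1000.0 + k * period_ms
        if onset >= duration * 1000.0:
            break
        if params.baseline_jitter > 0:
            onset += rng.normal(0.0, params.baseline_jitter)
        onsets.append(onset)
        k += 1
    onsets = np.asarray(onsets)

    d = np.zeros(n)
    span = params.decay_span_ms
    rows = []
    for i, onset in enumerate(onsets):
        s = t_ms - onset
        rise_mask = (s >= 0) & (s < params.time_to_peak)
        decay_mask = (s >= params.time_to_peak) & (s <= params.time_to_peak + span)
        d[rise_mask] = np.maximum(
            d[rise_mask], _rise(s[rise_mask], params.time_to_peak, params.amplitude)
        )
        d[decay_mask] = np.maximum(
            d[decay_mask],
            _decay(s[decay_mask] - params.time_to_peak, span, params.amplitude),
        )
        end = onset + params.time_to_peak + params.relaxation_time
        rows.append(
            {
                "beat": i,
                "onset_ms": onset,
                "peak_ms": onset + params.time_to_peak,
                "end_ms": end,
                "time_to_peak_ms": params.time_to_peak,
                "relaxation_time_ms": params.relaxation_time,
                "beat_duration_ms": params.time_to_peak + params.relaxation_time,
                "complete": end <= duration * 1000.0,
            }
        )

    truth = GroundTruth(
        fps=fps,
        d=d,
        onsets_ms=onsets,
        beats=pd.DataFrame(rows),
        amplitude=params.amplitude,
    )
    return d, truth


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

GEOMETRIES = ("banded_rod", "fog_rod", "cardioid")


@dataclass(frozen=True)
class SyntheticSpec:
    """Everything needed to render one clip deterministically."""

    geometry: str = "banded_rod"
    length_um: float = 113.0  # rod length (cells measure ~113 um)
    width_um: float = 25.0  # rod width
    diameter_um: float = 454.13  # cardioid diameter
    band_period_px: float = 12.0
    texture_scale_px: float = 3.0  # speckle correlation length
    waveform: WaveformParams = field(default_factory=WaveformParams)
    duration_s: float = 5.0
    fps: float = 143.0
    frame_shape: tuple[int, int] = (120, 160)  # (height, width) px
    pixel_size: float = 1.0  # um / px
    noise_sd: float = 0.01
    background: float = 0.12
    background_texture: float = 0.04  # static speckle contrast (fixed pattern)
    supersample: int = 4
    first_onset_s: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}")
        if int(round(self.duration_s * self.fps)) < 2:
            raise InvalidProtocolError("duration x fps must give >= 2 frames")

    @property
    def half_extent_px(self) -> float:
        """Half the major extent: rod half-length or cardioid radius, px."""
        if self.geometry == "cardioid":
            return 0.5 * self.diameter_um / self.pixel_size
        return 0.5 * self.length_um / self.pixel_size


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _make_texture_field(spec: SyntheticSpec, rng: np.random.Generator):
    """Pre-computed object-space speckle for fog rods and cardioid surfaces."""
    ext = int(math.ceil(spec.half_extent_px)) + 8
    size = 2 * ext + 1
    noise = rng.standard_normal((size, size))
    tex = gaussian_filter(noise, spec.texture_scale_px)
    lo, hi = tex.min(), tex.max()
    tex = (tex - lo) / (hi - lo) if hi > lo else np.full_like(tex, 0.5)
    return tex, ext


def render_clip(
    spec: SyntheticSpec, effect: TreatmentEffect = CONTROL
) -> tuple[VideoClip, GroundTruth]:
    """Render one ground-truthed clip under a treatment effect.

    Same spec + seed gives bit-identical frames.  Raises RenderError when
    the geometry (at rest, its largest state) does not fit the frame.
    """
    params = effect.apply(spec.waveform)
    h, w = spec.frame_shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    half = spec.half_extent_px
    if spec.geometry == "cardioid":
        if half + 6 > min(cx, cy):
            raise RenderError("cardioid does not fit inside the frame")
        half_y = half
    else:
        half_y = 0.5 * spec.width_um / spec.pixel_size
        if half + 4 > cx or half_y + 4 > cy:
            raise RenderError("rod does not fit inside the frame")

    seeds = np.random.SeedSequence(spec.seed).spawn(3)
    tex_rng = np.random.default_rng(seeds[0])
    noise_rng = np.random.default_rng(seeds[2])
    d, truth = make_waveform(
        params,
        spec.duration_s,
        spec.fps,
        seed=int(seeds[1].generate_state(1)[0] % (2**31)),
        first_onset_s=spec.first_onset_s,
    )
    truth.half_extent_px = half
    truth.pixel_size = spec.pixel_size

    tex = ext = None
    if spec.geometry in ("fog_rod", "cardioid"):
        tex, ext = _make_texture_field(spec, tex_rng)

    # supersampled coordinates over the (static) bounding box of the geometry
    m = spec.supersample
    pad = 6
    x0, x1 = int(max(0, cx - half - pad)), int(min(w, cx + half + pad + 1))
    if spec.geometry == "cardioid":
        y0, y1 = int(max(0, cy - half - pad)), int(min(h, cy + half + pad + 1))
    else:
        y0, y1 = int(max(0, cy - half_y - pad)), int(min(h, cy + half_y + pad + 1))
    xs = x0 + (np.arange((x1 - x0) * m) + 0.5) / m - 0.5
    ys = y0 + (np.arange((y1 - y0) * m) + 0.5) / m - 0.5
    uu_rest, vv_rest = np.meshgrid(xs - cx, ys - cy)  # object coords at scale 1

    n = d.size
    frames = np.empty((n, h, w), dtype=np.float32)
    # static background: flat level plus a fixed-pattern speckle, as a real
    # field of view carries (debris, illumination structure); a perfectly
    # featureless background would be unrealistically hostile to optical flow
    base = np.full((h, w), spec.background, dtype=np.float32)
    if spec.background_texture > 0:
        speck = gaussian_filter(tex_rng.standard_normal((h, w)), 2.0)
        sd = speck.std()
        if sd > 0:
            base += (spec.background_texture * speck / sd).astype(np.float32)

    def downsample(arr):
        return arr.reshape(len(ys) // m, m, len(xs) // m, m).mean(axis=(1, 3))

    for t in range(n):
        s = 1.0 - d[t]
        uu = uu_rest / s
        vv = vv_rest / s if spec.geometry == "cardioid" else vv_rest
        alpha, texture, extra = _render_patch(spec, uu, vv, half, half_y, tex, ext)
        alpha = downsample(alpha)
        texture = downsample(texture)
        frame = base.copy()
        region = frame[y0:y1, x0:x1]
        region *= 1.0 - alpha
        region += alpha * texture
        if extra is not None:
            region += downsample(extra)
        if spec.noise_sd > 0:
            frame += noise_rng.normal(0.0, spec.noise_sd, frame.shape).astype(
                np.float32
            )
        frames[t] = np.clip(frame, 0.0, 1.0)

    clip = VideoClip(frames, fps=spec.fps, pixel_size=spec.pixel_size)
    return clip, truth


def _render_patch(spec, uu, vv, half, half_y, tex, ext):
    """Supersampled (alpha, texture, additive-extra) for one frame's object."""
    edge = 1.0
    if spec.geometry == "banded_rod":
        mask = _smoothstep((half - np.abs(uu)) / edge) * _smoothstep(
            (half_y - np.abs(vv)) / edge
        )
        bx = 0.5 * (1.0 + np.cos(2.0 * np.pi * uu / spec.band_period_px))
        by = 0.5 * (1.0 + np.cos(2.0 * np.pi * vv / (2.0 * spec.band_period_px)))
        texture = 0.75 * (0.30 + 0.70 * bx) * (0.55 + 0.45 * by)
        return mask, texture, None
    if spec.geometry == "fog_rod":
        edge = 2.5  # diffuse phase-contrast boundary
        mask = _smoothstep((half - np.abs(uu)) / edge) * _smoothstep(
            (half_y - np.abs(vv)) / edge
        )
        coords = np.array([vv + ext, uu + ext])
        speckle = map_coordinates(tex, coords, order=1, mode="nearest")
        texture = 0.30 + 0.50 * speckle
        return mask, texture, None
    # cardioid: shaded disc + speckle + bright phase-contrast halo
    r = np.sqrt(uu**2 + vv**2)
    mask = _smoothstep((half - r) / 1.5)
    coords = np.array([vv + ext, uu + ext])
    speckle = map_coordinates(tex, coords, order=1, mode="nearest")
    shading = 1.0 - 0.55 * (np.clip(r / half, 0, 1)) ** 2
    texture = (0.30 + 0.35 * shading) + 0.18 * (speckle - 0.5)
    halo = 0.10 * np.exp(-(((r - 1.04 * half) / 2.5) ** 2))
    return mask, texture, halo


# ---------------------------------------------------------------------------
# Benchmark protocols
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BenchmarkProtocol:
    """A frequency x treatment-arm x replicate grid of clips."""

    name: str
    spec: SyntheticSpec
    frequencies: tuple[float, ...]
    treatment: str = "caffeine_like"
    replicates: int = 3
    master_seed: int = 0

    @property
    def arms(self) -> tuple[str, str]:
        return ("control", self.treatment)


@dataclass
class BenchmarkItem:
    clip: VideoClip
    truth: GroundTruth
    label: dict


def cells_spec(**overrides) -> SyntheticSpec:
    """Single-cell conditions: banded rod, 5 s at 143 fps, 160x120 px."""
    defaults = dict(
        geometry="banded_rod",
        duration_s=5.0,
        fps=143.0,
        frame_shape=(120, 160),
        pixel_size=1.0,
        waveform=WaveformParams(
            amplitude=0.08, time_to_peak=120.0, relaxation_time=200.0
        ),
    )
    defaults.update(overrides)
    return SyntheticSpec(**defaults)


def cardioid_spec(**overrides) -> SyntheticSpec:
    """Cardioid conditions: 454 um spheroid, 10 s at 143 fps, 160x160 px."""
    defaults = dict(
        geometry="cardioid",
        duration_s=10.0,
        fps=143.0,
        frame_shape=(160, 160),
        pixel_size=4.0,
        waveform=WaveformParams(
            amplitude=0.05,
            time_to_peak=250.0,
            relaxation_time=350.0,
            pacing_frequency=1.0,
        ),
    )
    defaults.update(overrides)
    return SyntheticSpec(**defaults)


def cells_protocol(
    treatment: str = "caffeine_like", replicates: int = 3, master_seed: int = 0, **spec_overrides
) -> BenchmarkProtocol:
    return BenchmarkProtocol(
        name="cells",
        spec=cells_spec(**spec_overrides),
        frequencies=(0.5, 1.0, 2.0),
        treatment=treatment,
        replicates=replicates,
        master_seed=master_seed,
    )


def cardioid_protocol(
    treatment: str = "caffeine_like", replicates: int = 3, master_seed: int = 0, **spec_overrides
) -> BenchmarkProtocol:
    return BenchmarkProtocol(
        name="cardioid",
        spec=cardioid_spec(**spec_overrides),
        frequencies=(0.5, 0.75, 1.0),
        treatment=treatment,
        replicates=replicates,
        master_seed=master_seed,
    )


def iter_benchmark(protocol: BenchmarkProtocol) -> Iterator[BenchmarkItem]:
    """Yield one labelled clip per (frequency x arm x replicate).

    Reproducible from the master seed; per-clip seeds are derived with a
    SeedSequence so the collection is byte-identical across runs.
    """
    combos = [
        (f, arm, rep)
        for f in protocol.frequencies
        for arm in protocol.arms
        for rep in range(protocol.replicates)
    ]
    child_seeds = np.random.SeedSequence(protocol.master_seed).spawn(len(combos))
    for (freq, arm, rep), ss in zip(combos, child_seeds):
        wf = replace(protocol.spec.waveform, pacing_frequency=freq)
        seed = int(ss.generate_state(1)[0] % (2**31))
        spec = replace(protocol.spec, waveform=wf, seed=seed)
        effect = preset_effect(arm, wf) if arm != "control" else CONTROL
        clip, truth = render_clip(spec, effect)
        yield BenchmarkItem(
            clip=clip,
            truth=truth,
            label={
                "sample_type": protocol.name,
                "frequency": freq,
                "arm": arm,
                "treatment": protocol.treatment,
                "label": 0 if arm == "control" else 1,
                "replicate": rep,
                "seed": seed,
            },
        )


def generate_benchmark(protocol: BenchmarkProtocol) -> list[BenchmarkItem]:
    return list(iter_benchmark(protocol))


# ---------------------------------------------------------------------------
# Feature-level simulation (per-beat tables without rendering)
# ---------------------------------------------------------------------------

FEATURES = (
    "beat_duration_ms",
    "t_theta_c_ms",
    "t_theta_r_ms",
    "t_theta_cr_ms",
    "contraction_peak",
    "relaxation_peak",
)

# plausible per-beat feature means and SDs (times ms, magnitudes um/s)
_FEATURE_BASE = {
    "beat_duration_ms": (800.0, 60.0),
    "t_theta_c_ms": (120.0, 15.0),
    "t_theta_r_ms": (220.0, 25.0),
    "t_theta_cr_ms": (330.0, 35.0),
    "contraction_peak": (120.0, 20.0),
    "relaxation_peak": (100.0, 18.0),
}


def sample_beat_features(
    n_per_class: int,
    effect_sd: float = 0.0,
    seed: int | None = None,
    shifted_features: tuple[str, str] = ("beat_duration_ms", "contraction_peak"),
) -> pd.DataFrame:
    """Draw a labelled per-beat feature table from Gaussian class models.

    ``effect_sd`` shifts the treated class by that many pooled SDs on the
    two ``shifted_features``; 0 gives two identical distributions (the null
    used for classifier calibration checks).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for label in (0, 1):
        for _ in range(n_per_class):
            row = {"label": label}
            for feat, (mu, sd) in _FEATURE_BASE.items():
                shift = effect_sd * sd if (label == 1 and feat in shifted_features) else 0.0
                row[feat] = rng.normal(mu + shift, sd)
            rows.append(row)
    return pd.DataFrame(rows)


def benchmark_feature_tables(
    protocols: Iterable[BenchmarkProtocol] | None = None,
    trackers: tuple[str, ...] = ("intensity", "flow", "marker"),
    master_seed: int = 0,
    measurement_jitter_ms: float = 3.5,
) -> pd.DataFrame:
    """Per-beat kinematic tables for a full benchmark, without rendering.

    Applies the real beat-analysis code to the analytic deformation trace of
    every (sample type, frequency, arm, replicate) combination, then emulates
    the three measurement channels by adding independent seeded jitter (half a
    frame period on times, 2 % on magnitudes) per tracker.  The output matches
    the schema of the video pipeline's per-beat table and feeds dataset
    assembly and classification.
    """
    from . import beats as _beats
    from .profiles import ContractionProfile

    if protocols is None:
        protocols = (cells_protocol(master_seed=master_seed),
                     cardioid_protocol(master_seed=master_seed))
    rng = np.random.default_rng(master_seed)
    rows = []
    for proto in protocols:
        for freq in proto.frequencies:
            for arm in proto.arms:
                for rep in range(proto.replicates):
                    wf = replace(proto.spec.waveform, pacing_frequency=freq)
                    effect = preset_effect(arm, wf) if arm != "control" else CONTROL
                    params = effect.apply(wf)
                    d, _ = make_waveform(
                        params, proto.spec.duration_s, proto.spec.fps
                    )
                    contraction = ContractionProfile(
                        d * proto.spec.half_extent_px * proto.spec.pixel_size,
                        fps=proto.spec.fps,
                        source="marker",
                        units="um",
                    )
                    speed = _beats.derivative(contraction)
                    beats = _beats.segment_beats(
                        speed, contraction, pacing_hint=freq
                    )
                    for b in beats:
                        p = _beats.beat_parameters(b, speed, contraction)
                        for tracker in trackers:
                            jit = rng.normal(0.0, measurement_jitter_ms, 4)
                            mag = rng.normal(1.0, 0.02, 2)
                            rows.append(
                                {
                                    "sample_type": proto.name,
                                    "frequency": freq,
                                    "arm": arm,
                                    "replicate": rep,
                                    "tracker": tracker,
                                    "beat": b.index,
                                    "label": 0 if arm == "control" else 1,
                                    "beat_duration_ms": p.beat_duration + jit[0],
                                    "t_theta_c_ms": p.t_theta_c + jit[1],
                                    "t_theta_r_ms": p.t_theta_r + jit[2],
                                    "t_theta_cr_ms": p.t_theta_cr + jit[3],
                                    "contraction_peak": p.contraction_peak_magnitude
                                    * mag[0],
                                    "relaxation_peak": p.relaxation_peak_magnitude
                                    * mag[1],
                                }
                            )
    return pd.DataFrame(rows)
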