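"""Beat segmentation and kinematic parameter extraction.

Shared post-processing for all three trackers.  Every beat is described by
five anchor points on the contraction profile and its rectified first
derivative (the speed profile, theta):

    A  contraction onset (first sample above a small fraction of the peak)
    B  contraction-speed peak (maximum ascending slope of the contraction)
    C  contraction-profile peak, i.e. the start of the relaxation limb
    D  relaxation-speed peak (maximum descending slope)
    E  beat end: contraction decayed to 5 % of the beat's peak

and by six derived parameters:

    beat duration          E - A
    t[theta_c]             B - A   time to the contraction-speed peak
    t[theta_r]             D - C   relaxation onset to relaxation-speed peak
    t[theta_c-r]           D - B   distance between the two speed peaks
    contraction peak magnitude     speed at B
    relaxation peak magnitude      speed at D

All speed profiles are rectified (absolute values) by convention, so both
magnitudes are non-negative.  The default forward-difference derivative is
timestamped at the left frame, deliberately reproducing the slight temporal
anticipation a ratio-of-increments derivative carries; a central-difference
scheme is available when that bias is unwanted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import percentile_filter
from scipy.signal import find_peaks

from .errors import EmptySummaryError, MissingAnchorError
from .profiles import ContractionProfile, SpeedProfile

__all__ = [
    "Beat",
    "BeatParameters",
    "derivative",
    "segment_beats",
    "beat_parameters",
    "summarize_beats",
    "time_to_peak",
    "beats_table",
]

PARAMETER_COLUMNS = (
    "beat_duration_ms",
    "t_theta_c_ms",
    "t_theta_r_ms",
    "t_theta_cr_ms",
    "contraction_peak",
    "relaxation_peak",
)


@dataclass
class Beat:
    """One segmented beat: sample range plus the five anchors in ms."""

    index: int
    start: int  # sample index of A on the contraction profile
    end: int  # sample index of E
    A_ms: float
    B_ms: float
    C_ms: float
    D_ms: float
    E_ms: float
    peak_value: float  # contraction-profile value at C


@dataclass
class BeatParameters:
    """The four interval and two magnitude features of one beat."""

    beat_duration: float  # ms, E - A
    t_theta_c: float  # ms, B - A
    t_theta_r: float  # ms, D - C
    t_theta_cr: float  # ms, D - B
    contraction_peak_magnitude: float  # speed units at B
    relaxation_peak_magnitude: float  # speed units at D


def derivative(profile: ContractionProfile, scheme: str = "forward") -> SpeedProfile:
    """Rectified first derivative of a contraction profile, per-second units.

    ``forward`` (default): |x[i+1] - x[i]| * fps at the time of sample i —
    the anticipated timestamp.  ``central``: |x[i+1] - x[i-1]| / 2 * fps at
    sample i, bias-free but one sample shorter on each side.
    """
    x = profile.values
    if x.size < 2:
        raise ValueError("profile needs at least 2 samples")
    fps = profile.fps
    units = f"{profile.units}/s" if profile.units != "a.u." else "a.u./s"
    if scheme == "forward":
        vals = np.abs(np.diff(x)) * fps
        times = np.arange(x.size - 1) / fps * 1000.0
    elif scheme == "central":
        vals = np.abs(x[2:] - x[:-2]) * 0.5 * fps
        times = np.arange(1, x.size - 1) / fps * 1000.0
    else:
        raise ValueError(f"unknown derivative scheme {scheme!r}")
    return SpeedProfile(vals, times, fps=fps, units=units, source="derivative")


def _smooth3(x: np.ndarray) -> np.ndarray:
    if x.size < 3:
        return x.copy()
    out = x.copy()
    out[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    return out


def segment_beats(
    speed: SpeedProfile,
    contraction: ContractionProfile,
    pacing_hint: float | None = None,
    onset_epsilon: float = 0.05,
) -> list[Beat]:
    """Split the contraction profile into beats and anchor each one.

    Onset A is the first sample exceeding ``onset_epsilon`` times the beat's
    peak (the noise-robust reading of "first value different from zero");
    the end E is the first sample after the relaxation-speed peak where the
    contraction has decayed to <= 5 % of that beat's peak.  Beats are found
    as contraction-profile peaks separated by at least half a pacing period
    when a pacing hint is given, else by prominence.  Incomplete trailing
    beats (no 5 % decay before the record ends) are dropped.
    """
    c_raw = contraction.values
    c = _smooth3(c_raw)
    fps = contraction.fps
    if c.max() - c.min() <= 0:
        return []
    # Peak finding runs on a detrended copy: a rolling low-quantile baseline
    # is subtracted so that the slow drift a flow-integrated trace can carry
    # does not inflate the range the prominence threshold is scaled by.
    # (window of 1.5 pacing periods always exceeds one beat; without a hint
    # the beat width is unknown, so only a constant quantile is removed)
    if pacing_hint:
        win = min(c.size, max(3, int(round(1.5 * fps / pacing_hint))))
        detrended = c - percentile_filter(c, 10, size=win)
    else:
        detrended = c - np.percentile(c, 10)
    span = detrended.max() - detrended.min()
    if span <= 0:
        return []
    if pacing_hint:
        distance = max(1, int(round(0.5 / pacing_hint * fps)))
        peaks, _ = find_peaks(detrended, distance=distance, prominence=0.3 * span)
    else:
        peaks, _ = find_peaks(detrended, prominence=0.3 * span)
    if peaks.size == 0:
        return []

    beats: list[Beat] = []
    for bi, p in enumerate(peaks):
        # Diastolic baseline, local to the beat: a robust low quantile of the
        # profile between the neighbouring peaks.  A global min would sit at
        # the intensity tracker's isolated zero (the reference frame), below
        # the diastolic noise floor, and a global quantile breaks on the slow
        # drift the flow-integrated trace can carry.
        w0 = peaks[bi - 1] if bi > 0 else 0
        w1 = peaks[bi + 1] if bi + 1 < peaks.size else c_raw.size
        # separate pre- and post-peak baselines so a slow drift of the
        # diastolic level (flow-integrated traces) cannot strand the 5 %
        # decay criterion above the post-beat diastole
        base_pre = float(np.percentile(c[w0 : p + 1], 10))
        base_post = float(np.percentile(c[p:w1], 10))
        peak_val = c_raw[p] - base_pre
        if peak_val <= 0 or c_raw[p] - base_post <= 0:
            continue
        onset_level = base_pre + onset_epsilon * peak_val
        end_level = base_post + 0.05 * (c_raw[p] - base_post)

        # walk left to the onset: last sample at/below the onset level
        a = p
        while a > 0 and c_raw[a - 1] > onset_level:
            a -= 1
        prev_end = beats[-1].end if beats else 0
        a = max(a, prev_end)

        # walk right to the 5 % decay
        next_peak = peaks[bi + 1] if bi + 1 < peaks.size else c_raw.size
        e = None
        for j in range(p + 1, next_peak):
            if c_raw[j] <= end_level:
                e = j
                break
        if e is None:
            continue  # incomplete trailing beat (or fused with the next)

        anchors = _locate_speed_peaks(speed, c, a, p, e, fps)
        if anchors is None:
            continue
        B_ms, D_ms = anchors
        beats.append(
            Beat(
                index=len(beats),
                start=a,
                end=e,
                A_ms=a / fps * 1000.0,
                B_ms=B_ms,
                C_ms=p / fps * 1000.0,
                D_ms=D_ms,
                E_ms=e / fps * 1000.0,
                peak_value=float(c_raw[p]),
            )
        )
    return beats


def _locate_speed_peaks(speed, c_smooth, a, p, e, fps):
    """Times of the max rectified speed on the ascending / descending limbs."""
    t_a = a / fps * 1000.0
    t_p = p / fps * 1000.0
    t_e = e / fps * 1000.0
    asc = (speed.times_ms >= t_a) & (speed.times_ms <= t_p)
    desc = (speed.times_ms >= t_p) & (speed.times_ms <= t_e)
    if not asc.any() or not desc.any():
        return None
    b_idx = np.flatnonzero(asc)[np.argmax(speed.values[asc])]
    d_idx = np.flatnonzero(desc)[np.argmax(speed.values[desc])]
    return float(speed.times_ms[b_idx]), float(speed.times_ms[d_idx])


def beat_parameters(
    beat: Beat, speed: SpeedProfile, contraction: ContractionProfile
) -> BeatParameters:
    """Compute the 4 interval + 2 magnitude features of a segmented beat.

    B and D are re-read from the speed profile at the beat's anchor times;
    magnitudes come from the raw (unsmoothed) rectified speed.  A beat with
    no distinct ascending or descending phase raises MissingAnchorError.
    """
    asc = (speed.times_ms >= beat.A_ms) & (speed.times_ms <= beat.C_ms)
    desc = (speed.times_ms >= beat.C_ms) & (speed.times_ms <= beat.E_ms)
    if not asc.any() or not desc.any():
        raise MissingAnchorError(
            f"beat {beat.index}: no samples on one limb (monotone beat?)"
        )
    b_idx = np.flatnonzero(asc)[np.argmax(speed.values[asc])]
    d_idx = np.flatnonzero(desc)[np.argmax(speed.values[desc])]
    B_ms = float(speed.times_ms[b_idx])
    D_ms = float(speed.times_ms[d_idx])
    return BeatParameters(
        beat_duration=beat.E_ms - beat.A_ms,
        t_theta_c=B_ms - beat.A_ms,
        t_theta_r=D_ms - beat.C_ms,
        t_theta_cr=D_ms - B_ms,
        contraction_peak_magnitude=float(speed.values[b_idx]),
        relaxation_peak_magnitude=float(speed.values[d_idx]),
    )


def time_to_peak(
    contraction: ContractionProfile,
    beat: Beat,
    onset_epsilon: float = 0.05,
    interpolate: bool = True,
) -> float:
    """Onset-to-peak interval of one beat, in ms.

    With ``interpolate`` the contraction peak is refined by a 3-point
    parabola and the onset by linear interpolation of the epsilon-crossing,
    giving sub-frame precision on smooth profiles; otherwise both anchors
    sit on the frame grid.
    """
    c = contraction.values
    fps = contraction.fps
    p = int(round(beat.C_ms / 1000.0 * fps))
    lo = max(beat.start, p - 1)
    hi = min(beat.end, p + 1)
    p = lo + int(np.argmax(c[lo : hi + 1]))
    if not interpolate:
        return beat.C_ms - beat.A_ms

    peak_t = p / fps * 1000.0
    if 0 < p < c.size - 1:
        f0, f1, f2 = c[p - 1], c[p], c[p + 1]
        denom = f0 - 2 * f1 + f2
        if denom < 0:
            peak_t += 0.5 * (f0 - f2) / denom / fps * 1000.0

    # beat-local diastolic baseline (consistent with segment_beats)
    w0 = max(0, beat.start - (beat.end - beat.start))
    baseline = float(np.percentile(_smooth3(c)[w0 : beat.end + 1], 10))
    level = baseline + onset_epsilon * (c[p] - baseline)
    a = int(round(beat.A_ms / 1000.0 * fps))
    onset_t = a / fps * 1000.0
    if a > 0 and c[a] > level >= c[a - 1]:
        frac = (level - c[a - 1]) / (c[a] - c[a - 1])
        onset_t = (a - 1 + frac) / fps * 1000.0
    return peak_t - onset_t


def summarize_beats(beats: list[BeatParameters]) -> pd.DataFrame:
    """Per-video mean +- SD table over beats (data reported as mean +- SD)."""
    if not beats:
        raise EmptySummaryError("no beats to summarize")
    table = pd.DataFrame(
        {
            "beat_duration_ms": [b.beat_duration for b in beats],
            "t_theta_c_ms": [b.t_theta_c for b in beats],
            "t_theta_r_ms": [b.t_theta_r for b in beats],
            "t_theta_cr_ms": [b.t_theta_cr for b in beats],
            "contraction_peak": [b.contraction_peak_magnitude for b in beats],
            "relaxation_peak": [b.relaxation_peak_magnitude for b in beats],
        }
    )
    out = pd.DataFrame(
        {"mean": table.mean(), "sd": table.std(ddof=1).fillna(0.0)}
    )
    out.attrs["n_beats"] = len(beats)
    return out


def beats_table(
    beats: list[Beat],
    speed: SpeedProfile,
    contraction: ContractionProfile,
    video_id: str = "",
    tracker: str = "",
) -> pd.DataFrame:
    """Flat per-beat table (one row per beat) in the package's CSV schema."""
    rows = []
    for b in beats:
        p = beat_parameters(b, speed, contraction)
        rows.append(
            {
                "video_id": video_id,
                "tracker": tracker,
                "beat_index": b.index,
                "A_ms": b.A_ms,
                "B_ms": b.B_ms,
                "C_ms": b.C_ms,
                "D_ms": b.D_ms,
                "E_ms": b.E_ms,
                "beat_duration_ms": p.beat_duration,
                "t_theta_c_ms": p.t_theta_c,
                "t_theta_r_ms": p.t_theta_r,
                "t_theta_cr_ms": p.t_theta_cr,
                "contraction_peak": p.contraction_peak_magnitude,
                "relaxation_peak": p.relaxation_peak_magnitude,
            }
        )
    return pd.DataFrame(rows)
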