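"""Marker/kernel tracking of local kinematics (ViKiE-style).

A marker is an image patch ("kernel") captured on the first frame and
followed through the clip by normalized cross-correlation inside a search
window around its previous position, refined to sub-pixel precision by
quadratic interpolation of the correlation peak.  Displacement and speed
derive from the trajectory, so the measurement is local to the marked
region — by design, unlike the whole-frame intensity and flow trackers.

Coordinates follow the package-wide convention: origin at the upper-left
corner of the first frame, x right, y down, units px.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from skimage.feature import match_template

from .errors import LostTrackError, PlacementError, LowConfidenceWarning
from .io import VideoClip
from .profiles import ContractionProfile, SpeedProfile

__all__ = [
    "Marker",
    "MarkerTrajectory",
    "place_markers",
    "track_markers",
    "marker_speed_profile",
]

KERNELS = ("patch", "disc", "cone")


@dataclass
class Marker:
    """An initialized tracking kernel: position, radius and reference patch."""

    x: float
    y: float
    radius: int
    kernel: str = "patch"
    patch: np.ndarray | None = None
    weight: np.ndarray | None = None


@dataclass
class MarkerTrajectory:
    """Sub-pixel (x, y) per frame plus the per-frame correlation score."""

    xs: np.ndarray
    ys: np.ndarray
    scores: np.ndarray
    fps: float
    radius: int
    kernel: str = "patch"

    def __post_init__(self):
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if not (self.xs.shape == self.ys.shape == self.scores.shape):
            raise ValueError("xs, ys, scores must align")

    def __len__(self) -> int:
        return self.xs.size

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.xs.size) / self.fps * 1000.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.xs.size),
                "time_ms": self.times_ms,
                "x_px": self.xs,
                "y_px": self.ys,
                "score": self.scores,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _kernel_weight(kernel: str, radius: int) -> np.ndarray:
    """Radial weighting applied to the patch; 'patch' is uniform."""
    size = 2 * radius + 1
    yy, xx = np.mgrid[0:size, 0:size] - radius
    r = np.hypot(xx, yy)
    if kernel == "patch":
        return np.ones((size, size))
    if kernel == "disc":
        return (r <= radius).astype(float)
    if kernel == "cone":
        return np.clip(1.0 - r / (radius + 1), 0.0, 1.0)
    raise ValueError(f"unknown kernel {kernel!r}; choose from {KERNELS}")


def _extract_patch(frame: np.ndarray, x: float, y: float, radius: int) -> np.ndarray:
    xi, yi = int(round(x)), int(round(y))
    return frame[yi - radius : yi + radius + 1, xi - radius : xi + radius + 1].copy()


def place_markers(
    clip: VideoClip,
    mode: str = "auto_contrast",
    coords: list[tuple[float, float]] | None = None,
    radius: int = 8,
    k: int = 1,
    kernel: str = "patch",
) -> list[Marker]:
    """Initialize markers on frame 0.

    ``manual`` places markers at the given (x, y) coordinates;
    ``auto_contrast`` picks the top-k non-overlapping patches by local
    intensity variance (high-contrast regions track best).  A featureless
    frame yields no markers and a LowConfidenceWarning.
    """
    frame = clip.frames[0]
    h, w = frame.shape
    weight = _kernel_weight(kernel, radius)

    def init(x: float, y: float) -> Marker:
        if not (radius <= x < w - radius and radius <= y < h - radius):
            raise PlacementError(
                f"marker at ({x}, {y}) (radius {radius}) falls outside the frame"
            )
        patch = _extract_patch(frame, x, y, radius)
        return Marker(x=float(x), y=float(y), radius=radius, kernel=kernel,
                      patch=patch, weight=weight)

    if mode == "manual":
        if not coords:
            raise PlacementError("manual placement requires coords")
        return [init(x, y) for x, y in coords]
    if mode != "auto_contrast":
        raise ValueError(f"unknown placement mode {mode!r}")

    size = 2 * radius + 1
    local_mean = uniform_filter(frame, size)
    local_var = uniform_filter(frame**2, size) - local_mean**2
    if local_var.max() < 1e-10:
        warnings.warn("featureless frame: no markers placed", LowConfidenceWarning)
        return []
    # greedy non-overlapping selection, borders excluded
    var = local_var.copy()
    var[:radius, :] = -np.inf
    var[-radius:, :] = -np.inf
    var[:, :radius] = -np.inf
    var[:, -radius:] = -np.inf
    markers = []
    for _ in range(k):
        idx = np.argmax(var)
        if not np.isfinite(var.flat[idx]) or var.flat[idx] <= 0:
            break
        y, x = np.unravel_index(idx, var.shape)
        markers.append(init(float(x), float(y)))
        y0, y1 = max(0, y - size), min(h, y + size + 1)
        x0, x1 = max(0, x - size), min(w, x + size + 1)
        var[y0:y1, x0:x1] = -np.inf
    return markers


def _ncc_map(window: np.ndarray, patch: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Weighted normalized cross-correlation of `patch` at every valid shift.

    Uniform weights (the default 'patch' kernel) go through scikit-image's
    FFT-based matcher; radially weighted kernels use the direct sum.
    """
    if np.all(weight == 1.0):
        out = match_template(window, patch, pad_input=False)
        return np.clip(out, -1.0, 1.0)
    ph, pw = patch.shape
    wh, ww = window.shape
    out = np.full((wh - ph + 1, ww - pw + 1), -1.0)
    wsum = weight.sum()
    p = (patch - (patch * weight).sum() / wsum) * weight
    pnorm = np.sqrt((p * p / np.where(weight > 0, weight, 1)).sum())
    if pnorm < 1e-12:
        return out
    for j in range(out.shape[0]):
        for i in range(out.shape[1]):
            win = window[j : j + ph, i : i + pw]
            q = (win - (win * weight).sum() / wsum) * weight
            qnorm = np.sqrt((q * q / np.where(weight > 0, weight, 1)).sum())
            if qnorm < 1e-12:
                continue
            out[j, i] = (p * q / np.where(weight > 0, weight, 1)).sum() / (
                pnorm * qnorm
            )
    return out


def _quad_refine(values: np.ndarray, idx: int) -> float:
    """Sub-sample offset of a peak by a 3-point parabola; 0 at the edges."""
    if idx <= 0 or idx >= values.size - 1:
        return 0.0
    f0, f1, f2 = values[idx - 1], values[idx], values[idx + 1]
    denom = f0 - 2 * f1 + f2
    if denom >= 0:
        return 0.0
    off = 0.5 * (f0 - f2) / denom
    return float(np.clip(off, -0.5, 0.5))


def track_markers(
    clip: VideoClip,
    markers: list[Marker],
    search_radius: int = 5,
    score_floor: float = 0.5,
    max_low_frames: int = 5,
    refresh_every: int | None = None,
) -> list[MarkerTrajectory]:
    """Follow each marker through the clip by windowed NCC.

    Candidate displacements per frame are bounded by ``search_radius`` (the
    maximum expected inter-frame motion, default 5 px; the pixel window
    actually correlated spans the marker radius plus that bound).  Keeping
    the bound below the texture period is what prevents locking onto a
    neighbouring band of a periodic pattern.  Ties at equal correlation
    resolve to the smallest displacement.  If the correlation stays below
    ``score_floor`` for more than ``max_low_frames`` consecutive frames the
    track is declared lost (LostTrackError names the frame).
    ``refresh_every`` re-captures the reference patch every k frames (off
    by default to avoid drift accumulation).
    """
    trajectories = []
    h, w = clip.shape
    for marker in markers:
        r = marker.radius
        sr = search_radius
        patch = marker.patch
        weight = marker.weight
        xs = [marker.x]
        ys = [marker.y]
        scores = [1.0]
        low_run = 0
        for t in range(1, clip.n_frames):
            frame = clip.frames[t]
            cx, cy = xs[-1], ys[-1]
            xi, yi = int(round(cx)), int(round(cy))
            x0 = max(r, xi - sr)
            x1 = min(w - r - 1, xi + sr)
            y0 = max(r, yi - sr)
            y1 = min(h - r - 1, yi + sr)
            window = frame[y0 - r : y1 + r + 1, x0 - r : x1 + r + 1]
            ncc = _ncc_map(window, patch, weight)
            # candidate centre positions for each correlation entry
            cand_y = np.arange(y0, y1 + 1)
            cand_x = np.arange(x0, x1 + 1)
            peak = ncc.max()
            close = np.argwhere(ncc >= peak - 1e-12)
            # tie-break: smallest displacement from the previous position
            d2 = (cand_y[close[:, 0]] - cy) ** 2 + (cand_x[close[:, 1]] - cx) ** 2
            j, i = close[np.argmin(d2)]
            if peak >= 1.0 - 1e-9:
                # exact match (static frame or integer translation): the
                # parabola fit would add a spurious sub-pixel offset
                off_y = off_x = 0.0
            else:
                off_y = _quad_refine(ncc[:, i], j)
                off_x = _quad_refine(ncc[j, :], i)
            new_x = float(np.clip(cand_x[i] + off_x, 0, w - 1))
            new_y = float(np.clip(cand_y[j] + off_y, 0, h - 1))
            xs.append(new_x)
            ys.append(new_y)
            scores.append(float(peak))
            if peak < score_floor:
                low_run += 1
                if low_run > max_low_frames:
                    raise LostTrackError(frame=t, score=float(peak))
            else:
                low_run = 0
            if refresh_every and t % refresh_every == 0:
                patch = _extract_patch(frame, new_x, new_y, r)
        trajectories.append(
            MarkerTrajectory(
                xs=np.array(xs), ys=np.array(ys), scores=np.array(scores),
                fps=clip.fps, radius=r, kernel=marker.kernel,
            )
        )
    return trajectories


def marker_speed_profile(
    traj: MarkerTrajectory, pixel_size: float, fps: float
) -> tuple[SpeedProfile, ContractionProfile]:
    """Speed (um/s) and displacement-from-rest (um) of one trajectory.

    The contraction profile is the Euclidean distance of the marker from its
    frame-0 position times the pixel size; the speed is the rectified frame-
    to-frame step length times pixel size and frame rate, timestamped at
    inter-frame midpoints.
    """
    disp = np.hypot(traj.xs - traj.xs[0], traj.ys - traj.ys[0]) * pixel_size
    contraction = ContractionProfile(disp, fps=fps, source="marker", units="um")
    steps = np.hypot(np.diff(traj.xs), np.diff(traj.ys)) * pixel_size * fps
    times_ms = (np.arange(steps.size) + 0.5) / fps * 1000.0
    speed = SpeedProfile(steps, times_ms, fps=fps, units="um/s", source="marker")
    return speed, contraction


def mean_profiles(
    profiles: list[tuple[SpeedProfile, ContractionProfile]]
) -> tuple[SpeedProfile, ContractionProfile]:
    """Element-wise mean across markers, for multi-marker clips."""
    if not profiles:
        raise ValueError("no profiles to aggregate")
    speeds = np.mean([p[0].values for p in profiles], axis=0)
    contractions = np.mean([p[1].values for p in profiles], axis=0)
    s0, c0 = profiles[0]
    return (
        SpeedProfile(speeds, s0.times_ms, fps=s0.fps, units=s0.units, source="marker"),
        ContractionProfile(contractions, fps=c0.fps, source="marker", units=c0.units),
    )
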