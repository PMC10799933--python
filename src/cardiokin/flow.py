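"""Dense optical-flow speed profile (CONTRACTIONWAVE-style).

The speed of contraction is the mean magnitude of the per-pixel displacement
field between successive frames, converted to physical units by the pixel
size and frame rate.  The mean runs over *all* pixels of the image, so a
static background dilutes the magnitude but not the timing; a foreground
mask option exists for users who want the motion restricted to the sample.

Two backends estimate the field:

``ilk``
    iterative Lucas-Kanade dense flow (scikit-image), the default — fast
    and sub-0.01 px accurate on smooth textures at the sub-pixel motions
    beating samples produce;
``block``
    an in-repo exhaustive block-matching search (integer displacement plus
    parabolic sub-pixel refinement).  Deliberately independent of any flow
    library, it serves as the test oracle for the translation contract and
    as a fallback.

Correctness is defined by that contract — for a pure translation of a
textured region, the mean estimated vector must be within 0.25 px of the
truth per component — not by a particular algorithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, sobel
from skimage.registration import optical_flow_ilk

from .errors import LowConfidenceWarning
from .io import VideoClip
from .profiles import ContractionProfile, SpeedProfile

__all__ = [
    "FlowField",
    "dense_flow",
    "block_matching_flow",
    "flow_profiles",
    "flow_speed_profile",
    "flow_contraction_profile",
]

# intensity spread below which a frame pair is treated as featureless
_TEXTURE_FLOOR = 1e-6


@dataclass
class FlowField:
    """Per-pixel displacement between two frames (x right, y down, px)."""

    dx: np.ndarray
    dy: np.ndarray

    def __post_init__(self):
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        if self.dx.shape != self.dy.shape or self.dx.ndim != 2:
            raise ValueError("dx and dy must be matching 2-D arrays")
        if not (np.all(np.isfinite(self.dx)) and np.all(np.isfinite(self.dy))):
            raise ValueError("flow field contains non-finite values")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.dx, self.dy)


def dense_flow(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    backend: str = "ilk",
    radius: int = 5,
    num_warp: int = 2,
) -> FlowField:
    """Estimate per-pixel displacement of the content from frame_a to frame_b.

    Positive dx moves right, positive dy moves down (upper-left origin).
    Featureless (constant) frames yield a zero field and a
    LowConfidenceWarning instead of a numerical blow-up.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("frames must be two 2-D arrays of the same shape")
    if a.std() < _TEXTURE_FLOOR or b.std() < _TEXTURE_FLOOR:
        warnings.warn(
            "featureless frame(s): returning zero flow", LowConfidenceWarning
        )
        return FlowField(np.zeros_like(a), np.zeros_like(a))
    if backend == "ilk":
        # optical_flow_ilk(ref, moving) returns (v_row, v_col) such that
        # moving(r + v_row, c + v_col) ~= ref(r, c); with ref = frame_a this
        # is exactly the content displacement a -> b.
        v = optical_flow_ilk(a, b, radius=radius, num_warp=num_warp)
        return FlowField(dx=v[1], dy=v[0])
    if backend == "block":
        return block_matching_flow(a, b)
    raise ValueError(f"unknown flow backend {backend!r}")


def block_matching_flow(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    block_size: int = 16,
    search_radius: int = 5,
) -> FlowField:
    """Exhaustive block-matching flow with parabolic sub-pixel refinement.

    For every block of ``frame_a`` the integer shift minimizing the SSD
    against ``frame_b`` is found over a (2r+1)^2 window, then refined to
    sub-pixel precision by fitting a parabola through the SSD values on
    either side of the minimum along each axis.  The per-block vector is
    broadcast to its pixels so the output aligns with the frame shape.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    h, w = a.shape
    r = search_radius
    ny = max(1, h // block_size)
    nx = max(1, w // block_size)

    shifts = [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1)]
    # SSD of every block for every candidate shift, vectorized over pixels
    ssd = np.full((len(shifts), ny, nx), np.inf)
    core = a[: ny * block_size, : nx * block_size]
    for k, (dy, dx) in enumerate(shifts):
        ys = slice(max(0, dy), min(h, h + dy))
        yd = slice(max(0, -dy), min(h, h - dy))
        xs = slice(max(0, dx), min(w, w + dx))
        xd = slice(max(0, -dx), min(w, w - dx))
        diff2 = np.full((h, w), np.nan)
        diff2[yd, xd] = (b[ys, xs] - a[yd, xd]) ** 2
        diff2 = diff2[: ny * block_size, : nx * block_size]
        blocks = diff2.reshape(ny, block_size, nx, block_size)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ssd[k] = np.nanmean(blocks, axis=(1, 3))
    ssd = np.nan_to_num(ssd, nan=np.inf)

    best = np.argmin(ssd, axis=0)
    side = 2 * r + 1
    by, bx = np.unravel_index(best, (side, side))
    dy_int = by.astype(float) - r
    dx_int = bx.astype(float) - r

    # parabolic refinement along each axis where the minimum is interior
    def refine(int_idx, axis_idx, other_idx, along_rows):
        frac = np.zeros_like(int_idx, dtype=float)
        interior = (axis_idx > 0) & (axis_idx < side - 1)
        for j in range(ny):
            for i in range(nx):
                if not interior[j, i]:
                    continue
                ai, oi = axis_idx[j, i], other_idx[j, i]
                if along_rows:
                    f0 = ssd[(ai - 1) * side + oi, j, i]
                    f1 = ssd[ai * side + oi, j, i]
                    f2 = ssd[(ai + 1) * side + oi, j, i]
                else:
                    f0 = ssd[oi * side + (ai - 1), j, i]
                    f1 = ssd[oi * side + ai, j, i]
                    f2 = ssd[oi * side + (ai + 1), j, i]
                denom = f0 - 2 * f1 + f2
                if np.isfinite(denom) and denom > 0:
                    frac[j, i] = 0.5 * (f0 - f2) / denom
        return frac

    dy_blk = dy_int + refine(dy_int, by, bx, along_rows=True)
    dx_blk = dx_int + refine(dx_int, bx, by, along_rows=False)

    dy_full = np.zeros((h, w))
    dx_full = np.zeros((h, w))
    dy_core = np.repeat(np.repeat(dy_blk, block_size, axis=0), block_size, axis=1)
    dx_core = np.repeat(np.repeat(dx_blk, block_size, axis=0), block_size, axis=1)
    dy_full[: ny * block_size, : nx * block_size] = dy_core
    dx_full[: ny * block_size, : nx * block_size] = dx_core
    # edge remainders inherit the nearest block
    dy_full[ny * block_size :, :] = dy_full[ny * block_size - 1, :]
    dx_full[ny * block_size :, :] = dx_full[ny * block_size - 1, :]
    dy_full[:, nx * block_size :] = dy_full[:, nx * block_size - 1][:, None]
    dx_full[:, nx * block_size :] = dx_full[:, nx * block_size - 1][:, None]
    return FlowField(dx=dx_full, dy=dy_full)


def _radial_basis(frames: np.ndarray):
    """Unit radial vectors about the intensity centroid of the first frame."""
    h, w = frames.shape[1:]
    total = frames[0].sum()
    ys, xs = np.mgrid[0:h, 0:w]
    if total > 0:
        cy = (ys * frames[0]).sum() / total
        cx = (xs * frames[0]).sum() / total
    else:
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry = ys - cy
    rx = xs - cx
    norm = np.hypot(rx, ry)
    norm[norm == 0] = 1.0
    return rx / norm, ry / norm


def flow_profiles(
    clip: VideoClip,
    backend: str = "ilk",
    foreground_mask: np.ndarray | None = None,
) -> tuple[SpeedProfile, ContractionProfile]:
    """Speed and integrated-contraction profiles from one pass of dense flow.

    Speed sample t is the mean |flow| between frames t and t+1 times pixel
    size and frame rate (um/s), timestamped at the inter-frame midpoint and
    averaged over *all* pixels unless a foreground mask is given.

    The contraction trace integrates the inward radial flow component about
    the intensity centroid of the first frame (positive while the sample
    shrinks, negative while it re-expands), weighted by the local gradient
    magnitude of the first frame — flow is only informative where there is
    texture, so the weighting keeps the dilute background from drowning the
    sample.  The per-pair rates are re-centred on their median (with
    diastole occupying most of a paced record, the median rate is the
    zero-motion bias) and cumulatively summed onto the frame time base,
    giving a displacement-like trace that beat segmentation treats exactly
    like the other trackers' contraction profiles.
    """
    frames = clip.frames
    n = clip.n_frames
    rx, ry = _radial_basis(frames)
    smooth0 = gaussian_filter(frames[0].astype(float), 1.0)
    grad = np.hypot(sobel(smooth0, 0), sobel(smooth0, 1))
    grad_w = grad / grad.sum() if grad.sum() > 0 else np.full_like(grad, 1.0 / grad.size)
    speeds = np.empty(n - 1)
    rates = np.empty(n - 1)
    for t in range(n - 1):
        field = dense_flow(frames[t], frames[t + 1], backend=backend)
        mag = field.magnitude
        if foreground_mask is not None:
            mag = mag[foreground_mask]
        speeds[t] = mag.mean() * clip.pixel_size * clip.fps
        rates[t] = -((field.dx * rx + field.dy * ry) * grad_w).sum() * clip.pixel_size
    times_ms = (np.arange(n - 1) + 0.5) / clip.fps * 1000.0
    speed = SpeedProfile(speeds, times_ms, fps=clip.fps, units="um/s", source="flow")
    contraction_values = np.concatenate(
        [[0.0], np.cumsum(rates - np.median(rates))]
    )
    contraction = ContractionProfile(
        contraction_values, fps=clip.fps, source="flow_integrated", units="um"
    )
    return speed, contraction


def flow_speed_profile(
    clip: VideoClip,
    backend: str = "ilk",
    foreground_mask: np.ndarray | None = None,
) -> SpeedProfile:
    """Mean |flow| x pixel_size x fps between successive frames, um/s."""
    return flow_profiles(clip, backend=backend, foreground_mask=foreground_mask)[0]


def flow_contraction_profile(
    clip: VideoClip, backend: str = "ilk"
) -> ContractionProfile:
    """Contraction-state trace integrated from the flow field, in um."""
    return flow_profiles(clip, backend=backend)[1]
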