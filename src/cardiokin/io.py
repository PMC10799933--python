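"""Grayscale video I/O: multipage TIFF, numbered PNG sequences, uncompressed AVI.

All readers return a :class:`VideoClip` whose intensities are min-max
normalized to [0, 1] *per clip* (not per frame), so that frame-difference
magnitudes stay comparable across time.  Color input is collapsed to
grayscale by the channel average before normalization; every acquisition
this package targets is monochrome.

Acquisition metadata (frame rate, pixel size) travels in a side-car JSON
(``<path>.meta.json`` next to a file, ``metadata.json`` inside a PNG
directory); AVI carries its own frame rate which an explicit argument can
override.  The AVI codec support is deliberately minimal — uncompressed
8-bit palettized or 24-bit DIB frames, which is what this package itself
writes — because no full codec stack is assumed.
"""

from __future__ import annotations

import json
import re
import struct
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import FormatError, InconsistentSequenceError, InsufficientDataError

__all__ = ["VideoClip", "read_video", "write_video"]

ORIGIN_CONVENTION = "upper-left, x right, y down"


@dataclass
class VideoClip:
    """Frames plus the acquisition metadata every tracker needs.

    frames
        (time, height, width) float array, intensities in [0, 1].
    fps
        frames per second (s^-1).
    pixel_size
        micrometres per pixel.
    """

    frames: np.ndarray
    fps: float
    pixel_size: float
    origin_convention: str = ORIGIN_CONVENTION

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if not np.issubdtype(self.frames.dtype, np.floating):
            self.frames = self.frames.astype(float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (time, height, width)")
        if self.frames.shape[0] < 2:
            raise InsufficientDataError("a clip needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite intensities")
        if self.frames.min() < -1e-9 or self.frames.max() > 1 + 1e-9:
            raise ValueError("frame intensities must lie in [0, 1]")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape[1:]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps * 1000.0


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 4:  # (T, H, W, C)
        arr = arr.mean(axis=-1)
    return arr.astype(float)


def _normalize(frames: np.ndarray) -> np.ndarray:
    lo, hi = frames.min(), frames.max()
    if hi == lo:
        return np.zeros_like(frames, dtype=float)
    return (frames - lo) / (hi - lo)


_NUM_RE = re.compile(r"(\d+)")


def _numeric_key(path: Path):
    """Sort key: last run of digits in the stem, zero-padding irrelevant."""
    nums = _NUM_RE.findall(path.stem)
    return (int(nums[-1]) if nums else -1, path.name)


def _read_sidecar(path: Path) -> dict:
    if path.is_dir():
        meta = path / "metadata.json"
    else:
        meta = path.with_name(path.name + ".meta.json")
    if meta.exists():
        return json.loads(meta.read_text())
    return {}


def _write_sidecar(path: Path, fps: float, pixel_size: float, is_dir: bool) -> None:
    meta = {"fps": fps, "pixel_size_um": pixel_size}
    target = path / "metadata.json" if is_dir else path.with_name(path.name + ".meta.json")
    target.write_text(json.dumps(meta))


def read_video(path, fps: float | None = None, pixel_size: float | None = None) -> VideoClip:
    """Read a TIFF stack, PNG directory/glob, or uncompressed AVI as a VideoClip.

    ``fps`` and ``pixel_size`` must be supplied when neither the container nor
    a side-car JSON carries them; explicit arguments always win.
    """
    path = Path(path)
    meta = {}
    if path.is_dir() or path.suffix.lower() == ".png" or "*" in path.name:
        frames, meta = _read_png_sequence(path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        if not path.exists():
            raise FormatError(f"no such file: {path}")
        try:
            frames = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
        if frames.ndim == 2:
            frames = frames[None]
        meta = _read_sidecar(path)
    elif path.suffix.lower() == ".avi":
        frames, container_fps = _read_avi(path)
        meta = _read_sidecar(path)
        meta.setdefault("fps", container_fps)
    else:
        raise FormatError(f"unsupported container: {path.suffix!r}")

    frames = _to_grayscale(np.asarray(frames))
    if frames.ndim != 3:
        raise FormatError(f"expected a frame stack, got shape {frames.shape}")
    if frames.shape[0] < 2:
        raise InsufficientDataError(f"{path} holds {frames.shape[0]} frame(s); need >= 2")

    fps = fps if fps is not None else meta.get("fps")
    pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    if fps is None:
        raise FormatError(f"{path}: frame rate not in container/side-car; pass fps=")
    if pixel_size is None:
        raise FormatError(f"{path}: pixel size unknown; pass pixel_size=")
    return VideoClip(_normalize(frames), fps=float(fps), pixel_size=float(pixel_size))


def _read_png_sequence(path: Path):
    if path.is_dir():
        files = sorted(path.glob("*.png"), key=_numeric_key)
        meta = _read_sidecar(path)
    elif "*" in path.name:
        files = sorted(path.parent.glob(path.name), key=_numeric_key)
        meta = _read_sidecar(path.parent)
    else:
        files = [path]
        meta = _read_sidecar(path)
    if not files:
        raise FormatError(f"no PNG frames found at {path}")
    frames = []
    shape = None
    for f in files:
        try:
            img = iio.imread(f)
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"cannot read PNG {f}: {exc}") from exc
        img = _to_grayscale(img[None])[0] if img.ndim == 3 else img.astype(float)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise InconsistentSequenceError(
                f"{f} has shape {img.shape}, expected {shape}"
            )
        frames.append(img)
    return np.stack(frames), meta


def write_video(clip: VideoClip, path, format: str = "tiff") -> Path:
    """Write a clip as multipage TIFF, a numbered PNG sequence, or AVI.

    Returns the path written (the directory for ``png_sequence``).  fps and
    pixel size go to a side-car JSON; AVI additionally stores fps natively.
    """
    path = Path(path)
    if format == "tiff":
        data = np.round(clip.frames * 65535).astype(np.uint16)
        tifffile.imwrite(path, data, photometric="minisblack")
        _write_sidecar(path, clip.fps, clip.pixel_size, is_dir=False)
        return path
    if format == "png_sequence":
        path.mkdir(parents=True, exist_ok=True)
        width = max(4, len(str(clip.n_frames - 1)))
        data = np.round(clip.frames * 255).astype(np.uint8)
        for i, frame in enumerate(data):
            iio.imwrite(path / f"frame_{i:0{width}d}.png", frame)
        _write_sidecar(path, clip.fps, clip.pixel_size, is_dir=True)
        return path
    if format == "avi":
        data = np.round(clip.frames * 255).astype(np.uint8)
        _write_avi(path, data, clip.fps)
        _write_sidecar(path, clip.fps, clip.pixel_size, is_dir=False)
        return path
    raise FormatError(f"unknown output format {format!r}")


# ---------------------------------------------------------------------------
# Minimal uncompressed RIFF/AVI container (8-bit grayscale palettized DIB).
# Frames are stored bottom-up with rows padded to 4 bytes, per the DIB spec.
# ---------------------------------------------------------------------------

def _write_avi(path: Path, frames: np.ndarray, fps: float) -> None:
    n, h, w = frames.shape
    row_bytes = (w + 3) & ~3
    frame_bytes = row_bytes * h
    rate = int(round(fps * 1000))
    scale = 1000

    avih = struct.pack(
        "<14I",
        int(round(1e6 / fps)),  # microseconds per frame
        frame_bytes * int(fps + 1),  # max bytes per second (approximate)
        0,  # padding granularity
        0x10,  # flags: AVIF_HASINDEX not set, AVIF_WASCAPTUREFILE not set
        n, 0, 1, frame_bytes, w, h, 0, 0, 0, 0,
    )
    strh = struct.pack(
        "<4s4sIHHIIIIIIIIhhhh",
        b"vids", b"DIB ", 0, 0, 0, 0, scale, rate, 0, n,
        frame_bytes, 0xFFFFFFFF, 0, 0, 0, w, h,
    )
    # BITMAPINFOHEADER + 256-entry grayscale palette
    bmih = struct.pack("<IiiHHIIiiII", 40, w, h, 1, 8, 0, frame_bytes, 0, 0, 256, 256)
    palette = b"".join(struct.pack("<BBBB", i, i, i, 0) for i in range(256))
    strf = bmih + palette

    def chunk(tag: bytes, payload: bytes) -> bytes:
        pad = b"\x00" if len(payload) % 2 else b""
        return tag + struct.pack("<I", len(payload)) + payload + pad

    def list_chunk(tag: bytes, payload: bytes) -> bytes:
        body = tag + payload
        return b"LIST" + struct.pack("<I", len(body)) + body

    strl = list_chunk(b"strl", chunk(b"strh", strh) + chunk(b"strf", strf))
    hdrl = list_chunk(b"hdrl", chunk(b"avih", avih) + strl)

    movi_payload = b""
    for frame in frames:
        dib = np.zeros((h, row_bytes), dtype=np.uint8)
        dib[:, :w] = frame[::-1]  # bottom-up rows
        movi_payload += chunk(b"00db", dib.tobytes())
    movi = list_chunk(b"movi", movi_payload)

    riff_body = b"AVI " + hdrl + movi
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(riff_body)) + riff_body)


def _iter_chunks(buf: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        tag = buf[pos : pos + 4]
        size = struct.unpack_from("<I", buf, pos + 4)[0]
        yield tag, pos + 8, size
        pos += 8 + size + (size % 2)


def _read_avi(path: Path):
    try:
        buf = Path(path).read_bytes()
    except OSError as exc:
        raise FormatError(f"cannot open {path}: {exc}") from exc
    if buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise FormatError(f"{path} is not an AVI file")

    fps = None
    width = height = bits = None
    frames = []

    def walk(start: int, end: int):
        nonlocal fps, width, height, bits
        for tag, off, size in _iter_chunks(buf, start, end):
            if tag == b"LIST":
                walk(off + 4, off + size)
            elif tag == b"strh" and buf[off : off + 4] == b"vids":
                scale, rate = struct.unpack_from("<II", buf, off + 20)
                if scale:
                    fps = rate / scale
            elif tag == b"strf" and width is None:
                _, w, h, _, b = struct.unpack_from("<IiiHH", buf, off)
                width, height, bits = w, abs(h), b
            elif tag in (b"00db", b"00dc") and size > 0:
                frames.append(buf[off : off + size])

    walk(12, len(buf))
    if not frames or width is None:
        raise FormatError(f"{path}: no video frames found")
    if bits not in (8, 24):
        raise FormatError(f"{path}: unsupported bit depth {bits} (need uncompressed 8/24)")

    out = []
    row_bytes = ((width * bits // 8) + 3) & ~3
    for raw in frames:
        arr = np.frombuffer(raw, dtype=np.uint8)
        if arr.size < row_bytes * height:
            raise FormatError(f"{path}: truncated frame data")
        arr = arr[: row_bytes * height].reshape(height, row_bytes)
        if bits == 8:
            img = arr[:, :width]
        else:
            img = arr[:, : width * 3].reshape(height, width, 3).mean(axis=2)
        out.append(img[::-1].astype(float))  # bottom-up -> top-down
    stack = np.stack(out)
    if len({f.shape for f in out}) != 1:
        raise InconsistentSequenceError(f"{path}: mixed frame shapes")
    return stack, fps
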