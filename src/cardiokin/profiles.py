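"""Time-series containers shared by the three trackers.

A *contraction profile* is a scalar displacement-over-time trace of a beating
sample (arbitrary units for the intensity tracker, micrometres for the marker
and flow trackers).  A *speed profile* is its rectified first time derivative
(two peaks per beat: one during contraction, one during relaxation).

The contraction profile is sampled on frame times (``i / fps``).  Difference
based series carry their own explicit time base: dense-flow samples sit at the
midpoint between the two frames they compare, while the default forward
difference used downstream is timestamped at the left frame, reproducing the
slight temporal anticipation inherent to a ratio-of-increments derivative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ContractionProfile", "SpeedProfile"]

_SOURCES = ("intensity", "flow_integrated", "marker")


@dataclass
class ContractionProfile:
    """Scalar contraction trace, one sample per frame."""

    values: np.ndarray
    fps: float
    source: str
    units: str = "a.u."

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("contraction profile must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("contraction profile contains non-finite values")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.source not in _SOURCES:
            raise ValueError(f"unknown source tag {self.source!r}")
        if self.source == "intensity" and np.any(self.values < -1e-12):
            raise ValueError("intensity-derived profile must be non-negative")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.values.size) / self.fps * 1000.0

    def normalized(self) -> np.ndarray:
        """Min-max normalized copy of the values (presentation only)."""
        lo, hi = self.values.min(), self.values.max()
        if hi == lo:
            return np.zeros_like(self.values)
        return (self.values - lo) / (hi - lo)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.values.size),
                "time_ms": self.times_ms,
                "value": self.values,
                "units": self.units,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class SpeedProfile:
    """Rectified speed trace with an explicit time base in ms."""

    values: np.ndarray
    times_ms: np.ndarray
    fps: float
    units: str = "um/s"
    rectified: bool = True
    source: str = "flow"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.values.shape != self.times_ms.shape:
            raise ValueError("values and times_ms must align")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("speed profile contains non-finite values")
        if self.rectified and np.any(self.values < -1e-12):
            raise ValueError("rectified speed profile must be non-negative")

    def __len__(self) -> int:
        return self.values.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(self.values.size),
                "time_ms": self.times_ms,
                "speed": self.values,
                "units": self.units,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
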