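"""Shared fixtures: rendered clips and texture/translation factories."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, shift as ndshift

from cardiokin.io import VideoClip
from cardiokin.synthetic import WaveformParams, cells_spec, render_clip


@pytest.fixture(scope="session")
def cells_clip():
    """Default single-cell banded rod: 1 Hz, 5 s at 143 fps, camera noise."""
    return render_clip(cells_spec(seed=1))


@pytest.fixture(scope="session")
def cells_clip_clean():
    """Noise-free banded rod, 1 Hz, 3 s — for exact recovery checks."""
    spec = cells_spec(seed=2, duration_s=3.0, noise_sd=0.0)
    return render_clip(spec)


@pytest.fixture(scope="session")
def fog_texture():
    """Smooth, feature-rich texture in [0, 1] for translation fixtures."""
    rng = np.random.default_rng(42)
    tex = gaussian_filter(rng.random((80, 100)), 3.0)
    return (tex - tex.min()) / (tex.max() - tex.min())


@pytest.fixture
def make_translation_clip(fog_texture):
    """Factory: clip whose texture translates rigidly by (dx, dy) px/frame."""

    def _make(dx=1.0, dy=0.0, n_frames=5, fps=143.0, pixel_size=0.5, noise_sd=0.0):
        rng = np.random.default_rng(7)
        frames = []
        for t in range(n_frames):
            f = ndshift(fog_texture, (dy * t, dx * t), order=3, mode="wrap")
            if noise_sd:
                f = f + rng.normal(0, noise_sd, f.shape)
            frames.append(np.clip(f, 0, 1))
        return VideoClip(np.stack(frames), fps=fps, pixel_size=pixel_size)

    return _make


@pytest.fixture
def static_clip(fog_texture):
    """Textured but perfectly still clip."""
    frames = np.stack([fog_texture] * 5)
    return VideoClip(frames, fps=100.0, pixel_size=1.0)
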