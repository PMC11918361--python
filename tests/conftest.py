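import numpy as np
import pytest

from scnphase.synthetic import (
    SliceSynthConfig,
    SnapshotSynthConfig,
    synth_slice_timeseries,
    synth_snapshot,
)


@pytest.fixture(scope="session")
def default_slice():
    """Default synthetic slice movie with ground truth (seeded)."""
    return synth_slice_timeseries(SliceSynthConfig(seed=3))


@pytest.fixture(scope="session")
def noiseless_slice():
    """Noise-free movie: heterogeneous amplitudes, tight phase field."""
    cfg = SliceSynthConfig(seed=5, noise_sd_frac=0.0)
    return synth_slice_timeseries(cfg)


@pytest.fixture(scope="session")
def default_snapshot():
    """Default synthetic snapshot cloud with ground truth (seeded)."""
    return synth_snapshot(SnapshotSynthConfig(seed=1))


@pytest.fixture(scope="session")
def small_snapshot():
    """Small cloud for pair-level and graph-level checks."""
    return synth_snapshot(SnapshotSynthConfig(n_neurons=400, seed=2))


def cosine_grid(phases_h, amplitude=1.0, baseline=0.0, n_frames=48):
    """Grid of pure 24-h cosines, one pixel per phase (hours)."""
    from scnphase.types import SliceTimeSeriesGrid

    phases_h = np.atleast_1d(np.asarray(phases_h, dtype=float))
    t = np.arange(n_frames)
    intensity = amplitude * np.cos(
        2 * np.pi * (t[None, :] - phases_h[:, None]) / 24.0
    ) + baseline
    intensity = intensity[:, None, :]  # (n, 1, frames)
    mask = np.ones((phases_h.size, 1), dtype=bool)
    return SliceTimeSeriesGrid(intensity=intensity, mask=mask)
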