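import numpy as np
import pytest

from alcoeeg import signal_io


@pytest.fixture
def tiny_recording():
    """2 channels x 4 samples x 3 trials with distinct values."""
    data = np.arange(2 * 4 * 3, dtype=float).reshape(2, 4, 3)
    return signal_io.EEGRecording(
        subject_id="s0", label="control", data=data, channel_names=["a", "b"]
    )


@pytest.fixture(scope="session")
def small_dataset():
    """8-channel, 6-per-class synthetic dataset with a clear class effect."""
    cfg = signal_io.SyntheticConfig(
        n_recordings_per_class=6, n_channels=8, class_separation=2.0, seed=7
    )
    return signal_io.generate_synthetic_dataset(cfg)


def two_blobs(n_per_blob=50, gap=20.0, spread=1.0, seed=0, d=2):
    """Two well-separated isotropic Gaussian blobs and their generating split."""
    rng = np.random.default_rng(seed)
    a = rng.normal(scale=spread, size=(n_per_blob, d))
    b = rng.normal(scale=spread, size=(n_per_blob, d)) + gap
    points = np.vstack([a, b])
    split = (set(range(n_per_blob)), set(range(n_per_blob, 2 * n_per_blob)))
    return points, split
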