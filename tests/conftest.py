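import datetime as dt

import numpy as np
import pytest

from ictalcycles.recording import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(signal, fs=256.0, seizures=(), soz=None, xyz=None):
    """Recording wrapper with minimal metadata for unit tests."""
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    n = signal.shape[0]
    labels = [f"C{i}" for i in range(n)]
    return Recording(
        signal=signal, fs=fs, channel_labels=labels,
        electrode_xyz=np.zeros((n, 3)) if xyz is None else np.asarray(xyz, float),
        start_time=dt.datetime(2024, 1, 1),
        seizures=np.asarray(seizures, dtype=float).reshape(-1, 2),
        soz_channels=[] if soz is None else [labels[i] for i in soz],
    )


@pytest.fixture
def small_recording():
    """3-channel, 2-hour synthetic recording with one seizure, reused by
    io/pipeline tests (session-independent, cheap to build)."""
    from ictalcycles.synth import SyntheticConfig, simulate_recording

    cfg = SyntheticConfig(n_channels=3, n_soz_channels=2, n_seizures=2, seed=7)
    rec, truth = simulate_recording(cfg, duration_s=2 * 3600.0)
    return rec, truth
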