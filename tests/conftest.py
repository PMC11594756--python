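import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from meanet import SpikeTrainSet


def make_recording(spikes_by_electrode, duration_s=600.0, **meta):
    """Build a SpikeTrainSet from {electrode: [times_s]} literals."""
    ids = tuple(str(e) for e in spikes_by_electrode)
    return SpikeTrainSet(
        electrode_ids=ids,
        spikes={str(e): np.asarray(t, dtype=float) for e, t in spikes_by_electrode.items()},
        duration_s=duration_s,
        meta=dict(meta),
    )


def random_recording(rng, n_electrodes, n_spikes, duration_s, bursty=False):
    """A random recording; with ``bursty`` the spikes cluster into volleys."""
    ids = tuple(f"e{i}" for i in range(n_electrodes))
    if bursty and n_spikes:
        n_clusters = max(1, n_spikes // 30)
        centers = rng.uniform(0, duration_s, size=n_clusters)
        times = rng.choice(centers, size=n_spikes) + rng.normal(0, 0.02, size=n_spikes)
        times = np.clip(times, 0, duration_s)
    else:
        times = rng.uniform(0, duration_s, size=n_spikes)
    owners = rng.integers(0, n_electrodes, size=n_spikes)
    max_on_grid = np.floor(duration_s * 1e5) / 1e5
    spikes = {}
    for i, eid in enumerate(ids):
        t = np.round(times[owners == i], 5)  # 0.01 ms grid
        spikes[eid] = np.unique(np.minimum(t, max_on_grid))
    return SpikeTrainSet(
        electrode_ids=ids, spikes=spikes, duration_s=duration_s, meta={}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def intact_recording():
    """One default intact-culture synthetic recording, shared across tests."""
    from meanet import default_config, generate_recording

    return generate_recording(default_config(seed=1))


@pytest.fixture(scope="session")
def intact_bursts(intact_recording):
    from meanet import detect_network_bursts

    rec, _ = intact_recording
    return detect_network_bursts(rec)
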