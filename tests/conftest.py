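import numpy as np
import pytest

from l2brain.montage import build_montage
from l2brain.preprocessing import Event, Recording
from l2brain.synth import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_cfg():
    """Small, short simulation for unit tests (not the study protocol)."""
    return SimulationConfig(
        n_subjects=3,
        n_channels=16,
        ec_segment_seconds=20.0,
        eo_segment_seconds=5.0,
        seed=7,
    )


def make_recording(data, fs=512.0, events=None):
    """Recording around a raw array with a synthetic montage."""
    data = np.atleast_2d(np.asarray(data))
    m = build_montage(data.shape[0]) if data.shape[0] >= 2 else None
    labels = m.labels if m else ("CH01",)
    pos = m.positions if m else np.zeros((1, 3))
    return Recording(data, fs, labels, pos, list(events or []))


@pytest.fixture
def recording_factory():
    return make_recording


@pytest.fixture
def ec_events():
    def _events(fs, eo_s, ec_s, n_cycles=2):
        evs, cursor = [], 0
        for _ in range(n_cycles):
            evs.append(Event(cursor, "eyes-open"))
            cursor += int(round(eo_s * fs))
            evs.append(Event(cursor, "eyes-closed"))
            cursor += int(round(ec_s * fs))
        return evs, cursor

    return _events
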