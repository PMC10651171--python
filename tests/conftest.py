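import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from herpipeline.core_io import BlockType, Condition, Group, Recording, build_neighbor_graph
from herpipeline.sim import generate_event_stream, hemispherical_layout


@pytest.fixture(scope="session")
def layout64():
    return hemispherical_layout(64)


@pytest.fixture(scope="session")
def graph64(layout64):
    return build_neighbor_graph(layout64)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def quiet_recording(rng):
    """Small recording with events and near-zero EEG, 8 channels, 120 s."""
    lay = hemispherical_layout(8)
    events = generate_event_stream(
        BlockType.XX, 40, 0.2, fs=250.0, seed=3, start_sample=250
    )
    n = events[-1].onset_sample + 500
    eeg = rng.normal(0, 1e-3, (8, n))
    return Recording("quiet", Group.MCS, eeg, 250.0, lay, events)


def make_recording(eeg, events=(), fs=250.0, group=Group.MCS, subject_id="t"):
    lay = hemispherical_layout(eeg.shape[0])
    return Recording(subject_id, group, eeg, fs, lay, list(events))
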