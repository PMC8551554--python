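from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from plvnet.io import Recording, SourceActivity
from plvnet.synthcohort import make_toy_lead_field


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_lead_field():
    """32 sensors / 68 sources spherical toy forward model."""
    return make_toy_lead_field(n_sensors=32, n_sources=68, seed=11)


@pytest.fixture
def sine_recording():
    """Three channels: 10 Hz, 50 Hz and DC, 10 s at 500 Hz."""
    fs = 500.0
    t = np.arange(int(10 * fs)) / fs
    data = np.vstack([np.sin(2 * np.pi * 10 * t),
                      np.sin(2 * np.pi * 50 * t),
                      np.ones_like(t)])
    return Recording(data=data, fs=fs, channel_labels=["c10", "c50", "dc"])


def make_source_activity(data: np.ndarray, fs: float) -> SourceActivity:
    labels = [f"region{i:02d}" for i in range(data.shape[0])]
    return SourceActivity(data=data, fs=fs, region_labels=labels)
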