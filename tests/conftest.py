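"""Shared fixtures: small synthetic designs, plans, and epoch cohorts."""

import numpy as np
import pandas as pd
import pytest

import touchdecode as td
from touchdecode import simulate as sim

SMALL_SPEC = {"object_type": 4, "material": 3, "touch_type": 2}


@pytest.fixture(scope="session")
def small_design():
    return td.build_design(8, SMALL_SPEC, seed=3)


@pytest.fixture(scope="session")
def small_plan(small_design):
    return sim.generate_sequence_plan(
        small_design, n_sequences=4, repetitions=1,
        targets_range=(1, 2), min_gap=2, seed=5,
    )


@pytest.fixture(scope="session")
def noise_epochs(small_design, small_plan):
    """One subject of pure-noise epochs at 256 Hz, 16 channels."""
    return sim.simulate_subject(
        small_design, small_plan, effects=[],
        noise=sim.NoiseSpec(white_sd=1.0, pink_scale=1.0),
        seed=11, sampling_rate=256.0, n_channels=16,
    )


@pytest.fixture
def toy_epochs():
    """Tiny deterministic EpochArray for transform unit tests."""
    fs = 100.0
    time = -0.1 + np.arange(90) / fs
    rng = np.random.default_rng(0)
    data = rng.standard_normal((6, 3, 90))
    trials = pd.DataFrame(
        {
            "stimulus_id": [f"s{i}" for i in range(6)],
            "sequence_index": [0, 0, 0, 1, 1, 1],
            "is_target": [False] * 6,
        }
    )
    return td.EpochArray(data, fs, time, ["c1", "c2", "c3"], trials)
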