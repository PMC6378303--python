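import numpy as np
import pandas as pd
import pytest

from nichebreadth.community_io import OTUTable, SampleMetadata
from nichebreadth.synthetic_data import SimulationConfig, simulate_metacommunity


@pytest.fixture
def tiny_table() -> OTUTable:
    return OTUTable(
        ["t1", "t2", "t3"], ["s1", "s2", "s3", "s4"],
        np.array([[5, 0, 2, 1],
                  [5, 3, 0, 1],
                  [0, 3, 2, 8]]))


@pytest.fixture
def tiny_metadata() -> SampleMetadata:
    return SampleMetadata(pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "elevation_m": [2100.0, 2300.0, 2600.0, 2900.0],
        "x_m": [0.0, 100.0, 250.0, 400.0],
        "y_m": [0.0, 10.0, -5.0, 20.0],
        "gradient": ["LEG", "LEG", "MEG", "HEG"],
        "pH": [6.3, 6.2, 5.9, 5.8],
    }))


def scaled_config(seed: int, **overrides) -> SimulationConfig:
    """Reduced metacommunity for fast simulation-heavy tests."""
    defaults = dict(n_specialist=100, n_generalist=100, n_neutral=400,
                    depth=2000, seed=seed)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def small_metacommunity():
    cfg = scaled_config(seed=11)
    return simulate_metacommunity(cfg, seed=11)
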