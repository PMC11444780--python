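import numpy as np
import pandas as pd
import pytest

from splitcost import SimulationConfig, generate_dataset
from splitcost.simgen import MASS_COL, TIMING_COL


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def default_data(default_config) -> pd.DataFrame:
    """One n=120 replicate under the default generator (seed 0)."""
    return generate_dataset(default_config)


@pytest.fixture(scope="session")
def tiny_data() -> pd.DataFrame:
    """Frozen 10-row dataset for closed-form / oracle comparisons."""
    timing = np.array([55.0, 57.0, 58.5, 60.0, 61.0, 62.5, 64.0, 66.0, 70.0, 75.0])
    mass = np.array([44.1, 41.8, 43.0, 39.5, 40.2, 38.7, 37.9, 36.4, 34.8, 31.9])
    return pd.DataFrame({TIMING_COL: timing, MASS_COL: mass})
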