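import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from m6acall import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset shared by read-only tests."""
    return simulate_dataset(SimConfig(n_genes=15, rng_seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
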