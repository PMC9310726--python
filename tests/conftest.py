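import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from neurolz import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_cfg():
    """Scaled-down generator configuration for fast unit tests."""
    return SyntheticConfig(n_cats=2, epochs_per_condition=10, seed=99)


@pytest.fixture
def default_cfg():
    return SyntheticConfig(seed=1234)
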