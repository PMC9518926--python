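import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from popsizehmm.demography import DemographicModel


@pytest.fixture
def constant_model():
    """Constant-size model at human-like rates (theta = rho = 5e-4)."""
    return DemographicModel.constant(1e4)


@pytest.fixture
def sawtooth_model():
    """Three-epoch oscillating history."""
    return DemographicModel.from_sizes([1000.0, 10000.0],
                                       [5000.0, 20000.0, 5000.0])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
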