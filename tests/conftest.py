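import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from fibrilnet import ModelParams


@pytest.fixture
def params():
    """A moderate, well-mixing parameter set used across the suite."""
    return ModelParams(phi_e=-1.5, phi_2s=0.3, phi_ESP1=-0.4)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
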