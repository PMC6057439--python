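import numpy as np
import pytest

from tendonmech.mechanics import AnalysisConfig
from tendonmech.simulate import TraceParams, simulate_trace


@pytest.fixture
def default_trace():
    """One synthetic trace with its analytic ground truth (seed fixed)."""
    return simulate_trace(TraceParams(seed=1))


@pytest.fixture
def default_cfg():
    return AnalysisConfig(diameter=0.3, laststrainpt=0.14)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
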