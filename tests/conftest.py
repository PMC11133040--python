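import numpy as np
import pytest

from scedrand import EffectSpec, SCEDSeries


@pytest.fixture
def step_series():
    """Tiny series with a perfect level shift at occasion 4."""
    return SCEDSeries(labels=("A",) * 3 + ("B",) * 3, scores=np.array([0, 0, 0, 5, 5, 5.0]))


@pytest.fixture
def immediate_abrupt():
    return EffectSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(20230925)
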