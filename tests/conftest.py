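import numpy as np
import pytest

from gutabm.params import SimulationParams, desk_scale_params


@pytest.fixture
def params() -> SimulationParams:
    """Published defaults (full-scale gut)."""
    return SimulationParams()


@pytest.fixture
def desk() -> SimulationParams:
    """Desk-scale study profile used for simulation tests."""
    return desk_scale_params(seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
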