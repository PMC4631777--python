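import numpy as np
import pytest

from congression import ModelParams


@pytest.fixture
def fast_params() -> ModelParams:
    """Short simulation for unit tests: full physics, small time budget."""
    return ModelParams(t_meta=120.0, t_ana=60.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
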