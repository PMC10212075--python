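import numpy as np
import pytest

from fishlhopt import (
    AllocationSchedule,
    GrowthParams,
    MortalityModel,
    literature_gradients,
)


@pytest.fixture
def gp():
    """Round-number growth parameters with closed-form checkpoints."""
    return GrowthParams(k=4.0, w0=16.0, b=0.75)


@pytest.fixture
def sched():
    return AllocationSchedule(alpha=2.0, h=1.0)


@pytest.fixture
def mort():
    return MortalityModel(M=0.5, p=0.8)


@pytest.fixture(scope="session")
def gradients():
    """Published per-latitude calibration (reconstructed gradients)."""
    return literature_gradients("predictions")


@pytest.fixture(scope="session")
def coefficient_gradients():
    return literature_gradients("coefficients")


@pytest.fixture
def rng():
    return np.random.default_rng(20230525)
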