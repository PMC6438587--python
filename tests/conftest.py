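import numpy as np
import pytest

from ringwander.model_core import (
    NoiseParams,
    RingGrid,
    RingParams,
    StimulusParams,
    stable_bump,
)
from ringwander.phase_reduction import build_phase_reduction


@pytest.fixture(scope="session")
def params() -> RingParams:
    """Worked parameter set: unit weight, gain 4, threshold 0.5, unit max rate."""
    return RingParams(weight_amplitude=1.0, gain=4.0, threshold=0.5, max_rate=1.0)


@pytest.fixture(scope="session")
def grid() -> RingGrid:
    return RingGrid(n_points=200)


@pytest.fixture(scope="session")
def bump(params, grid):
    return stable_bump(params, grid=grid)


@pytest.fixture(scope="session")
def noise_worked() -> NoiseParams:
    """Worked noise parameters: eps=0.05, a=3, b=0.5 (per-point white convention)."""
    return NoiseParams(epsilon=0.05, white_weight=3.0, cosine_weight=0.5)


@pytest.fixture(scope="session")
def reduction_worked(params, noise_worked, grid):
    return build_phase_reduction(
        params, StimulusParams(contrast=2.0), noise_worked, grid=grid
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
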