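import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def bright_cube_stack():
    """A 5x5x5 cube of value 100 inside a dim (value 5) 11x15x15 stack."""
    from nucleoquant import VoxelStack

    arr = np.full((11, 15, 15), 5.0)
    arr[3:8, 4:9, 6:11] = 100.0
    return VoxelStack(arr)
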