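import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_stack(rng):
    """Random uint16 hyperstack with non-trivial extents on every axis."""
    from voxcorr import Hyperstack

    data = rng.integers(0, 4096, size=(2, 5, 3, 8, 9)).astype(np.uint16)
    return Hyperstack(
        data,
        voxel_size_um=(0.4, 0.4, 1.5),
        stack_period_s=0.5,
        channel_labels=["gcamp", "sr101"],
    )
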