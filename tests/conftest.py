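import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20230615)


@pytest.fixture
def unit_grid_xy():
    """Centroids of a 5x5 unit-cell lattice."""
    xs, ys = np.meshgrid(np.arange(5) + 0.5, np.arange(5) + 0.5)
    return np.column_stack([xs.ravel(), ys.ravel()])
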