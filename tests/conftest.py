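import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def two_type_params():
    from dmmsort import AdhesionParams

    return AdhesionParams.from_flat([0.3, -0.2, 0.1])


@pytest.fixture()
def interface_config():
    """6x6 two-band configuration: rows 0-2 type 0, rows 3-5 type 1."""
    from dmmsort import LatticeConfig

    grid = np.zeros((6, 6), dtype=np.int64)
    grid[3:, :] = 1
    return LatticeConfig(grid, 2)
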