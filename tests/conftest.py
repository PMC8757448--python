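import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from proteocell import (
    DEFAULT_GEOMETRY,
    GridControls,
    ProteinParams,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def geometry():
    return DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def fitted_params():
    """Langmuir parameters fitted for albumin on the biomimetic HA disk."""
    return ProteinParams(k_a=6.2e-4, k_d=0.2, c_s_max=31.5, D=0.3)


@pytest.fixture(scope="session")
def coarse_grid():
    """Discretisation used for fast forward runs in tests."""
    return GridControls(n_cells=60, dt_h=0.1)


@pytest.fixture(scope="session")
def protein_schedule():
    return np.array([2.0, 4.0, 6.0, 8.0, 24.0, 48.0, 72.0])
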