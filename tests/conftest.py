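import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pdda_table():
    from kaisim.kinetics import default_pdda_table

    return default_pdda_table()


@pytest.fixture(scope="session")
def small_params():
    """Population parameters scaled down for fast unit tests."""
    from kaisim.population import ModelParams

    return ModelParams(n_hexamers=500)
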