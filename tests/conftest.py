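import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from her2cea import table1_fixture
from her2cea.sensitivity import run_psa

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table():
    """The packaged canonical (published) parameter table."""
    return table1_fixture()


@pytest.fixture(scope="session")
def means(table):
    return table.means()


@pytest.fixture(scope="session")
def psa_small(table):
    """A modest PSA run shared by tests that only need distributional shape."""
    return run_psa(table, n=2000, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20190101)
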