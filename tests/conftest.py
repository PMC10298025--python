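import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from triqtl import genome, io

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_gmap():
    return genome.default_map()


@pytest.fixture(scope="session")
def toy_map():
    """One chromosome, 20 markers at 5 cM: small enough for exhaustive checks."""
    return genome.default_map(n_chromosomes=1, markers_per_chromosome=20, spacing_cm=5.0)


@pytest.fixture(scope="session")
def tiny_fixture():
    return io.make_fixture("tiny", seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
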