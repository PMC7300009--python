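import numpy as np
import pytest

from itmc.materials import get_material
from itmc.mscatter import build_ms_table


@pytest.fixture(scope="session")
def ms_tables():
    """Shared multiple-scattering table (expensive to build)."""
    return build_ms_table()


@pytest.fixture(scope="session")
def water():
    return get_material("water")


@pytest.fixture(scope="session")
def graphite():
    return get_material("graphite")


@pytest.fixture(scope="session")
def aluminum():
    return get_material("aluminum")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
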