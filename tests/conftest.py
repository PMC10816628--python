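import numpy as np
import pytest

from hittriage import synthetic_data as sd


@pytest.fixture(scope="session")
def small_library():
    """60-compound synthetic library (30 active / 30 inactive), seeded."""
    return sd.gen_library(sd.LibrarySpec(n_active=30, n_inactive=30, seed=1))


@pytest.fixture(scope="session")
def large_library():
    """500-compound library for the chem-core determinism checks."""
    return sd.gen_library(sd.LibrarySpec(n_active=250, n_inactive=250, seed=3))


@pytest.fixture(scope="session")
def paper_fixture():
    return sd.build_paper_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
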