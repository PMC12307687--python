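import numpy as np
import pytest

from strucbif import fixtures as fixture_mod


@pytest.fixture(scope="session")
def example1():
    return fixture_mod.load_fixture("example1")


@pytest.fixture(scope="session")
def conserved_example():
    return fixture_mod.load_fixture("conserved_example")


@pytest.fixture(scope="session")
def macrophage_wt():
    return fixture_mod.load_fixture("macrophage_wt")


@pytest.fixture(scope="session")
def macrophage_socs3d():
    return fixture_mod.load_fixture("macrophage_socs3d")


@pytest.fixture(scope="session")
def macrophage_socs3d_klf4d():
    return fixture_mod.load_fixture("macrophage_socs3d_klf4d")


@pytest.fixture(scope="session")
def all_fixtures(example1, conserved_example, macrophage_wt,
                 macrophage_socs3d, macrophage_socs3d_klf4d):
    return [example1, conserved_example, macrophage_wt, macrophage_socs3d,
            macrophage_socs3d_klf4d]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
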