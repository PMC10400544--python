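import pytest

from tcosa import linear_chain, prepare_tcosa_model, redox_fixture
from tcosa.milp import FluxConstraints, MilpConfig
from tcosa.scenarios import wild_type_assignment


@pytest.fixture(scope="session")
def fixture_tcosa():
    """Prepared catabolic/anabolic redox fixture (both pools exercised)."""
    model, thermo, cof = redox_fixture()
    return prepare_tcosa_model(model, thermo, cof)


@pytest.fixture(scope="session")
def fixture_wildtype(fixture_tcosa):
    return wild_type_assignment(fixture_tcosa)


@pytest.fixture
def unit_flux():
    return FluxConstraints(growth_min=1.0)


@pytest.fixture
def config():
    return MilpConfig()


@pytest.fixture(scope="session")
def chain():
    """Factory for prepared linear chains with given per-step dG0."""

    def make(n_steps, dG0s=None):
        model, thermo, cof = linear_chain(n_steps, dG0s)
        return prepare_tcosa_model(model, thermo, cof)

    return make
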