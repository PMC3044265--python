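import hypothesis
import pytest

from netprior import (
    PPINetwork,
    ScenarioParams,
    diffusion_kernel,
    make_scenario,
)

hypothesis.settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=40
)
hypothesis.settings.load_profile("suite")


@pytest.fixture
def two_node():
    return PPINetwork.from_edges([("a", "b")])


@pytest.fixture
def path4():
    return PPINetwork.from_edges([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def triangle():
    return PPINetwork.from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture(scope="session")
def small_scenario():
    """Compact planted scenario for fast unit tests."""
    return make_scenario(ScenarioParams(n_genes=120, n_diseases=40, q=2, seed=4))


@pytest.fixture(scope="session")
def small_kernels(small_scenario):
    return [diffusion_kernel(n, 0.2) for n in small_scenario.networks]


@pytest.fixture(scope="session")
def default_scenario():
    """The standard benchmark: generator defaults, seed 1."""
    return make_scenario()


@pytest.fixture(scope="session")
def default_kernels(default_scenario):
    return [diffusion_kernel(n, 0.2) for n in default_scenario.networks]
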