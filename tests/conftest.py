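import numpy as np
import pytest

import geripbpk as g


@pytest.fixture(scope="session")
def default_spec() -> g.PopulationSpec:
    return g.PopulationSpec()


@pytest.fixture(scope="session")
def population_1k(default_spec):
    return g.generate_population(default_spec, 1000, seed=3)


@pytest.fixture(scope="session")
def pop_frame(population_1k):
    return g.population_frame(population_1k)


@pytest.fixture(scope="session")
def subject(default_spec) -> g.VirtualSubject:
    """One reproducible male subject used by engine-level tests."""
    return g.build_subject(default_spec, np.random.default_rng(7), sex="M")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
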