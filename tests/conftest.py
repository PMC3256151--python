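import numpy as np
import pytest

from coagxa import (
    FACTOR_NAMES,
    PlasmaComposition,
    SimulationConfig,
    build_network,
    default_means,
    simulate,
)
from coagxa.synthetic import default_spec, fixture_compositions


@pytest.fixture(scope="session")
def network():
    return build_network()


@pytest.fixture(scope="session")
def means():
    return default_means()


@pytest.fixture(scope="session")
def nominal():
    return PlasmaComposition("nominal", {f: 100.0 for f in FACTOR_NAMES})


@pytest.fixture(scope="session")
def nominal_trajectory(nominal, network, means):
    return simulate(nominal, network=network, means=means)


@pytest.fixture(scope="session")
def printed_compositions():
    return fixture_compositions()


@pytest.fixture(scope="session")
def table1_spec():
    return default_spec()


def random_composition(rng, spec, group="control", subject_id="random"):
    """A composition drawn uniformly within the printed per-factor ranges."""
    levels = {
        f: rng.uniform(d.min, d.max) for f, d in spec.factors[group].items()
    }
    return PlasmaComposition(subject_id, levels, group=group)


@pytest.fixture
def rng():
    return np.random.default_rng(20120111)
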