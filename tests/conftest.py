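import logging

import pytest
from hypothesis import HealthCheck, settings

import agesim as ag

# routine retention-capping messages would flood the test log
logging.getLogger("agesim").setLevel(logging.ERROR)

settings.register_profile(
    "suite", derandomize=True, max_examples=60, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy() -> ag.ModelBundle:
    """The bundled reduced central-carbon + ROS fixture (in memory)."""
    return ag.toy_bundle()


@pytest.fixture(scope="session")
def wildtype(toy) -> ag.Timeline:
    """One full wildtype lifespan under the fixture's default parameters.

    Shared across tests: the run is deterministic, so every consumer
    sees the same timeline.
    """
    return ag.simulate_lifespan(toy.model, toy.network, toy.table, toy.params)


@pytest.fixture(scope="session")
def wildtype_phases(wildtype) -> ag.PhaseAnnotation:
    return ag.segment_phases(wildtype)
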