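import pytest

from karyoweave import grch38_map, u937_fixture, u937_stemline
from karyoweave.scenarios import u937_scenario


@pytest.fixture(scope="session")
def genome():
    return grch38_map()


@pytest.fixture(scope="session")
def pop():
    """Nominal-fraction U937 population."""
    return u937_fixture("nominal")


@pytest.fixture(scope="session")
def stemline():
    return u937_stemline()


@pytest.fixture(scope="session")
def chr6_scenario():
    """Simulated chromosome-6 track of the fixture at default noise."""
    return u937_scenario(seed=1, chromosomes=["6"])


@pytest.fixture(scope="session")
def chr6_calls(chr6_scenario):
    from karyoweave import call_segments

    return call_segments(chr6_scenario.track, seed=1, bootstrap=False)
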