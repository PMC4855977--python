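import pytest
from hypothesis import settings

import phaflux as pf

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


# --- toy model texts ---------------------------------------------------------

CHAIN = """
up: -> A[c]
mid: A[c] -> B[c]
out: B[c] ->
"""

DIAMOND = """
up: -> A[c]
r2: A[c] -> B[c]
r3: A[c] -> B[c]
out: B[c] ->
"""

# two routes of different product yield from the same precursor
TWO_ROUTE = """
up: -> A[c]
r_low: A[c] -> B[c]
r_high: A[c] -> 2 B[c]
out: B[c] ->
waste: A[c] ->
"""


@pytest.fixture
def chain_network():
    return pf.load_network(CHAIN)


@pytest.fixture
def diamond_network():
    return pf.load_network(DIAMOND)


@pytest.fixture
def two_route_network():
    return pf.load_network(TWO_ROUTE)


# --- reference fixtures (session-scoped: enumeration is the expensive step) --

@pytest.fixture(scope="session")
def ref_network():
    return pf.load_reference_network()


@pytest.fixture(scope="session")
def ref_modes(ref_network):
    return pf.enumerate_efms(ref_network)


@pytest.fixture(scope="session")
def ref_modes_normalized(ref_modes):
    return pf.normalize_modes(ref_modes, "EX_glycerol")


@pytest.fixture(scope="session")
def carbon_limited_series():
    return pf.read_observations(pf.data_path("chemostat_carbon_limited.tsv"))


@pytest.fixture(scope="session")
def condition_observations():
    return {o.condition: o
            for o in pf.read_observations(pf.data_path("chemostat_conditions.tsv"))}
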