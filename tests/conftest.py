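"""Shared fixtures: one small simulated world reused across test modules."""

import pytest
from hypothesis import settings

from aavint import itrseq, longread
from aavint import simulate as sim

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config():
    return sim.SimConfig(seed=7, n_events=30, n_long_reads=60)


@pytest.fixture(scope="session")
def references(small_config):
    return sim.forge_references(small_config)


@pytest.fixture(scope="session")
def host(references):
    return references[0]


@pytest.fixture(scope="session")
def vector(references):
    return references[1]


@pytest.fixture(scope="session")
def events(references, small_config):
    host, vector = references
    return sim.plant_events(host, vector, small_config)


@pytest.fixture(scope="session")
def host_index(host):
    return itrseq.build_host_index(host)


@pytest.fixture(scope="session")
def longread_index(vector, host):
    return longread.build_index(vector, host)


@pytest.fixture(scope="session")
def layout(vector):
    anchor, residual = sim.itr_anchor(vector)
    return itrseq.ReadLayout(anchor=anchor, residual=residual)


@pytest.fixture(scope="session")
def short_reads(events, references, small_config):
    host, vector = references
    return sim.make_itrseq_reads(events, host, vector, small_config)


@pytest.fixture(scope="session")
def long_reads(events, references, small_config):
    host, vector = references
    return sim.make_long_reads(events, host, vector, small_config)
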