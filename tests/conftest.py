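import logging

import pytest

from gemcom import Medium, assemble_community, dhp_spec, make_designed_consortium
from gemcom.synth import chain_strain, cross_feeder_pair

# medium-mismatch warnings are expected noise in tests that probe media
logging.getLogger("gemcom.fba").setLevel(logging.ERROR)


@pytest.fixture
def t1():
    """Linear glucose -> biomass chain strain."""
    return chain_strain()


@pytest.fixture
def glc10():
    return Medium("glc10", {"glc": 10})


@pytest.fixture
def pair():
    """Obligate cross-feeder strains (A feeds X to B)."""
    return cross_feeder_pair()


@pytest.fixture
def pair_community(pair, glc10):
    return assemble_community(list(pair), glc10)


@pytest.fixture(scope="session")
def dhp():
    """Degrader/Helper/Potentiator models plus the C1/C2 media series."""
    models, media = make_designed_consortium(dhp_spec())
    return models, media
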