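import pytest

from oligofountain.distributions import raptor_rfc5053
from oligofountain.rules import RuleSet
from oligofountain.synth import generate_file


@pytest.fixture(scope="session")
def raptor():
    return raptor_rfc5053()


@pytest.fixture(scope="session")
def default_rules():
    return RuleSet(h_max=3, gc_min=0.4, gc_max=0.6)


@pytest.fixture(scope="session")
def relaxed_rules():
    return RuleSet(h_max=4, gc_min=0.3, gc_max=0.7)


@pytest.fixture(scope="session")
def text_file():
    """6,641-byte medium-entropy stand-in for natural-language prose."""
    return generate_file(6641, 1.94101, rng_seed=7)


@pytest.fixture(scope="session")
def low_entropy_file():
    """Low-entropy stand-in emulating a black-and-white bitmap."""
    return generate_file(2048, 0.52611, rng_seed=8)
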