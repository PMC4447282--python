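import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

BASES = "ACGT"


@pytest.fixture
def rng():
    return np.random.default_rng(20150528)


def random_dna(rng, length, p=(0.25, 0.25, 0.25, 0.25)):
    return "".join(rng.choice(list(BASES), size=length, p=list(p)))


@pytest.fixture
def random_dna_factory(rng):
    def make(length, p=(0.25, 0.25, 0.25, 0.25)):
        return random_dna(rng, length, p)

    return make
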