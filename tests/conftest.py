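import numpy as np
import pytest
from hypothesis import settings

from metamerge.spatial import build_weights
from metamerge.types import SeqRecord

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

SITE_ORDER = {
    "ind1": ("cecum", "transverse_colon", "feces"),
    "ind2": ("cecum", "transverse_colon", "feces"),
}


@pytest.fixture(scope="session")
def site_order():
    return SITE_ORDER


@pytest.fixture(scope="session")
def weights():
    return build_weights(SITE_ORDER)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def genome_record(rng):
    return SeqRecord(id="g", sequence=random_seq(rng, 12000))
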