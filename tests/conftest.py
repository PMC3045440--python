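import numpy as np
import pytest
from hypothesis import settings

from igloci.seqio import GenomicSequence

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.integers(0, 4, n).astype(np.uint8).choose(BASES).tobytes().decode()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_scaffold(rng):
    return GenomicSequence("rand", random_dna(rng, 10_000))
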