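import numpy as np
import pytest

from ervprofiler import GenomeSequence
from ervprofiler.simulate import random_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_920)


@pytest.fixture
def random_genome(rng):
    return GenomeSequence("chr1", random_sequence(rng, 10_000))


def make_genome(seed: int, length: int, name: str = "chr1") -> GenomeSequence:
    return GenomeSequence(name, random_sequence(np.random.default_rng(seed), length))
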