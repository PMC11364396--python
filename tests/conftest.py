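import pytest

from editscan import GenomeRef, SyntheticConfig, generate_genome


@pytest.fixture(scope="session")
def default_bundle():
    """Default synthetic genome: 2 contigs, 6 genes (3 minus-strand),
    SINE-like repeats and one planted (30, 50) inverted repeat."""
    return generate_genome(SyntheticConfig())


@pytest.fixture(scope="session")
def genome(default_bundle):
    return default_bundle[0]


@pytest.fixture(scope="session")
def genes(default_bundle):
    return default_bundle[1]


@pytest.fixture(scope="session")
def repeats(default_bundle):
    return default_bundle[2]


@pytest.fixture(scope="session")
def ir_truth(default_bundle):
    return default_bundle[3]["inverted_repeats"]


@pytest.fixture
def toy_genome():
    """A deliberately tiny hand-made reference for exact-arithmetic tests."""
    return GenomeRef({"ctg": "ACGT" * 100})
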