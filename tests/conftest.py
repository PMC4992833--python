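import numpy as np
import pytest

from shallowcna import GenomeModel, hg19_genome


@pytest.fixture(scope="session")
def hg19():
    """Bundled hg19-style genome, all 24 chromosomes."""
    return hg19_genome()


@pytest.fixture(scope="session")
def hg19_female():
    """hg19 without chrY, the default simulation frame."""
    return hg19_genome(include_chrY=False)


@pytest.fixture
def toy_genome():
    """Small two-chromosome genome for fast unit tests."""
    return GenomeModel((("chrA", 50_000_000), ("chrB", 30_000_000)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
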