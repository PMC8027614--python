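import numpy as np
import pytest

from svharvest.io import GenomeRef
from svharvest.splitread import KmerIndex


@pytest.fixture(scope="session")
def toy_genome() -> GenomeRef:
    """A deterministic 10 kb two-contig genome for realignment tests."""
    rng = np.random.default_rng(424242)
    bases = np.array(list("ACGT"))
    seqs = {
        "chrI": "".join(rng.choice(bases, size=8000)),
        "chrII": "".join(rng.choice(bases, size=2000)),
    }
    return GenomeRef(seqs)


@pytest.fixture(scope="session")
def toy_index(toy_genome) -> KmerIndex:
    return KmerIndex(toy_genome, seed_len=12)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
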