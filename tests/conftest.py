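import numpy as np
import pytest

from genosketch import fixtures


@pytest.fixture(scope="session")
def small_genomes():
    """Ten 5 kb random genomes, pairwise mutated from a common ancestor."""
    base = fixtures.random_genome(5000, 1000, name="anc")
    out = [base]
    for i in range(9):
        rate = 0.01 * (i + 1)
        g = fixtures.mutate(base, fixtures.MutationModel(rate, 2000 + i))
        out.append(fixtures.SequenceRecord(id=f"g{i}", seq=g.seq))
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
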