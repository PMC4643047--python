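import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20150913)


@pytest.fixture
def tiny_genome():
    """A deterministic 20 kb single-contig genome."""
    r = np.random.default_rng(42)
    seq = "".join(r.choice(list("ACGT"), size=20000,
                           p=[0.29, 0.21, 0.21, 0.29]))
    from ervfossil import GenomeSeq
    return [GenomeSeq("c1", seq)]
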