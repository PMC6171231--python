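import numpy as np
import pytest

from coniphy.codonrates import CodonAlignment


def pairwise_alignment(seq_a: str, seq_b: str) -> CodonAlignment:
    """Gap-free codon alignment of two equal-length in-frame sequences."""
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    cols = tuple(
        (seq_a[i : i + 3], seq_b[i : i + 3]) for i in range(0, len(seq_a), 3)
    )
    return CodonAlignment(id_a="a", id_b="b", columns=cols)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
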