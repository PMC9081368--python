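import numpy as np
import pytest

from mhcvote import ProteinSequence, default_tables
from mhcvote.seqio import ALPHABET


@pytest.fixture(scope="session")
def tables():
    return default_tables()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_seq():
    """Factory: seeded random ProteinSequence of a given length."""

    def make(length: int, seed: int = 0, sid: str = "s") -> ProteinSequence:
        r = np.random.default_rng(seed)
        return ProteinSequence(
            id=f"{sid}{seed}",
            residues="".join(r.choice(list(ALPHABET), size=length)),
        )

    return make
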