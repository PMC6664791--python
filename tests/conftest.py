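import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np
import pytest

from irescan.sequence_io import RnaSequence

BASES = "ACGU"


def random_rna(rng: np.random.Generator, length: int, seq_id: str = "r") -> RnaSequence:
    return RnaSequence(seq_id, "".join(rng.choice(list(BASES), size=length)))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def seq173(rng):
    return random_rna(rng, 173, "s173")
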