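import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from thermoprot.sequence_io import ProteinSequence
from thermoprot.synthetic_data import default_profiles, generate
from thermoprot.tables import AMINO_ACIDS


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@pytest.fixture(scope="session")
def random_sequences() -> list[ProteinSequence]:
    """200 uniform-random sequences of lengths 3-100 (fixed seed)."""
    rng = np.random.default_rng(20201022)
    out = []
    for i in range(200):
        length = int(rng.integers(3, 101))
        out.append(ProteinSequence(f"rand_{i:03d}", random_protein(rng, length)))
    return out


@pytest.fixture(scope="session")
def small_dataset():
    """A small paper-profile synthetic dataset: 40 positives, 40 negatives."""
    pos, neg = default_profiles(min_length=60, max_length=200)
    return generate(pos, neg, 40, 40, seed=7)
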