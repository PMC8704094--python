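from pathlib import Path

import numpy as np
import pytest

from dualbarcode.seq_io import SequenceRecord, SequenceSet
from dualbarcode.synthetic_data import build_synthetic_its2

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_its2():
    """ITS2-like template sequence + helix-annotated structure."""
    return build_synthetic_its2(seed=7)


@pytest.fixture
def two_species_set():
    return SequenceSet(
        records=[
            SequenceRecord("a1", "ACGTACGTAC", species="Alpha", locus="ITS"),
            SequenceRecord("a2", "ACGTACGTAC", species="Alpha", locus="ITS"),
            SequenceRecord("b1", "ACGTACGTCC", species="Beta", locus="ITS"),
            SequenceRecord("b2", "ACGTACTTCC", species="Beta", locus="ITS"),
        ],
        locus="ITS",
    )


def random_balanced_dotbracket(rng, max_len=60):
    """Random balanced dot-bracket string (for parser property tests)."""
    out = []
    depth = 0
    n = int(rng.integers(1, max_len))
    for _ in range(n):
        r = rng.random()
        if depth > 0 and r < 0.3:
            out.append(")")
            depth -= 1
        elif r < 0.6:
            out.append("(")
            depth += 1
        else:
            out.append(".")
    out.extend(")" * depth)
    return "".join(out)
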