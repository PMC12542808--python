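from pathlib import Path

import numpy as np
import pytest

from baitkit import MultipleAlignment, read_stats_table

FIXTURES = Path(__file__).parent / "fixtures"

BASES = np.array(list("ACGT"))


def random_alignment(rng, n_seqs, length, missing=0.0, labels=None):
    """Random alignment over ACGT with optional missing/gap characters."""
    labels = labels or [f"t{i}" for i in range(n_seqs)]
    records = []
    for lab in labels:
        arr = BASES[rng.integers(0, 4, size=length)].copy()
        if missing:
            mask = rng.random(length) < missing
            arr[mask] = rng.choice(list("N-?"), size=int(mask.sum()))
        records.append((lab, "".join(arr)))
    return MultipleAlignment(records)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def table1_rows():
    return read_stats_table(FIXTURES / "table1.tsv")
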