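import numpy as np
import pytest

from sulfoscan.msa_io import Alignment, SequenceRecord
from sulfoscan.synthetic_data import FamilyConfig, generate_family
from sulfoscan.taxonomy import CladeTable


def make_alignment(rows, ids=None):
    """Alignment from a list of residue strings (plain ids)."""
    ids = ids or [f"seq{i}" for i in range(len(rows))]
    return Alignment(
        tuple(SequenceRecord.from_header(i, r) for i, r in zip(ids, rows))
    )


def random_alignment(rng, n_records, n_columns, gap_rate=0.1, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    letters = np.array(list(alphabet), dtype="<U1")
    mat = letters[rng.integers(0, len(letters), size=(n_records, n_columns))]
    mat[rng.random((n_records, n_columns)) < gap_rate] = "-"
    # keep every record non-empty and every column minimally sane
    rows = ["".join(row) for row in mat]
    return make_alignment(rows)


@pytest.fixture(scope="session")
def default_family():
    """One deterministically generated synthetic family (seed 17)."""
    return generate_family(FamilyConfig())


@pytest.fixture
def toy_alignment():
    """5 sequences, Y-rich column 2, gap dialect exercised downstream."""
    return make_alignment(
        ["QYDDC", "QYDEC", "QYEDC", "QDEDC", "Q-DDC"],
        ids=[f"s{i}" for i in range(5)],
    )


@pytest.fixture
def toy_clades():
    return CladeTable(
        {
            "s0": "mammal",
            "s1": "mammal",
            "s2": "amphibian",
            "s3": "amphibian",
            "s4": "ray_finned_fish",
        }
    )
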