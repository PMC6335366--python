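import numpy as np
import pytest

from pprkit.property_tables import builtin_groupings, builtin_normalized_indices
from pprkit.sequence_io import ALPHABET, ProteinRecord


@pytest.fixture(scope="session")
def schemes():
    return builtin_groupings()


@pytest.fixture(scope="session")
def norm_indices():
    return builtin_normalized_indices()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture()
def random_record(rng):
    """Factory for random canonical-alphabet records."""

    def make(length: int, rid: str = "r1") -> ProteinRecord:
        letters = rng.integers(0, 20, size=length)
        return ProteinRecord(rid, "".join(ALPHABET[i] for i in letters))

    return make


@pytest.fixture()
def fasta_file(tmp_path):
    """Factory writing raw FASTA text to a temp file."""

    def make(text: str, name: str = "input.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return make
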