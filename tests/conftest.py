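import numpy as np
import pytest

from cuticula.config import RunConfig
from cuticula.sequence_io import AMINO_ACIDS, ProteinRecord
from cuticula.synthetic_data import make_reference_catalog


@pytest.fixture(scope="session")
def config():
    return RunConfig()

@pytest.fixture(scope="session")
def reference():
    return make_reference_catalog(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_protein(rng, length, pid="p"):
    seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))
    return ProteinRecord(pid, seq)


@pytest.fixture()
def fasta_file(tmp_path):
    def write(text, name="test.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path
    return write
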