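import numpy as np
import pytest

from piscape.sequence_io import ProteinRecord


@pytest.fixture
def make_records():
    """Factory: list of sequences -> list of ProteinRecord."""
    def _make(sequences, proteome_id="test"):
        return [ProteinRecord(f"p{i:03d}", proteome_id, seq)
                for i, seq in enumerate(sequences)]
    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_protein(rng, length, residues="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(rng.choice(list(residues), size=length))
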