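import numpy as np
import pytest

from viroproteome.constants import CANONICAL_RESIDUES
from viroproteome.io_fasta import ProteinRecord
from viroproteome.physchem import profile


def random_peptide(rng: np.random.Generator, min_len: int = 1, max_len: int = 500) -> str:
    length = int(rng.integers(min_len, max_len + 1))
    idx = rng.integers(0, len(CANONICAL_RESIDUES), size=length)
    return "".join(CANONICAL_RESIDUES[i] for i in idx)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20211028)


@pytest.fixture
def small_profiles():
    """Profiles of a handful of fixed peptides across two host groups."""
    records = [
        ProteinRecord("a1", "MSSTT", host_group="algae"),
        ProteinRecord("a2", "MQMQEKGWKIIIEEQ", host_group="algae"),
        ProteinRecord("b1", "MGISGEKLGNFLIFK", host_group="bacteria"),
        ProteinRecord("b2", "MKKRRLLHHA", host_group="bacteria"),
        ProteinRecord("b3", "MDDEEYYCCA", host_group="bacteria"),
    ]
    return [profile(r) for r in records]
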