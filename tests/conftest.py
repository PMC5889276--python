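import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from phagekit import GenomeRecord  # noqa: E402

from oracles import random_dna  # noqa: E402


@pytest.fixture
def make_genome():
    def _make(seed: int, length: int, gc: float = 0.5) -> GenomeRecord:
        return GenomeRecord(id=f"rand{seed}", seq=random_dna(seed, length, gc))

    return _make


@pytest.fixture
def tmp_fasta(tmp_path):
    def _write(seq: str, header: str = "g", name: str = "genome.fasta"):
        path = tmp_path / name
        path.write_text(f">{header}\n{seq}\n")
        return path

    return _write
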