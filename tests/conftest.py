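from __future__ import annotations

import numpy as np
import pytest

from markerscreen.seq import SequenceRecord
from markerscreen.simulate import random_protein, reverse_translate
from markerscreen.seq import decode_dna


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_protein(rng, length: int, name: str = "p") -> SequenceRecord:
    return SequenceRecord(name, random_protein(length, rng), "protein")


def cds_of(protein: SequenceRecord, rng) -> str:
    """A nucleotide coding sequence of a protein (random synonymous codons)."""
    return decode_dna(reverse_translate(protein.seq, rng))


def mutate_nt(seq: str, rate: float, rng) -> str:
    """Substitute bases at the given per-base rate."""
    bases = "ACGT"
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = bases[(bases.index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)
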