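from __future__ import annotations

import random

import pytest

from fragmerge import Chromatogram, SequenceRecord


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20130312)


@pytest.fixture
def make_chromatogram():
    def _make(bases: str, qualities: list[int], name: str = "trace") -> Chromatogram:
        return Chromatogram(name=name, bases=bases, qualities=qualities)

    return _make


def random_dna(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


@pytest.fixture
def record():
    def _make(seq: str, rid: str = "seq") -> SequenceRecord:
        return SequenceRecord(id=rid, sequence=seq)

    return _make
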