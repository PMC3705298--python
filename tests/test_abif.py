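"""ABIF (AB1) reader/writer: round trips, error contracts, external parser agreement."""

from __future__ import annotations

import random
import struct

import pytest
from hypothesis import given, settings, strategies as st

from fragmerge import AbifError, Chromatogram, read_abif, write_abif

dna = st.text(alphabet="ACGTNRYSWKM", min_size=1, max_size=200)


@pytest.mark.parametrize(
    "bases,quals",
    [
        ("ACGT", [10, 20, 30, 40]),
        ("A", [0]),                      # data <= 4 bytes is stored inline
        ("ACGTN", [1, 2, 3, 4, 5]),
        ("ACG", [62, 0, 31]),            # full quality range
    ],
)
def test_round_trip_examples(tmp_path, bases, quals):
    path = write_abif(bases, quals, tmp_path / "t.ab1")
    chrom = read_abif(path)
    assert chrom.bases == bases
    assert chrom.qualities == quals
    assert chrom.name == "t"


@settings(derandomize=True, max_examples=40, deadline=None)
@given(bases=dna, data=st.data())
def test_round_trip_property(tmp_path_factory, bases, data):
    quals = data.draw(
        st.lists(st.integers(0, 62), min_size=len(bases), max_size=len(bases))
    )
    path = tmp_path_factory.mktemp("abif") / "t.ab1"
    write_abif(bases, quals, path)
    chrom = read_abif(path)
    assert (chrom.bases, chrom.qualities) == (bases, quals)


def test_realistic_amplicon_scale(tmp_path):
    rng = random.Random(42)
    bases = "".join(rng.choice("ACGT") for _ in range(800))
    quals = [rng.randint(0, 62) for _ in range(800)]
    chrom = read_abif(write_abif(bases, quals, tmp_path / "big.ab1"))
    assert len(chrom) == 800 == len(chrom.bases) == len(chrom.qualities)
    assert (chrom.bases, chrom.qualities) == (bases, quals)


def test_uniform_quality_500(tmp_path):
    bases = "ACGT" * 125
    chrom = read_abif(write_abif(bases, [35] * 500, tmp_path / "u.ab1"))
    assert len(chrom) == 500
    assert set(chrom.qualities) == {35}


def test_biopython_reads_our_fixture(tmp_path):
    """Independent parser oracle: Bio.SeqIO must see the same bases/qualities."""
    from Bio import SeqIO

    bases, quals = "ACGTACGTNN", [2, 5, 10, 20, 30, 40, 50, 60, 62, 0]
    path = write_abif(bases, quals, tmp_path / "x.ab1")
    rec = SeqIO.read(str(path), "abi")
    assert str(rec.seq) == bases
    assert rec.letter_annotations["phred_quality"] == quals


def test_prefers_edited_entry_one(tmp_path):
    """When PBAS1 and PBAS2 disagree, entry 1 (edited calls) wins."""
    path = write_abif("AAAAA", [10] * 5, tmp_path / "e.ab1")
    blob = bytearray(path.read_bytes())
    # corrupt entry 2's data: our writer stores entry 2 blocks after entry 1's
    idx = blob.find(b"AAAAA", 128 + 5)  # skip the entry-1 block
    assert idx > 0
    blob[idx : idx + 5] = b"CCCCC"
    path.write_bytes(bytes(blob))
    assert read_abif(path).bases == "AAAAA"


def test_bad_magic_rejected(tmp_path):
    p = tmp_path / "fake.ab1"
    p.write_bytes(b"FAKE" + b"\x00" * 200)
    with pytest.raises(AbifError, match="not an ABIF"):
        read_abif(p)


def test_missing_quality_entry_is_incomplete(tmp_path):
    path = write_abif("ACGT", [1, 2, 3, 4], tmp_path / "m.ab1")
    blob = bytearray(path.read_bytes())
    for off in range(0, len(blob) - 3):
        if blob[off : off + 4] == b"PCON":
            blob[off : off + 4] = b"XXXX"
    path.write_bytes(bytes(blob))
    with pytest.raises(AbifError, match="incomplete trace"):
        read_abif(path)


def test_length_mismatch_is_corrupt(tmp_path):
    path = write_abif("ACGTACGT", [9] * 8, tmp_path / "c.ab1")
    blob = bytearray(path.read_bytes())
    # shrink the declared size of every PCON entry by one
    for off in range(0, len(blob) - 3):
        if blob[off : off + 4] == b"PCON":
            (size,) = struct.unpack(">i", blob[off + 16 : off + 20])
            blob[off + 16 : off + 20] = struct.pack(">i", size - 1)
            blob[off + 12 : off + 16] = struct.pack(">i", size - 1)
    path.write_bytes(bytes(blob))
    with pytest.raises(AbifError, match="corrupt trace"):
        read_abif(path)


def test_writer_rejects_mismatched_inputs(tmp_path):
    with pytest.raises(AbifError, match="length mismatch"):
        write_abif("ACGT", [1, 2, 3], tmp_path / "bad.ab1")
    with pytest.raises(AbifError, match="quality"):
        write_abif("AC", [1, 63], tmp_path / "bad.ab1")


def test_chromatogram_invariant_enforced():
    with pytest.raises(AbifError):
        Chromatogram(name="x", bases="ACGT", qualities=[1, 2, 3])
    with pytest.raises(AbifError):
        Chromatogram(name="x", bases="AC", qualities=[1, -2])
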