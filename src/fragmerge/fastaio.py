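"""FASTA I/O and the merger's FASTA-ID bookkeeping rules.

Parsing and writing are delegated to ``Bio.SeqIO``; this module adds the
contracts the assembly pipeline relies on: records entering a merge must be
non-empty, the ID is the full header line after ``>`` (spaces kept, so trim
annotations can be appended in a human-readable way), and FASTA fragments
are used verbatim — they are never quality-trimmed, since FASTA carries no
quality scores and such files are assumed to hold already-curated sequence.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .errors import FastaError


@dataclass
class SequenceRecord:
    """One named nucleotide sequence (IUPAC alphabet, case preserved)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if "\n" in self.id or "\r" in self.id:
            raise FastaError("FASTA ID must not contain a newline")

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read all records from a FASTA file.

    Sequence lines are concatenated and whitespace-stripped. Raises
    :class:`FastaError` for a file with no FASTA header ("not FASTA") or a
    record with an empty sequence ("empty sequence record").
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip().startswith(">"):
        raise FastaError(f"not FASTA: {path}")
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = re.sub(r"\s", "", str(rec.seq))
        if not seq:
            raise FastaError(f"empty sequence record: '{rec.description}' in {path}")
        records.append(SequenceRecord(id=rec.description, sequence=seq))
    if not records:
        raise FastaError(f"not FASTA: no records in {path}")
    return records


def write_fasta(
    records: list[SequenceRecord], path: str | Path, width: int = 60
) -> Path:
    """Write records as wrapped FASTA; :func:`read_fasta` inverts it."""
    if not records:
        raise FastaError("no records to write")
    if width < 1:
        raise FastaError("line width must be positive")
    path = Path(path)
    bio = [
        _BioRecord(Seq(r.sequence), id=r.id.split(" ")[0] or "unnamed",
                   description=" ".join(r.id.split(" ")[1:]))
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)
    return path


_TRIM_SUFFIX = re.compile(r" trimmed\(w=(\d+),t=(\d+)\)$")


def annotate_trimmed_id(record_id: str, window: int, threshold: int) -> str:
    """Append the trim parameters to a FASTA ID, e.g. ``frag1 trimmed(w=10,t=20)``.

    Applied exactly once per record: an already-annotated ID is returned
    unchanged so a pipeline retry cannot stack suffixes.
    """
    if _TRIM_SUFFIX.search(record_id):
        return record_id
    return f"{record_id} trimmed(w={window},t={threshold})"


def is_trim_annotated(record_id: str) -> bool:
    return bool(_TRIM_SUFFIX.search(record_id))


def merged_sequence_id(user_id: str | None, first_fragment_id: str) -> str:
    """ID for the final merged sequence.

    The user-supplied ID wins; when omitted or blank, the merged sequence
    inherits the ID of the first fragment submitted.
    """
    if not first_fragment_id:
        raise FastaError("first fragment has no ID")
    if user_id is not None and user_id.strip():
        return user_id.strip()
    return first_fragment_id
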