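"""Pairwise overlap merging with conflict and orientation reporting.

Two sequences are aligned end to end (free end gaps) and read off column
by column: overhang columns contribute the single base present, matching
overlap columns contribute the shared base, and mismatching overlap
columns are *conflicts* that must be resolved to a single base and
reported.  Resolution prefers the base with the higher Phred-like quality
when both fragments carry qualities; otherwise the base further from its
own fragment's nearer end wins (read middles are more reliable than read
ends); a full tie keeps the first fragment's base.

When no positively-scoring overlap exists the two sequences are simply
concatenated sharing a single overlapping nucleotide — the degenerate
behaviour of the EMBOSS merger this module replaces — and the merge is
flagged for checking.

Each merge also reports its *orientation*: fragments supplied in order are
expected to overlap 3'-end-of-first to 5'-end-of-second; a merge that
joined the other way round is marked ``CHECK`` rather than ``CORRECT``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .align import AlignmentParams, align_overlap
from .errors import MergeError
from .fastaio import SequenceRecord


class Orientation(enum.Enum):
    CORRECT = "Correct"
    CHECK = "Check"


@dataclass
class Conflict:
    """One overlap column where the fragments disagree."""

    merged_position: int  # 1-based position in the merged sequence
    base_a: str
    base_b: str
    chosen: str
    rule: str


@dataclass
class PairwiseMergeReport:
    merged: SequenceRecord
    score: float
    overlap_len: int
    conflicts: list[Conflict]
    orientation: Orientation
    aligned_a: str
    aligned_b: str
    id_a: str = ""
    id_b: str = ""


def _resolve(
    base_a: str, base_b: str,
    ia: int, ib: int, len_a: int, len_b: int,
    qa: int | None, qb: int | None,
) -> tuple[str, str]:
    """Pick one base for a conflicting column; returns (base, rule)."""
    if qa is not None and qb is not None and qa != qb:
        return (base_a, f"quality {qa}>{qb}") if qa > qb else (base_b, f"quality {qb}>{qa}")
    da = min(ia, len_a - 1 - ia)
    db = min(ib, len_b - 1 - ib)
    if da != db:
        return (base_a, f"end-distance {da}>{db}") if da > db else (base_b, f"end-distance {db}>{da}")
    return base_a, "tie: first fragment"


def _end_gaps(aligned: str) -> tuple[int, int]:
    stripped_left = len(aligned) - len(aligned.lstrip("-"))
    stripped_right = len(aligned) - len(aligned.rstrip("-"))
    return stripped_left, stripped_right


def _one_base_concat(
    a: SequenceRecord, b: SequenceRecord,
    qual_a: list[int] | None, qual_b: list[int] | None,
    score: float,
) -> PairwiseMergeReport:
    """Degenerate merge: concatenate with exactly one overlapping nucleotide."""
    la, lb = len(a.sequence), len(b.sequence)
    junction_a, junction_b = a.sequence[-1], b.sequence[0]
    conflicts: list[Conflict] = []
    if junction_a.upper() != junction_b.upper():
        chosen, rule = _resolve(
            junction_a, junction_b, la - 1, 0, la, lb,
            qual_a[-1] if qual_a else None, qual_b[0] if qual_b else None,
        )
        conflicts.append(Conflict(la, junction_a, junction_b, chosen, rule))
    else:
        chosen = junction_a
    merged_seq = a.sequence[:-1] + chosen + b.sequence[1:]
    return PairwiseMergeReport(
        merged=SequenceRecord(id=a.id, sequence=merged_seq),
        score=score,
        overlap_len=1,
        conflicts=conflicts,
        orientation=Orientation.CHECK,
        aligned_a=a.sequence + "-" * (lb - 1),
        aligned_b="-" * (la - 1) + b.sequence,
        id_a=a.id,
        id_b=b.id,
    )


def merge_pair(
    a: SequenceRecord,
    b: SequenceRecord,
    qual_a: list[int] | None = None,
    qual_b: list[int] | None = None,
    params: AlignmentParams | None = None,
) -> PairwiseMergeReport:
    """Merge two overlapping sequences into one via global overlap alignment."""
    if not a.sequence or not b.sequence:
        raise MergeError("empty fragment")
    if qual_a is not None and len(qual_a) != len(a.sequence):
        raise MergeError("qual_a length does not match fragment a")
    if qual_b is not None and len(qual_b) != len(b.sequence):
        raise MergeError("qual_b length does not match fragment b")
    params = params or AlignmentParams()

    aligned_a, aligned_b, score = align_overlap(a.sequence, b.sequence, params)
    overlap_len = sum(
        1 for ca, cb in zip(aligned_a, aligned_b) if ca != "-" and cb != "-"
    )
    if score <= 0 or overlap_len == 0:
        return _one_base_concat(a, b, qual_a, qual_b, score)

    la, lb = len(a.sequence), len(b.sequence)
    merged: list[str] = []
    conflicts: list[Conflict] = []
    ia = ib = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-":
            merged.append(cb)
            ib += 1
        elif cb == "-":
            merged.append(ca)
            ia += 1
        elif ca.upper() == cb.upper():
            merged.append(ca)
            ia += 1
            ib += 1
        else:
            chosen, rule = _resolve(
                ca, cb, ia, ib, la, lb,
                qual_a[ia] if qual_a else None,
                qual_b[ib] if qual_b else None,
            )
            merged.append(chosen)
            conflicts.append(Conflict(len(merged), ca, cb, chosen, rule))
            ia += 1
            ib += 1

    lead_a, trail_a = _end_gaps(aligned_a)
    lead_b, trail_b = _end_gaps(aligned_b)
    orientation = (
        Orientation.CORRECT
        if lead_b >= lead_a and trail_a >= trail_b
        else Orientation.CHECK
    )
    return PairwiseMergeReport(
        merged=SequenceRecord(id=a.id, sequence="".join(merged)),
        score=score,
        overlap_len=overlap_len,
        conflicts=conflicts,
        orientation=orientation,
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        id_a=a.id,
        id_b=b.id,
    )
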