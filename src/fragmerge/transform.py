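"""Sequence transformations: reverse, complement, circular rotation.

Sanger fragments are sequenced from primers on either strand, so fragments
may need reversing and/or complementing before they are merged.  Assemblies
of circular genomes additionally come out at an arbitrary rotation: the
``slide`` operation rotates the merged sequence so that a landmark motif
(for hepatitis B virus, the EcoRI site GAATTC) starts at a conventional
coordinate, by convention position 1.  ``double_reference`` concatenates a
linear reference with itself so any rotation of a circular assembly aligns
against it without wrap-around end gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import SlideError
from .fastaio import SequenceRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "-": "-",
}
_COMPLEMENT_TABLE = str.maketrans(
    {**_COMPLEMENT, **{k.lower(): v.lower() for k, v in _COMPLEMENT.items()}}
)
_VALID = set(_COMPLEMENT) | {k.lower() for k in _COMPLEMENT}


@dataclass(frozen=True)
class SlideSpec:
    """Rotate a circular sequence so `motif` starts at 1-based `position`."""

    motif: str
    position: int = 1

    def __post_init__(self) -> None:
        if not self.motif:
            raise SlideError("slide motif must be non-empty")
        if self.position < 1:
            raise SlideError("slide position is 1-based and must be >= 1")


def reverse(seq: str) -> str:
    return seq[::-1]


def complement(seq: str) -> str:
    """IUPAC complement, case preserved. Unknown characters are rejected."""
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid base(s) for complement: {sorted(bad)}")
    return seq.translate(_COMPLEMENT_TABLE)


def reverse_complement(seq: str) -> str:
    return complement(seq)[::-1]


def find_circular(seq: str, motif: str) -> int | None:
    """0-based index of the first occurrence of motif in the circular seq.

    The search wraps: a motif straddling the end of the linear
    representation is found by scanning ``seq + seq[:len(motif)-1]``.
    Case-insensitive exact match; no ambiguity-code expansion.
    """
    hay = (seq + seq[: len(motif) - 1]).upper()
    idx = hay.find(motif.upper())
    return idx if idx >= 0 else None


def slide(seq: str, spec: SlideSpec) -> str:
    """Rotate `seq` so the motif's first base lands at `spec.position` (1-based).

    Raises :class:`SlideError` when the motif does not occur anywhere in the
    circular sequence; if it occurs more than once, the first circular
    occurrence is used and a warning is logged.
    """
    if len(spec.motif) > len(seq):
        raise SlideError("slide motif not found: motif longer than sequence")
    idx = find_circular(seq, spec.motif)
    if idx is None:
        raise SlideError(f"slide motif not found: {spec.motif!r}")
    hay = (seq + seq[: len(spec.motif) - 1]).upper()
    if hay.find(spec.motif.upper(), idx + 1) >= 0:
        logger.warning(
            "slide motif %r occurs more than once; using first occurrence "
            "at position %d", spec.motif, idx + 1,
        )
    shift = (idx - (spec.position - 1)) % len(seq)
    return seq[shift:] + seq[:shift]


def double_reference(ref: SequenceRecord) -> SequenceRecord:
    """Self-concatenated reference for checking rotated circular assemblies."""
    if not ref.sequence:
        raise ValueError("reference sequence is empty")
    return SequenceRecord(id=f"{ref.id}_x2", sequence=ref.sequence * 2)
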