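"""Sequential (left-fold) merging of an ordered fragment list.

Fragments must be supplied in merge order, already trimmed and
reverse/complemented; the chain merges them pairwise left to right —
``merge(merge(f1, f2), f3) ...`` — exactly ``n − 1`` merges for ``n``
fragments.  Intermediate merged sequences carry no quality scores, so
conflict resolution in later merges falls back to the positional rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .align import AlignmentParams
from .errors import MergeError
from .fastaio import SequenceRecord
from .merge import PairwiseMergeReport, merge_pair

logger = logging.getLogger(__name__)

MIN_FRAGMENTS = 2
MAX_FRAGMENTS = 12
MERGED_LENGTH_GUIDANCE = 100_000  # warn above this; not an error


@dataclass
class ChainResult:
    final: SequenceRecord
    merges: list[PairwiseMergeReport]

    @property
    def fragment_count(self) -> int:
        return len(self.merges) + 1


def merge_chain(
    fragments: list[SequenceRecord],
    qualities: list[list[int] | None] | None = None,
    params: AlignmentParams | None = None,
    max_fragments: int = MAX_FRAGMENTS,
    max_merged_length: int = MERGED_LENGTH_GUIDANCE,
) -> ChainResult:
    """Merge 2–12 ordered fragments into one sequence (n − 1 pairwise merges)."""
    n = len(fragments)
    if n < MIN_FRAGMENTS:
        raise MergeError("need at least two fragments")
    if n > max_fragments:
        raise MergeError(f"too many fragments: {n} > {max_fragments}")
    if qualities is None:
        qualities = [None] * n
    if len(qualities) != n:
        raise MergeError("qualities list must parallel fragments")
    for frag in fragments:
        if not frag.sequence:
            raise MergeError("empty fragment")

    current = fragments[0]
    current_qual = qualities[0]
    merges: list[PairwiseMergeReport] = []
    for frag, qual in zip(fragments[1:], qualities[1:]):
        report = merge_pair(current, frag, current_qual, qual, params)
        merges.append(report)
        current = report.merged
        current_qual = None  # merged intermediates carry no quality scores
    if len(current.sequence) > max_merged_length:
        logger.warning(
            "merged sequence is %d nt, above the recommended maximum of %d",
            len(current.sequence), max_merged_length,
        )
    return ChainResult(final=current, merges=merges)
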