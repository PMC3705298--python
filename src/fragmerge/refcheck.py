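"""Post-assembly validation against reference sequences.

The merged sequence is aligned to one or more references purely as a
check — references never alter the assembly (this is not a mapping
assembler).  For a single reference a pairwise global alignment with free
end gaps is produced; for several references each is aligned to the merged
sequence and the pairwise gap patterns are reconciled into one multiple
alignment threaded on the merged sequence.

The report renders a match line under the alignment: ``|`` marks columns
where every sequence carries the identical base, a space marks any
disagreement.  A gap in any row counts as a disagreement, so end overhangs
(e.g. from a rotated circular assembly checked against a single-copy
reference) show up in the mismatch count; checking against a double-length
reference avoids that artefact.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import AlignmentParams, align_overlap
from .errors import MergeError
from .fastaio import SequenceRecord


@dataclass
class ReferenceCheckReport:
    ids: list[str]          # merged first, then each reference
    rows: list[str]         # gapped aligned strings, equal length
    match_line: str
    n_matches: int
    n_mismatches: int

    @property
    def alignment_length(self) -> int:
        return len(self.match_line)

    def as_text(self, width: int = 60) -> str:
        """Interleaved plain-text rendering with the match line."""
        label_w = max(len(i) for i in self.ids) + 2
        blocks = []
        for start in range(0, self.alignment_length, width):
            lines = [
                f"{name:<{label_w}}{row[start:start + width]}"
                for name, row in zip(self.ids, self.rows)
            ]
            lines.append(" " * label_w + self.match_line[start:start + width])
            blocks.append("\n".join(lines))
        footer = f"\nMatches: {self.n_matches}  Mismatches: {self.n_mismatches}\n"
        return "\n\n".join(blocks) + footer


def _insertion_profile(aligned_master: str) -> list[int]:
    """Gap-run lengths in the master row: profile[p] = gaps before base p."""
    n_bases = len(aligned_master) - aligned_master.count("-")
    profile = [0] * (n_bases + 1)
    p = 0
    for ch in aligned_master:
        if ch == "-":
            profile[p] += 1
        else:
            p += 1
    return profile


def _expand_rows(
    aligned_master: str, aligned_other: str, target_profile: list[int]
) -> str:
    """Re-pad `aligned_other` so the master row matches `target_profile`."""
    own_profile = _insertion_profile(aligned_master)
    out: list[str] = []
    k = 0  # cursor in the pairwise alignment columns
    p = 0  # master base index
    n_cols = len(aligned_master)
    while p <= len(own_profile) - 1:
        run = own_profile[p]
        chunk = aligned_other[k : k + run]
        out.append(chunk + "-" * (target_profile[p] - run))
        k += run
        if k < n_cols:
            out.append(aligned_other[k])
            k += 1
        p += 1
    return "".join(out)


def check_against_references(
    merged: SequenceRecord,
    refs: list[SequenceRecord],
    params: AlignmentParams | None = None,
) -> ReferenceCheckReport:
    """Align the merged sequence to the references and tally agreement."""
    if not refs:
        raise MergeError("no references given")
    params = params or AlignmentParams()

    pairwise = [align_overlap(merged.sequence, r.sequence, params) for r in refs]
    profiles = [_insertion_profile(am) for am, _, _ in pairwise]
    master_profile = [max(col) for col in zip(*profiles)]

    master_row = []
    seq = merged.sequence
    for p, gaps in enumerate(master_profile):
        master_row.append("-" * gaps)
        if p < len(seq):
            master_row.append(seq[p])
    rows = ["".join(master_row)]
    for (am, ar, _), _prof in zip(pairwise, profiles):
        rows.append(_expand_rows(am, ar, master_profile))

    length = len(rows[0])
    assert all(len(r) == length for r in rows)
    match_line = "".join(
        "|"
        if all(r[c] != "-" for r in rows)
        and len({r[c].upper() for r in rows}) == 1
        else " "
        for c in range(length)
    )
    n_matches = match_line.count("|")
    return ReferenceCheckReport(
        ids=[merged.id] + [r.id for r in refs],
        rows=rows,
        match_line=match_line,
        n_matches=n_matches,
        n_mismatches=length - n_matches,
    )
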