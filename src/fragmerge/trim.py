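"""Sliding-window quality trimming of chromatogram ends.

A window of ``window`` consecutive bases is slid inward from each end of
the trace until every quality score inside the window is at or above
``threshold``; everything outside the first such window (from each side) is
trimmed away.  The passing window itself is retained.  Defaults of window
10 and threshold 20 suit typical Sanger amplicon data.

Each trimmed fragment receives a status flag mirroring the tool's
notification icons:

* ``GREEN``  — trimmed, and no warning applies;
* ``YELLOW`` — trimmed length below the short-amplicon warning length
  (default 200 nt);
* ``RED``    — trimmed to below the trimmed-length threshold percentage of
  the original length (default 50%); takes precedence over YELLOW;
* ``BLUE``   — a FASTA fragment, never trimmed, reported as 100% retained.

Flags warn; they never exclude a fragment from the merge.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .abif import Chromatogram
from .errors import TrimmedToZeroError
from .fastaio import SequenceRecord, annotate_trimmed_id

DEFAULT_TRIM_WINDOW = 10
DEFAULT_TRIM_THRESHOLD = 20
DEFAULT_WARNING_LENGTH = 200
DEFAULT_TRIMMED_PCT = 50.0


class Flag(enum.Enum):
    GREEN = "green"
    YELLOW = "yellow"
    RED = "red"
    BLUE = "blue"


@dataclass(frozen=True)
class TrimParams:
    window: int = DEFAULT_TRIM_WINDOW
    threshold: int = DEFAULT_TRIM_THRESHOLD

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("trim window must be >= 1")
        if self.threshold < 0:
            raise ValueError("trim threshold must be >= 0")


@dataclass
class TrimResult:
    record: SequenceRecord
    left_trimmed: int
    right_trimmed: int
    original_length: int
    flag: Flag = Flag.GREEN

    @property
    def percent_retained(self) -> float:
        return 100.0 * len(self.record.sequence) / self.original_length


def _first_passing_window(qualities: list[int], window: int, threshold: int) -> int | None:
    """Smallest start index whose next `window` scores all pass, else None."""
    n = len(qualities)
    if n < window:
        # degenerate: shorter than the window — keep whole only if all pass
        return 0 if all(q >= threshold for q in qualities) else None
    run = 0
    for i, q in enumerate(qualities):
        run = run + 1 if q >= threshold else 0
        if run >= window:
            return i - window + 1
    return None


def trim(chromatogram: Chromatogram, params: TrimParams | None = None) -> TrimResult:
    """Trim both ends of a chromatogram by the sliding-window rule.

    Raises :class:`TrimmedToZeroError` when no window passes from either
    end (the trace is unusable and no merge should be attempted).
    """
    params = params or TrimParams()
    quals = chromatogram.qualities
    n = len(quals)
    if n == 0:
        raise TrimmedToZeroError(
            f"'{chromatogram.name}' is empty; no merge performed"
        )
    left = _first_passing_window(quals, params.window, params.threshold)
    right = _first_passing_window(quals[::-1], params.window, params.threshold)
    if left is None or right is None:
        raise TrimmedToZeroError(
            f"'{chromatogram.name}' trimmed to length zero; no merge performed"
        )
    last = n - 1 - right
    if left > last:
        raise TrimmedToZeroError(
            f"'{chromatogram.name}' trimmed to length zero; no merge performed"
        )
    kept = chromatogram.bases[left : last + 1]
    record = SequenceRecord(
        id=annotate_trimmed_id(chromatogram.name, params.window, params.threshold),
        sequence=kept,
    )
    return TrimResult(
        record=record,
        left_trimmed=left,
        right_trimmed=n - 1 - last,
        original_length=n,
    )


def trimmed_qualities(chromatogram: Chromatogram, result: TrimResult) -> list[int]:
    """Quality scores for the kept region of a trimmed chromatogram."""
    n = result.original_length
    return chromatogram.qualities[result.left_trimmed : n - result.right_trimmed]


def assign_flag(
    result: TrimResult,
    warning_length: int = DEFAULT_WARNING_LENGTH,
    trimmed_pct_threshold: float = DEFAULT_TRIMMED_PCT,
) -> Flag:
    """Status flag for a trimmed chromatogram (RED beats YELLOW)."""
    if result.percent_retained < trimmed_pct_threshold:
        return Flag.RED
    if len(result.record.sequence) < warning_length:
        return Flag.YELLOW
    return Flag.GREEN
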