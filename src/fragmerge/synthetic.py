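"""Simulated genomes, overlapping fragment sets and AB1/FASTA fixtures.

This module emulates the study design the merger targets: a small genome
(linear, or circular like the ~3.2 kb hepatitis B virus genome) covered by
2–12 overlapping Sanger amplicons supplied in order, some possibly
sequenced on the opposite strand.  Each simulated chromatogram carries a
quality profile with low-quality flanks and a high-quality plateau:

* flank ("junk") bases are random and do not come from the genome; their
  qualities ramp linearly from ``end_quality`` (default 2) up to just
  below the default trim threshold, so

* sliding-window trimming with the default parameters removes exactly the
  flanks and keeps exactly the genomic core (plateau quality 40).

This makes trim boundaries analytically predictable, which is what the
tests need; it deliberately does not model chromatogram peak shapes or
realistic error processes (a substitution-injection knob exists solely to
exercise conflict reporting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .abif import write_abif
from .errors import SyntheticError
from .fastaio import SequenceRecord
from .transform import reverse_complement

_BASES = np.array(list("ACGT"))

PLATEAU_QUALITY = 40
END_QUALITY = 2
RAMP_TOP = 19  # strictly below the default trim threshold of 20


def simulate_genome(
    length: int,
    seed: int,
    motif: str | None = None,
    motif_pos: int | None = None,
    max_retries: int = 50,
) -> SequenceRecord:
    """Uniform-random ACGT genome, optionally with a uniquely planted motif.

    ``motif_pos`` is 1-based.  Uniqueness is circular (the motif occurs
    exactly once even across the end-start junction), so the genome can be
    used to test rotation to the motif.  Redraws on collision; raises
    :class:`SyntheticError` if a unique placement cannot be found.
    """
    if length < 1:
        raise SyntheticError("genome length must be positive")
    if motif is not None:
        if motif_pos is None:
            motif_pos = 1
        if len(motif) > length:
            raise SyntheticError("motif placement failed: motif longer than genome")
        if not 1 <= motif_pos <= length - len(motif) + 1:
            raise SyntheticError("motif placement failed: position out of range")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        seq = "".join(rng.choice(_BASES, size=length))
        if motif is None:
            return SequenceRecord(id=f"sim_genome_{seed}", sequence=seq)
        upper = motif.upper()
        planted = (
            seq[: motif_pos - 1] + upper + seq[motif_pos - 1 + len(motif):]
        )
        circular = planted + planted[: len(motif) - 1]
        if circular.count(upper) == 1:
            return SequenceRecord(id=f"sim_genome_{seed}", sequence=planted)
    raise SyntheticError("motif placement failed: no unique placement found")


@dataclass(frozen=True)
class FragmentPlan:
    """How to cut a genome into an ordered, overlapping fragment set."""

    n_fragments: int
    overlap_range: tuple[int, int] = (20, 40)
    circular: bool = False
    ramp_len: int = 25          # low-quality junk flank per end (0 = none)
    plateau_quality: int = PLATEAU_QUALITY
    end_quality: int = END_QUALITY
    allow_revcomp: bool = False  # flip ~half the fragments to the other strand
    substitutions_per_overlap: int = 0  # injected errors, to exercise conflicts
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_fragments <= 12:
            raise SyntheticError("n_fragments must be in [2, 12]")
        lo, hi = self.overlap_range
        if lo < 1 or hi < lo:
            raise SyntheticError("overlap_range must satisfy 1 <= min <= max")


@dataclass
class SimulatedFragment:
    """One simulated chromatogram plus its ground truth."""

    record: SequenceRecord       # junk flank + core (possibly revcomp'd) + junk flank
    qualities: list[int]
    reverse: bool
    complement: bool
    core_start: int              # 0-based genome coordinate of the core
    core_end: int                # exclusive

    @property
    def core_length(self) -> int:
        return self.core_end - self.core_start


def _ramp(n: int, low: int, high: int) -> list[int]:
    if n == 0:
        return []
    return [int(round(v)) for v in np.linspace(low, high, n)]


def fragment_genome(
    genome: SequenceRecord, plan: FragmentPlan
) -> list[SimulatedFragment]:
    """Cut a genome into ordered overlapping fragments per the plan.

    For a circular plan the genome is first rotated by a random offset, so
    the merged assembly is a rotation of the input; a linear plan tiles the
    genome from base 1 and merging recovers it exactly.
    """
    rng = np.random.default_rng(plan.seed)
    n = plan.n_fragments
    seq = genome.sequence
    length = len(seq)

    offset = 0
    if plan.circular:
        offset = int(rng.integers(0, length))
        seq = seq[offset:] + seq[:offset]

    overlaps = [
        int(rng.integers(plan.overlap_range[0], plan.overlap_range[1] + 1))
        for _ in range(n - 1)
    ]
    bounds = [round(i * length / n) for i in range(n + 1)]
    frags: list[tuple[int, int]] = []
    for i in range(n):
        start = bounds[i] - (overlaps[i - 1] if i > 0 else 0)
        end = bounds[i + 1]
        if start < 0 or end - start <= 0:
            raise SyntheticError("cannot tile genome: fragments too short for overlaps")
        frags.append((start, end))
    for (s0, e0), (s1, e1) in zip(frags, frags[1:]):
        if s1 <= s0 or e1 <= e0 or e0 - s1 < plan.overlap_range[0]:
            raise SyntheticError("cannot tile genome: overlap exceeds fragment length")

    out: list[SimulatedFragment] = []
    for i, (start, end) in enumerate(frags):
        core = seq[start:end]
        if plan.substitutions_per_overlap and i > 0:
            # inject substitutions inside the left overlap of this fragment
            ov = overlaps[i - 1]
            core_list = list(core)
            for _ in range(plan.substitutions_per_overlap):
                pos = int(rng.integers(0, ov))
                core_list[pos] = rng.choice(
                    [b for b in "ACGT" if b != core_list[pos].upper()]
                )
            core = "".join(core_list)
        flip = plan.allow_revcomp and bool(rng.integers(0, 2))
        stored_core = reverse_complement(core) if flip else core
        junk_l = "".join(rng.choice(_BASES, size=plan.ramp_len))
        junk_r = "".join(rng.choice(_BASES, size=plan.ramp_len))
        bases = junk_l + stored_core + junk_r
        quals = (
            _ramp(plan.ramp_len, plan.end_quality, RAMP_TOP)
            + [plan.plateau_quality] * len(stored_core)
            + _ramp(plan.ramp_len, RAMP_TOP, plan.end_quality)
        )
        out.append(SimulatedFragment(
            record=SequenceRecord(id=f"frag{i + 1}", sequence=bases),
            qualities=quals,
            reverse=flip,
            complement=flip,
            core_start=(start + offset) % length,
            core_end=end + offset if end + offset <= length else (end + offset) % length,
        ))
    return out


def write_fixture_set(
    genome: SequenceRecord, plan: FragmentPlan, directory: str | Path
) -> tuple[list[Path], Path]:
    """Write one AB1 file per simulated fragment plus a ground-truth manifest.

    Returns ``(ab1_paths, manifest_path)``; the manifest is a TSV of
    fragment order, strand flags and genome coordinates of the core.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frags = fragment_genome(genome, plan)
    paths: list[Path] = []
    rows = ["order\tname\trev\tcomp\tcore_start\tcore_end\ttotal_len"]
    for i, frag in enumerate(frags, start=1):
        path = directory / f"frag{i}.ab1"
        write_abif(frag.record.sequence, frag.qualities, path)
        paths.append(path)
        rows.append(
            f"{i}\t{frag.record.id}\t{int(frag.reverse)}\t{int(frag.complement)}\t"
            f"{frag.core_start}\t{frag.core_end}\t{len(frag.record.sequence)}"
        )
    manifest = directory / "manifest.tsv"
    manifest.write_text("\n".join(rows) + "\n")
    return paths, manifest
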