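"""End-to-end fragment-merging pipeline.

Orchestrates the full run: load each fragment in merge order (AB1
chromatogram or FASTA), quality-trim chromatograms and flag them,
reverse/complement as requested, chain-merge, optionally rotate a circular
assembly to a landmark motif, optionally check against references, and
write every output file plus a ZIP archive (excluding the binary
chromatograms) whose internal folder is named with the run date and time.

The pipeline is deterministic: identical inputs and configuration produce
identical outputs apart from the timestamp, which can be pinned via
``RunConfig.timestamp``.
"""

from __future__ import annotations

import datetime as _dt
import enum
import logging
import re
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

from . import abif, fastaio
from .align import AlignmentParams
from .chain import ChainResult, MAX_FRAGMENTS, MERGED_LENGTH_GUIDANCE, merge_chain
from .errors import ConfigError, FragmergeError
from .fastaio import SequenceRecord, merged_sequence_id
from .refcheck import ReferenceCheckReport, check_against_references
from .transform import SlideSpec, complement, reverse, slide
from .trim import (
    DEFAULT_TRIMMED_PCT,
    DEFAULT_WARNING_LENGTH,
    Flag,
    TrimParams,
    assign_flag,
    trim,
    trimmed_qualities,
)

logger = logging.getLogger(__name__)


class FileType(enum.Enum):
    AB1 = "ab1"
    FASTA = "fasta"


_FASTA_EXTENSIONS = {".fa", ".fasta", ".fsa", ".fna"}


def detect_type(path: str | Path) -> FileType:
    """Guess the input type from the filename extension.

    ``.ab1`` is a chromatogram; common FASTA extensions (and ``.txt`` files
    whose first character is ``>``) are FASTA.  Anything else needs an
    explicit override.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".ab1":
        return FileType.AB1
    if ext in _FASTA_EXTENSIONS:
        return FileType.FASTA
    if ext == ".txt" and path.exists():
        with open(path, "rb") as fh:
            if fh.read(1) == b">":
                return FileType.FASTA
    raise ConfigError(f"cannot detect type of {path}; specify it explicitly")


@dataclass
class FragmentSpec:
    """One ordered input fragment and its per-fragment options."""

    path: Path
    ftype: FileType | None = None  # None: auto-detect from extension
    trim: TrimParams = field(default_factory=TrimParams)
    reverse: bool = False
    complement: bool = False

    def resolved_type(self) -> FileType:
        return self.ftype if self.ftype is not None else detect_type(self.path)


@dataclass
class RunConfig:
    fragments: list[FragmentSpec]
    outdir: Path = Path(".")
    warning_length: int = DEFAULT_WARNING_LENGTH
    trimmed_pct_threshold: float = DEFAULT_TRIMMED_PCT
    merged_id: str | None = None
    slide: SlideSpec | None = None
    reference_path: Path | None = None
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    max_fragments: int = MAX_FRAGMENTS
    max_merged_length: int = MERGED_LENGTH_GUIDANCE
    timestamp: str | None = None  # YYYYMMDD-HHMMSS; None = now
    make_archive: bool = True


@dataclass
class FragmentSummary:
    order: int
    name: str
    ftype: FileType
    original_length: int
    trimmed_length: int
    left_trimmed: int
    right_trimmed: int
    percent_retained: float
    flag: Flag


@dataclass
class RunResult:
    final: SequenceRecord
    chain: ChainResult
    summaries: list[FragmentSummary]
    refcheck: ReferenceCheckReport | None
    outdir: Path
    files: dict[str, str]  # filename -> description
    archive: Path | None


def _sanitize(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "_", name).strip("_") or "sequence"


@dataclass
class _Prepared:
    record: SequenceRecord
    qualities: list[int] | None
    untrimmed: SequenceRecord
    summary: FragmentSummary


def _prepare_fragment(spec: FragmentSpec, order: int, config: RunConfig) -> _Prepared:
    ftype = spec.resolved_type()
    if ftype is FileType.AB1:
        chrom = abif.read_abif(spec.path)
        untrimmed = SequenceRecord(id=chrom.name, sequence=chrom.bases)
        result = trim(chrom, spec.trim)
        quals = trimmed_qualities(chrom, result)
        flag = assign_flag(result, config.warning_length, config.trimmed_pct_threshold)
        record = result.record
        summary = FragmentSummary(
            order=order, name=chrom.name, ftype=ftype,
            original_length=result.original_length,
            trimmed_length=len(record.sequence),
            left_trimmed=result.left_trimmed,
            right_trimmed=result.right_trimmed,
            percent_retained=result.percent_retained,
            flag=flag,
        )
    else:
        records = fastaio.read_fasta(spec.path)
        record = records[0]
        if len(records) > 1:
            logger.warning(
                "%s holds %d records; using the first (%r)",
                spec.path, len(records), record.id,
            )
        untrimmed = record
        quals = None
        summary = FragmentSummary(
            order=order, name=record.id, ftype=ftype,
            original_length=len(record.sequence),
            trimmed_length=len(record.sequence),
            left_trimmed=0, right_trimmed=0,
            percent_retained=100.0,
            flag=Flag.BLUE,
        )
    if spec.reverse:
        record = SequenceRecord(record.id, reverse(record.sequence))
        quals = quals[::-1] if quals is not None else None
    if spec.complement:
        record = SequenceRecord(record.id, complement(record.sequence))
    return _Prepared(record=record, qualities=quals, untrimmed=untrimmed, summary=summary)


def _merge_report_text(i: int, report) -> str:
    lines = [
        f"Merge {i}",
        f"First fragment : {report.id_a}",
        f"Second fragment: {report.id_b}",
        f"Score          : {report.score:.1f}",
        f"Overlap length : {report.overlap_len}",
        f"Orientation    : {report.orientation.value}",
        f"Merged length  : {len(report.merged.sequence)}",
        "",
        f"Conflicts ({len(report.conflicts)}):",
        "merged_pos\tbase_1\tbase_2\tused\trule",
    ]
    for c in report.conflicts:
        lines.append(f"{c.merged_position}\t{c.base_a}\t{c.base_b}\t{c.chosen}\t{c.rule}")
    lines += ["", "Alignment:"]
    width = 60
    match = "".join(
        "|" if x != "-" and y != "-" and x.upper() == y.upper() else " "
        for x, y in zip(report.aligned_a, report.aligned_b)
    )
    for start in range(0, len(report.aligned_a), width):
        lines.append(f"seq1  {report.aligned_a[start:start + width]}")
        lines.append(f"      {match[start:start + width]}")
        lines.append(f"seq2  {report.aligned_b[start:start + width]}")
        lines.append("")
    return "\n".join(lines) + "\n"


def _summary_tsv(summaries: list[FragmentSummary]) -> str:
    header = "order\tname\ttype\toriginal_len\ttrimmed_len\tleft\tright\tpct\tflag"
    rows = [header]
    for s in summaries:
        rows.append(
            f"{s.order}\t{s.name}\t{s.ftype.value}\t{s.original_length}\t"
            f"{s.trimmed_length}\t{s.left_trimmed}\t{s.right_trimmed}\t"
            f"{s.percent_retained:.1f}\t{s.flag.value}"
        )
    return "\n".join(rows) + "\n"


def run(config: RunConfig) -> RunResult:
    """Execute a full merge run and write all outputs under ``config.outdir``."""
    n = len(config.fragments)
    if n < 2:
        raise ConfigError("need at least two fragments")
    if n > config.max_fragments:
        raise ConfigError(f"too many fragments: {n} > {config.max_fragments}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_records: list[str] = []

    class _Collector(logging.Handler):
        def emit(self, rec: logging.LogRecord) -> None:
            log_records.append(self.format(rec))

    collector = _Collector()
    collector.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("fragmerge")
    root.addHandler(collector)
    try:
        prepared: list[_Prepared] = []
        for order, spec in enumerate(config.fragments, start=1):
            try:
                prepared.append(_prepare_fragment(spec, order, config))
            except FragmergeError as exc:
                raise type(exc)(f"fragment {order} ({spec.path}): {exc}") from exc
        for p in prepared:
            if p.summary.flag in (Flag.YELLOW, Flag.RED):
                logger.warning(
                    "fragment %d (%s) flagged %s (%d nt kept, %.1f%%)",
                    p.summary.order, p.summary.name, p.summary.flag.value,
                    p.summary.trimmed_length, p.summary.percent_retained,
                )

        chain = merge_chain(
            [p.record for p in prepared],
            [p.qualities for p in prepared],
            config.alignment,
            max_fragments=config.max_fragments,
            max_merged_length=config.max_merged_length,
        )
        final_id = merged_sequence_id(config.merged_id, prepared[0].record.id)
        final_seq = chain.final.sequence
        if config.slide is not None:
            final_seq = slide(final_seq, config.slide)
            final_id += f" slid({config.slide.motif}@{config.slide.position})"
        final = SequenceRecord(id=final_id, sequence=final_seq)

        refs = None
        report = None
        if config.reference_path is not None:
            refs = fastaio.read_fasta(config.reference_path)
            report = check_against_references(final, refs, config.alignment)

        # ---- write outputs -------------------------------------------------
        files: dict[str, str] = {}

        def _write(name: str, text: str, description: str) -> None:
            (outdir / name).write_text(text)
            files[name] = description

        for p in prepared:
            tag = f"{p.summary.order:02d}_{_sanitize(p.summary.name)}"
            fastaio.write_fasta([p.untrimmed], outdir / f"Input_{tag}.fasta")
            files[f"Input_{tag}.fasta"] = (
                f"Untrimmed input sequence data for fragment {p.summary.order}"
            )
            fastaio.write_fasta([p.record], outdir / f"ToMerge_{tag}.fasta")
            files[f"ToMerge_{tag}.fasta"] = (
                f"Fragment {p.summary.order} as merged (trimmed/oriented)"
            )

        merged_name = f"Merge0_{_sanitize(final.id.split()[0])}.fasta"
        fastaio.write_fasta([final], outdir / merged_name)
        files[merged_name] = "Final merged sequence"

        for i, rep in enumerate(chain.merges, start=1):
            _write(f"outFile{i}.txt", _merge_report_text(i, rep),
                   f"Detailed output of merge {i} of {len(chain.merges)}")

        _write("summary.tsv", _summary_tsv([p.summary for p in prepared]),
               "Per-fragment summary: trimming counts, percent retained, flag")

        if refs is not None and report is not None:
            fastaio.write_fasta(refs, outdir / "reference.fasta")
            files["reference.fasta"] = "Reference sequence(s) as submitted"
            fastaio.write_fasta([final] + refs, outdir / "merged_plus_refs_unaligned.fasta")
            files["merged_plus_refs_unaligned.fasta"] = (
                "Merged sequence and references, unaligned"
            )
            aligned = [
                SequenceRecord(id=i, sequence=row)
                for i, row in zip(report.ids, report.rows)
            ]
            fastaio.write_fasta(aligned, outdir / "merged_plus_refs_aligned.fasta")
            files["merged_plus_refs_aligned.fasta"] = (
                "Merged sequence aligned against the reference(s), FASTA"
            )
            _write("reference_alignment.txt", report.as_text(),
                   "Merged-vs-reference alignment with match line and counts")

        _write("run.log", "\n".join(log_records) + ("\n" if log_records else ""),
               "Warnings and notices emitted during the run")

        readme = ["README.txt — contents of this archive", ""]
        for name in sorted(files):
            readme.append(f"{name}\n    {files[name]}")
        readme.append("README.txt\n    This file")
        _write("README.txt", "\n".join(readme) + "\n", "This file")

        archive = None
        if config.make_archive:
            stamp = config.timestamp or _dt.datetime.now().strftime("%Y%m%d-%H%M%S")
            archive = write_archive(outdir, list(files), stamp)

        return RunResult(
            final=final, chain=chain, summaries=[p.summary for p in prepared],
            refcheck=report, outdir=outdir, files=files, archive=archive,
        )
    finally:
        root.removeHandler(collector)


def write_archive(outdir: Path, filenames: list[str], stamp: str) -> Path:
    """Bundle the run's output files into a ZIP archive.

    Members sit inside a folder named with the run date-time; binary input
    chromatograms are never included.
    """
    outdir = Path(outdir)
    archive = outdir / f"fragmerge_{stamp}.zip"
    with zipfile.ZipFile(archive, "w", zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(filenames):
            if name.lower().endswith(".ab1"):
                continue
            zf.write(outdir / name, arcname=f"{stamp}/{name}")
    return archive
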