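# Methods

## Scope and model

`fragmerge` assembles 2–12 *ordered* overlapping sequence fragments — the
situation of direct Sanger sequencing of long amplicons, where the primer
layout tells the user the fragment order and strand up front. It is neither
a shotgun assembler (no ordering/orientation inference) nor a mapping
assembler (references are used only to check the result, never to build
it). The final merged length is intended to stay below 100,000 nt; longer
assemblies trigger a warning, not an error.

## AB1 parsing

Only two blocks of the ABIF container are used: `PBAS` (called bases) and
`PCON` (per-base quality scores, 0–62). Sequencers write each twice —
directory entry 1 holds user-edited calls, entry 2 the raw basecaller
output. The reader prefers entry 1 and falls back to entry 2; which entry
the original Sanger workflows used is a convention, and this choice (edited
calls win) is the one most users expect from an editor-exported trace. All
integers are big-endian. Ambiguity codes in the base calls are preserved
verbatim — the merger never disambiguates them, nor does it detect or strip
primer/vector sequence.

The companion writer emits a minimal trace (header, directory, PBAS/PCON
entries 1 and 2) so pipelines can be exercised from simulated data; it
writes no electropherogram arrays, so such files are fixtures, not
renderable traces. `Bio.SeqIO`'s `abi` parser reads them identically, which
the test suite uses as an independent round-trip oracle.

## Quality trimming

A window of `window` consecutive bases (default 10) slides inward from
each end until every score in it is ≥ `threshold` (default 20); the kept
region runs from the first base of the first passing window on the left to
the last base of the last passing window on the right. Two readings of
"slide until the window passes" exist — keep the passing window or cut it
too; this implementation keeps it, the standard behaviour of
quality-trimming tools. The scan step is 1 base. A trace shorter than the
window is kept whole only when every base passes. When no window passes
from either end, or the two kept boundaries cross, the trace is "trimmed to
length zero": this is an error that aborts the run before any merge, since
a vanished fragment would silently corrupt the chain.

Status flags mirror the tool's notification icons: RED when the kept
fraction falls below `trimmed_pct_threshold` (default 50%), else YELLOW
when the kept length falls below `warning_length` (default 200 nt), else
GREEN; FASTA fragments are BLUE and reported as 100% retained. RED is
ranked above YELLOW when both conditions hold (the two were presented as
distinct icons without a stated precedence; severity ordering was chosen).
Flags never exclude a fragment from the merge.

## Overlap alignment and merging

Fragments are merged pairwise by a semi-global Needleman–Wunsch/Gotoh
alignment: both sequences aligned end to end, affine gap costs inside the
overlap, end gaps free. Scoring uses the EDNAFULL matrix (+5 match, −4
mismatch, reduced penalties against IUPAC codes; loaded from Biopython's
`NUC.4.4` data) with gap open 50 and extend 0.5 — the defaults of the
EMBOSS `merger` program whose role this module takes over. A gap of length
L costs `open + (L−1)·extend`. Scores therefore live on this scheme's
scale; no external score scale is reproduced. Alignment is case-insensitive
(scores computed on upper-cased bases, input case preserved in output).

Determinism: DP ties prefer diagonal, then gap-in-second-sequence, then
gap-in-first; among equal-scoring alignment end points the one with the
smallest trailing overhang wins. The DP kernels are numba-compiled; the
matrices are float32 (all scores are multiples of 0.5 well inside float32's
exact-integer range, so arithmetic is exact).

The merged sequence is read column-by-column: overhang columns contribute
their single base, matching overlap columns the shared base. Mismatching
overlap columns are **conflicts**, resolved by: higher per-base quality
wins when both fragments carry qualities; otherwise (or on a quality tie)
the base lying further from its own fragment's nearer end wins — read
middles are more trustworthy than read ends; a complete tie keeps the
first fragment's base. Every conflict is reported with both bases, the
chosen base and the rule that fired.

If the best alignment score is ≤ 0 (no positively-scoring overlap exists),
the two sequences are concatenated sharing exactly one overlapping
nucleotide, the degenerate behaviour users of the classic merger will
recognise; the merge is flagged `Check`. Orientation is otherwise derived
from the end-gap structure of the alignment: `Correct` means the overlap
joins the 3′ end of the first sequence to the 5′ end of the second, the
geometry expected for correctly ordered fragments.

Chaining is a left fold: `merge(merge(f1, f2), f3)…`, exactly n − 1 merges.
Intermediate merged sequences carry no quality scores (mirroring the
FASTA-only handoff between successive merges in the original pipe chain),
so conflicts in later merges fall back to the positional rule. The
12-fragment cap is an interface convention, not algorithmic, and is
overridable.

## Circular rotation (slide)

A circular assembly is rotated so a landmark motif starts at a 1-based
target coordinate — e.g. hepatitis B's EcoRI site `GAATTC` at position 1.
The motif search is exact-match, case-insensitive, without ambiguity-code
expansion, and circular: a motif straddling the linear end is found by
scanning `seq + seq[:len(motif)−1]`. A missing motif is an error (no
rotation applied); multiple occurrences use the first and log a warning.
Sliding is only meaningful for circular assemblies, so the pipeline applies
it only when a slide specification is given.

## Reference checking

The merged sequence is aligned to each reference with the same semi-global
scheme; for several references the pairwise gap patterns are reconciled by
threading them onto the merged sequence (per-position maximum insertion
counts), yielding one multiple alignment without a full MSA program — the
deliverable is the match line and counts, not a phylogeny-grade alignment.
A column is a match (`|`) only when *all* rows carry the identical base; a
gap in any row is a disagreement. This strict convention makes end
overhangs visible in the counts, which is intentional: a rotated circular
assembly checked against a single-copy reference shows long overhang
mismatch runs, and the documented remedy is a double-length reference
(`double_reference`), against which only the unmatched second copy remains
unpaired.

## Synthetic data

The generator reproduces the study design the merger targets: a uniform
random ACGT genome (optionally with a uniquely planted motif, uniqueness
checked circularly), cut into n fragments whose adjacent overlaps are drawn
from a configurable range (default 20–40 nt), optionally starting from a
random rotation (circular plans) and optionally flipping ~half the
fragments to the opposite strand with the matching rev/comp flags.
Simulated chromatograms get junk flanks of `ramp_len` random non-genomic
bases (default 25 per end) whose qualities ramp linearly from 2 to 19 —
kept strictly below the default trim threshold of 20 so that default
trimming removes *exactly* the flanks — and a quality-40 plateau over the
genomic core. This makes trim boundaries analytically predictable, the
property the tests lean on. An optional substitution-injection knob plants
mismatches inside overlaps to exercise conflict reporting.

What the generator does **not** model: chromatogram peak data, realistic
error/quality processes (miscalls correlated with low quality, indels,
homopolymer noise), primer or vector contamination, and non-uniform base
composition. Passing tests therefore demonstrate the mechanics of
trimming, merging, rotation and reporting — not robustness to poor-quality
real traces, where low-quality miscalls surviving a lenient trim can still
produce false indels (the user-facing guidance to check conflicts and the
reference alignment stands).

Genome recovery guarantees assume error-free fragments with overlaps ≥ 20
that occur uniquely in the genome; random ACGT genomes ≥ 1 kb with the
default overlap range satisfy this with overwhelming probability at the
seeds used. Short-alphabet or repeat-rich sequences can legitimately merge
at a spurious overlap; that is a property of overlap assembly, not a
defect.

## Problem sizes and numerical choices

Tests and the acceptance script run genomes of 0.3–8 kb with 2–12
fragments, the scale of single genes to small viral genomes the tool is
aimed at; alignment cost is O(n·m) per merge in time and memory (three
float32 + three int8 matrices). The largest exercised case (10 kb genome,
12 fragments) merges in seconds. Degenerate inputs: empty fragments are
rejected before alignment; a fragment trimmed to zero aborts the run with
the offending fragment's index; equal sequences merge to themselves.

## Pipeline conventions

The command-line interface replaces an input form: per-fragment settings
ride on the fragment argument (`path[:rev][:comp][:w=N][:t=N][:type=...]`),
global options mirror the form labels, and a YAML file can stand in for the
argument list. File type is auto-detected from the extension (`.ab1` vs
`.fa/.fasta/.fsa/.fna`, plus `.txt` peeking for `>`), overridable per
fragment. Outputs use stable name prefixes (`Input_`, `ToMerge_`,
`Merge0_`, `outFile<i>`, `summary.tsv`, `README.txt`, `run.log`) and are
zipped into a folder named `YYYYMMDD-HHMMSS` (pinnable for reproducible
runs); chromatograms are never archived. The run is fully deterministic:
identical inputs and configuration give byte-identical outputs apart from
the timestamp.
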