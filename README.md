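# fragmerge

Assembly of ordered, overlapping Sanger sequencing fragments into a single
merged sequence.

PCR amplicons run to a few thousand bases, but one direct Sanger read
covers only ~500–800 nt, so covering a gene or a small genome takes several
overlapping reads. Stitching those reads together by eye — trimming the
ragged ends of each chromatogram, sliding fragments until they overlap,
typing out the consensus — is slow and error-prone, and worse for circular
genomes (such as the ~3.2 kb hepatitis B virus genome), which come out of
assembly at an arbitrary rotation. `fragmerge` automates the whole
procedure for 2–12 fragments supplied **in merge order**:

1. **Read** each fragment from an AB1 chromatogram (base calls + Phred-like
   quality scores) or a FASTA file (already-curated sequence, used verbatim).
2. **Trim** chromatogram ends with a sliding window: a window of *w*
   consecutive bases (default 10) is slid inward from each end until every
   quality in the window is ≥ the threshold *t* (default 20). Fragments are
   flagged green / yellow (shorter than 200 nt) / red (trimmed below 50% of
   original length) / blue (FASTA, untrimmed); flags warn but never exclude.
3. **Reverse/complement** fragments sequenced on the opposite strand.
4. **Merge** the fragments left to right by successive pairwise
   Needleman–Wunsch global alignments (affine gaps, free end gaps, EDNAFULL
   scoring: match +5, mismatch −4, gap open 50, gap extend 0.5) — *n*
   fragments take exactly *n − 1* merges. Overlap columns where the two
   fragments disagree are reported as conflicts together with the base used;
   each merge's orientation is checked against the expectation that the end
   of the first fragment overlaps the start of the next.
5. **Slide** a circular assembly so a landmark motif starts at a chosen
   coordinate (e.g. the HBV EcoRI site `GAATTC` at position 1).
6. **Check** the result against reference sequences — alignment only, never
   assembly guidance — with a `|`/space match line and match/mismatch counts.

All outputs (per-fragment summary, merged FASTA, per-merge `outFile`
reports, reference alignment, README) are written to a directory and
bundled into a ZIP archive named with the run date-time, excluding the
binary chromatograms.

## Worked example

Simulate a 3221 nt circular genome with a uniquely planted `GAATTC`, cut it
into six overlapping chromatograms (low-quality ramped ends, four of them
on the opposite strand), and assemble:

```python
from fragmerge import (FragmentPlan, double_reference, simulate_genome,
                       write_fasta, write_fixture_set)

genome = simulate_genome(3221, seed=4, motif="GAATTC", motif_pos=1000)
plan = FragmentPlan(n_fragments=6, circular=True, allow_revcomp=True, seed=5)
paths, manifest = write_fixture_set(genome, plan, "fragments")
write_fasta([double_reference(genome)], "reference_x2.fasta")
```

The manifest records which fragments need `rev`/`comp`; pass those flags on
the fragment arguments:

```bash
fragmerge run \
    fragments/frag1.ab1:rev:comp fragments/frag2.ab1:rev:comp \
    fragments/frag3.ab1:rev:comp fragments/frag4.ab1 \
    fragments/frag5.ab1:rev:comp fragments/frag6.ab1 \
    --slide-motif GAATTC --reference reference_x2.fasta \
    --merged-id sampleA_genome -o out
```

which prints:

```
Merged 6 fragments (5 merges) -> 3221 nt: sampleA_genome slid(GAATTC@1)
  [green ] #1 frag1: 587 -> 537 nt (91.5%)
  [green ] #2 frag2: 623 -> 573 nt (92.0%)
  [green ] #3 frag3: 606 -> 556 nt (91.7%)
  [green ] #4 frag4: 623 -> 573 nt (92.0%)
  [green ] #5 frag5: 616 -> 566 nt (91.9%)
  [green ] #6 frag6: 617 -> 567 nt (91.9%)
  merge 1: score 180.0, overlap 36, 0 conflict(s), orientation Correct
  merge 2: score 100.0, overlap 20, 0 conflict(s), orientation Correct
  merge 3: score 180.0, overlap 36, 0 conflict(s), orientation Correct
  merge 4: score 145.0, overlap 29, 0 conflict(s), orientation Correct
  merge 5: score 150.0, overlap 30, 0 conflict(s), orientation Correct
  reference check: 3221 matches, 3221 mismatches
  archive: out/fragmerge_20260930-031052.zip
```

Each fragment kept ~92% of its bases after trimming (the 50 ramped
low-quality bases removed), every merge joined end-of-first to
start-of-next with a clean overlap, and the final 3221 nt sequence begins
with `GAATTC`. The reference check ran against a *double-length* reference
(the genome concatenated with itself) so the rotated assembly aligns
without wrap-around artefacts: the 3221 matches are the full assembly, and
the 3221 "mismatches" are the leftover copy of the doubled reference, which
has nothing to pair with (gap columns count as disagreement).

The same run is available as a library call (`fragmerge.run(RunConfig(...))`)
returning a `RunResult` with the merged record, per-merge reports, fragment
summaries and the reference-check report.

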