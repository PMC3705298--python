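"""Synthetic genomes, fragment plans and fixture generation."""

from __future__ import annotations

import pytest

from fragmerge import (
    Chromatogram,
    FragmentPlan,
    SyntheticError,
    fragment_genome,
    merge_chain,
    read_abif,
    reverse,
    complement,
    simulate_genome,
    trim,
    trimmed_qualities,
    write_fixture_set,
)


def test_seeding_is_reproducible():
    a = simulate_genome(10, seed=7)
    b = simulate_genome(10, seed=7)
    c = simulate_genome(10, seed=8)
    assert a.sequence == b.sequence
    assert a.sequence != c.sequence
    assert set(a.sequence) <= set("ACGT")


def test_motif_planted_uniquely():
    g = simulate_genome(3200, seed=1, motif="GAATTC", motif_pos=1)
    assert g.sequence.startswith("GAATTC")
    circular = g.sequence + g.sequence[:5]
    assert circular.count("GAATTC") == 1


def test_motif_at_interior_position():
    g = simulate_genome(500, seed=3, motif="GAATTC", motif_pos=101)
    assert g.sequence[100:106] == "GAATTC"


def test_motif_longer_than_genome_rejected():
    with pytest.raises(SyntheticError, match="motif"):
        simulate_genome(5, seed=1, motif="GAATTCA", motif_pos=1)


def test_fragments_tile_with_requested_overlaps():
    g = simulate_genome(1000, seed=2)
    frags = fragment_genome(g, FragmentPlan(n_fragments=3, overlap_range=(30, 30),
                                            ramp_len=0, seed=5))
    assert len(frags) == 3
    for left, right in zip(frags, frags[1:]):
        assert left.core_end - right.core_start == 30
    # cores reassemble the genome
    assert frags[0].core_start == 0 and frags[-1].core_end == 1000
    rebuilt = frags[0].record.sequence
    for f in frags[1:]:
        rebuilt = rebuilt[: f.core_start] + f.record.sequence
    assert rebuilt == g.sequence


def test_quality_profile_trims_to_exact_core():
    """Default trimming removes exactly the low-quality junk flanks."""
    g = simulate_genome(900, seed=4)
    for frag in fragment_genome(g, FragmentPlan(n_fragments=3, ramp_len=25, seed=1)):
        chrom = Chromatogram(frag.record.id, frag.record.sequence, frag.qualities)
        result = trim(chrom)
        assert result.left_trimmed == 25
        assert result.right_trimmed == 25
        assert len(result.record.sequence) == frag.core_length
        assert set(trimmed_qualities(chrom, result)) == {40}


def test_revcomp_flags_restore_the_core():
    g = simulate_genome(1200, seed=9)
    frags = fragment_genome(
        g, FragmentPlan(n_fragments=4, ramp_len=0, allow_revcomp=True, seed=9)
    )
    assert any(f.reverse for f in frags)  # the plan actually flipped some
    restored = []
    for f in frags:
        seq = f.record.sequence
        if f.reverse:
            seq = reverse(seq)
        if f.complement:
            seq = complement(seq)
        restored.append(f.record.__class__(f.record.id, seq))
    assert merge_chain(restored).final.sequence == g.sequence


def test_minimum_overlap_of_one_still_merges():
    g = simulate_genome(600, seed=11)
    frags = fragment_genome(g, FragmentPlan(n_fragments=2, overlap_range=(1, 1),
                                            ramp_len=0, seed=2))
    result = merge_chain([f.record for f in frags])
    assert result.final.sequence == g.sequence


def test_infeasible_plan_rejected():
    g = simulate_genome(60, seed=1)
    with pytest.raises(SyntheticError, match="cannot tile"):
        fragment_genome(g, FragmentPlan(n_fragments=12, overlap_range=(30, 30),
                                        ramp_len=0, seed=1))


def test_plan_validation():
    with pytest.raises(SyntheticError):
        FragmentPlan(n_fragments=1)
    with pytest.raises(SyntheticError):
        FragmentPlan(n_fragments=13)
    with pytest.raises(SyntheticError):
        FragmentPlan(n_fragments=3, overlap_range=(5, 2))


def test_substitution_injection_creates_conflicts():
    g = simulate_genome(800, seed=6)
    frags = fragment_genome(g, FragmentPlan(n_fragments=2, ramp_len=0,
                                            substitutions_per_overlap=2, seed=3))
    result = merge_chain([f.record for f in frags])
    assert len(result.merges[0].conflicts) >= 1


def test_fixture_set_round_trips_through_abif(tmp_path):
    g = simulate_genome(700, seed=8)
    plan = FragmentPlan(n_fragments=3, seed=4)
    paths, manifest = write_fixture_set(g, plan, tmp_path)
    assert len(paths) == 3
    frags = fragment_genome(g, plan)
    for path, frag in zip(paths, frags):
        chrom = read_abif(path)
        assert chrom.bases == frag.record.sequence
        assert chrom.qualities == frag.qualities
    lines = manifest.read_text().splitlines()
    assert lines[0].startswith("order\t")
    assert len(lines) == 4
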