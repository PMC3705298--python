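"""Pairwise merging: overlap detection, conflicts, orientation, degenerate concat."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings, strategies as st

from fragmerge import (
    MergeError,
    Orientation,
    SequenceRecord,
    merge_pair,
)


def rec(seq: str, rid: str = "r") -> SequenceRecord:
    return SequenceRecord(rid, seq)


def test_exact_suffix_prefix_overlap():
    # suffix "GTAA" of a == prefix of b: classic overlap merge
    report = merge_pair(rec("ACGTACGTAA", "a"), rec("GTAACGGTT", "b"))
    assert report.merged.sequence == "ACGTACGTAACGGTT"
    assert len(report.merged.sequence) == 10 + 9 - 4
    assert report.overlap_len == 4
    assert report.conflicts == []
    assert report.orientation is Orientation.CORRECT


def test_identity_merge():
    report = merge_pair(rec("ACGTACGTCC"), rec("ACGTACGTCC"))
    assert report.merged.sequence == "ACGTACGTCC"
    assert report.overlap_len == 10
    assert report.conflicts == []


def test_no_overlap_concatenates_with_one_shared_base():
    # disjoint alphabets: no overlap can score positively
    a, b = "ACACACACCA" * 3, "GTGTGTGTTG" * 2
    report = merge_pair(rec(a, "a"), rec(b, "b"))
    assert len(report.merged.sequence) == len(a) + len(b) - 1
    assert report.overlap_len == 1
    assert report.orientation is Orientation.CHECK


def test_positional_conflict_rule_prefers_read_middle():
    """A mismatch near a's 3' end vs deep inside b: b's base wins."""
    rng = random.Random(5)
    genome = "".join(rng.choice("ACGT") for _ in range(120))
    a = genome[:60]
    b = genome[40:]
    # conflict 3 bases from a's end == genome position 56; b-local index 16
    pos = 56
    mutated = "G" if a[pos] != "G" else "C"
    a = a[:pos] + mutated + a[pos + 1 :]
    report = merge_pair(rec(a, "a"), rec(b, "b"))
    assert len(report.conflicts) == 1
    conflict = report.conflicts[0]
    assert conflict.base_a == mutated
    assert conflict.base_b == genome[pos]
    assert conflict.chosen == genome[pos]  # positional rule fired
    assert "end-distance" in conflict.rule
    assert report.merged.sequence == genome


def test_quality_conflict_rule_prefers_higher_quality():
    rng = random.Random(6)
    genome = "".join(rng.choice("ACGT") for _ in range(100))
    a = genome[:60]
    b = genome[40:]
    pos = 50  # middle of the overlap
    mutated = "G" if b[pos - 40] != "G" else "C"
    b = b[: pos - 40] + mutated + b[pos - 40 + 1 :]
    qa = [20] * len(a)
    qb = [55] * len(b)  # b claims higher quality everywhere
    report = merge_pair(rec(a, "a"), rec(b, "b"), qa, qb)
    (conflict,) = report.conflicts
    assert conflict.chosen == mutated
    assert "quality" in conflict.rule
    # flip the qualities and fragment a's base must win instead
    report2 = merge_pair(rec(a, "a"), rec(b, "b"), qb[: len(a)], [3] * len(b))
    assert report2.conflicts[0].chosen == genome[pos]


def test_conflict_count_equals_mismatching_overlap_columns():
    rng = random.Random(8)
    genome = "".join(rng.choice("ACGT") for _ in range(150))
    a = genome[:90]
    b = list(genome[50:])
    n_mut = 4
    for i in (5, 12, 20, 33):  # all inside the 40-column overlap
        b[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[i]]
    report = merge_pair(rec(a), rec("".join(b)))
    assert len(report.conflicts) == n_mut
    for c in report.conflicts:
        assert c.chosen in (c.base_a, c.base_b)


def test_wrong_order_flagged_check():
    rng = random.Random(9)
    genome = "".join(rng.choice("ACGT") for _ in range(120))
    first, second = genome[:70], genome[50:]
    report = merge_pair(rec(second, "b"), rec(first, "a"))  # swapped order
    assert report.orientation is Orientation.CHECK


def test_empty_fragment_rejected():
    with pytest.raises(MergeError, match="empty fragment"):
        merge_pair(rec(""), rec("ACGT"))


def test_quality_length_validation():
    with pytest.raises(MergeError):
        merge_pair(rec("ACGT"), rec("ACGT"), [30, 30], None)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(data=st.data())
def test_merged_length_bounds_and_identity(data):
    genome = data.draw(st.text(alphabet="ACGT", min_size=30, max_size=120))
    cut = data.draw(st.integers(10, len(genome) - 10))
    overlap = data.draw(st.integers(1, min(10, cut)))
    a, b = genome[:cut], genome[cut - overlap :]
    report = merge_pair(rec(a), rec(b))
    merged = report.merged.sequence
    assert max(len(a), len(b)) <= len(merged) <= len(a) + len(b)
    # self-merge is the identity
    self_report = merge_pair(rec(genome), rec(genome))
    assert self_report.merged.sequence == genome
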