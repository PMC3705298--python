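"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: trimming is checked by
enumerating every window position, and alignment scores by enumerating
every possible global alignment and scoring its gap runs directly.
"""

from __future__ import annotations

import math


def brute_trim(qualities: list[int], window: int, threshold: int):
    """(L, R) inclusive kept span by exhaustive window enumeration, or None."""
    n = len(qualities)
    if n < window:
        return (0, n - 1) if all(q >= threshold for q in qualities) else None
    starts = [
        i for i in range(n - window + 1)
        if all(q >= threshold for q in qualities[i : i + window])
    ]
    if not starts:
        return None
    left = starts[0]
    right = max(s + window - 1 for s in starts)
    if left > right:
        return None
    return left, right


def _score_alignment(cols, a, b, sub, gap_open, gap_extend):
    """Score one alignment given as a list of ops: 'M', 'X' (gap in b), 'Y'."""
    score = 0.0
    ia = ib = 0
    i = 0
    n = len(cols)
    while i < n:
        op = cols[i]
        if op == "M":
            score += sub[a[ia]][b[ib]]
            ia += 1
            ib += 1
            i += 1
            continue
        j = i
        while j < n and cols[j] == op:
            j += 1
        run = j - i
        if op == "X":
            ia += run
        else:
            ib += run
        free = i == 0 or j == n  # end gaps are free
        if not free:
            score -= gap_open + (run - 1) * gap_extend
        i = j
    return score


def brute_align_score(a, b, sub, gap_open=50.0, gap_extend=0.5):
    """Best score over every global alignment, free end gaps, affine costs."""
    best = -math.inf
    cols: list[str] = []

    def rec(i: int, j: int) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, _score_alignment(cols, a, b, sub, gap_open, gap_extend))
            return
        if i < len(a) and j < len(b):
            cols.append("M")
            rec(i + 1, j + 1)
            cols.pop()
        if i < len(a):
            cols.append("X")
            rec(i + 1, j)
            cols.pop()
        if j < len(b):
            cols.append("Y")
            rec(i, j + 1)
            cols.pop()

    rec(0, 0)
    return best


def ednafull_dict():
    """EDNAFULL as a nested dict, loaded independently of fragmerge.align."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("NUC.4.4")
    alpha = str(mat.alphabet)
    return {x: {y: float(mat[x][y]) for y in alpha} for x in alpha}
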