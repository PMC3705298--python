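"""Global overlap alignment (Needleman–Wunsch/Gotoh, affine gaps, free end gaps).

Two ordered Sanger fragments overlap suffix-to-prefix, so the right model
is a *semi-global* alignment: both sequences are aligned end to end, gaps
inside the overlap are penalized with affine costs, and the unaligned
overhangs at either end are free.  Scoring follows the EDNAFULL nucleotide
matrix (match +5, mismatch −4, reduced penalties against IUPAC ambiguity
codes) with gap open 50 and gap extend 0.5 — the defaults of the classic
EMBOSS ``merger`` program this stage replaces.  A gap of length L costs
``gap_open + (L−1)·gap_extend``.

Ties in the dynamic program are broken deterministically: diagonal first,
then gap-in-second-sequence, then gap-in-first; among equal-scoring end
points the one with the smallest trailing overhang wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numba import njit

_NEG = np.float32(-1e30)

# state codes used throughout the DP
_M, _X, _Y = 0, 1, 2  # diagonal / gap in b (consumes a) / gap in a (consumes b)


@lru_cache(maxsize=1)
def _ednafull() -> tuple[str, np.ndarray]:
    """EDNAFULL (NUC.4.4) substitution matrix from Biopython's data files."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("NUC.4.4")
    alphabet = str(mat.alphabet)
    return alphabet, np.asarray(mat, dtype=np.float32)


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for overlap alignment.

    `matrix` maps ordered nucleotide pairs to scores over `alphabet`;
    defaults to EDNAFULL.  `end_gaps_penalized=False` gives free overhangs
    (the overlap-merge setting).
    """

    gap_open: float = 50.0
    gap_extend: float = 0.5
    end_gaps_penalized: bool = False
    alphabet: str | None = None
    matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.gap_extend < 0 or self.gap_open < self.gap_extend:
            raise ValueError("require gap_open >= gap_extend >= 0")

    def resolved(self) -> tuple[str, np.ndarray]:
        if self.matrix is None or self.alphabet is None:
            return _ednafull()
        return self.alphabet, np.asarray(self.matrix, dtype=np.float32)


def _encoder(alphabet: str) -> np.ndarray:
    lut = np.full(256, alphabet.index("N") if "N" in alphabet else 0, dtype=np.int64)
    for i, ch in enumerate(alphabet):
        lut[ord(ch)] = i
        lut[ord(ch.lower())] = i
    if "U" not in alphabet and "T" in alphabet:
        lut[ord("U")] = alphabet.index("T")
        lut[ord("u")] = alphabet.index("T")
    return lut


def _encode(seq: str, lut: np.ndarray) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return lut[raw]


@njit(cache=False)
def _gotoh_fill(a, b, sub, go, ge, free_end):  # pragma: no cover - numba
    n, m = a.shape[0], b.shape[0]
    M = np.full((n + 1, m + 1), _NEG, np.float32)
    X = np.full((n + 1, m + 1), _NEG, np.float32)
    Y = np.full((n + 1, m + 1), _NEG, np.float32)
    PM = np.zeros((n + 1, m + 1), np.int8)
    PX = np.zeros((n + 1, m + 1), np.int8)
    PY = np.zeros((n + 1, m + 1), np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = 0.0 if free_end else -(go + (i - 1) * ge)
        PX[i, 0] = _M if i == 1 else _X
    for j in range(1, m + 1):
        Y[0, j] = 0.0 if free_end else -(go + (j - 1) * ge)
        PY[0, j] = _M if j == 1 else _Y
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # diagonal
            best = M[i - 1, j - 1]
            src = _M
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                src = _X
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                src = _Y
            M[i, j] = best + sub[a[i - 1], b[j - 1]]
            PM[i, j] = src
            # gap in b (consume a[i-1])
            best = M[i - 1, j] - go
            src = _M
            if X[i - 1, j] - ge > best:
                best = X[i - 1, j] - ge
                src = _X
            if Y[i - 1, j] - go > best:
                best = Y[i - 1, j] - go
                src = _Y
            X[i, j] = best
            PX[i, j] = src
            # gap in a (consume b[j-1])
            best = M[i, j - 1] - go
            src = _M
            if X[i, j - 1] - go > best:
                best = X[i, j - 1] - go
                src = _X
            if Y[i, j - 1] - ge > best:
                best = Y[i, j - 1] - ge
                src = _Y
            Y[i, j] = best
            PY[i, j] = src
    return M, X, Y, PM, PX, PY


@njit(cache=False)
def _best_state(M, X, Y, i, j):  # pragma: no cover - numba
    s, st = M[i, j], _M
    if X[i, j] > s:
        s, st = X[i, j], _X
    if Y[i, j] > s:
        s, st = Y[i, j], _Y
    return s, st


@njit(cache=False)
def _endpoint(M, X, Y, n, m, free_end):  # pragma: no cover - numba
    if not free_end:
        s, st = _best_state(M, X, Y, n, m)
        return n, m, st, s
    bi, bj = n, m
    bs, bst = _best_state(M, X, Y, n, m)
    for j in range(m - 1, -1, -1):
        s, st = _best_state(M, X, Y, n, j)
        if s > bs:
            bs, bst, bi, bj = s, st, n, j
    for i in range(n - 1, -1, -1):
        s, st = _best_state(M, X, Y, i, m)
        if s > bs:
            bs, bst, bi, bj = s, st, i, m
    return bi, bj, bst, bs


@njit(cache=False)
def _traceback(PM, PX, PY, i, j, state):  # pragma: no cover - numba
    """Return ops array (0=diag,1=consume a,2=consume b), reversed order."""
    ops = np.empty(i + j, np.int8)
    k = 0
    while i > 0 or j > 0:
        ops[k] = state
        k += 1
        if state == _M:
            state = PM[i, j]
            i -= 1
            j -= 1
        elif state == _X:
            state = PX[i, j]
            i -= 1
        else:
            state = PY[i, j]
            j -= 1
    return ops[:k]


def align_overlap(
    a: str, b: str, params: AlignmentParams | None = None
) -> tuple[str, str, float]:
    """Optimal end-to-end alignment of two sequences.

    Returns ``(aligned_a, aligned_b, score)`` where the aligned strings are
    equal length, gap character ``-``; stripping gaps recovers the inputs.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    params = params or AlignmentParams()
    alphabet, sub = params.resolved()
    lut = _encoder(alphabet)
    ea, eb = _encode(a, lut), _encode(b, lut)
    free = not params.end_gaps_penalized
    M, X, Y, PM, PX, PY = _gotoh_fill(
        ea, eb, sub, np.float32(params.gap_open), np.float32(params.gap_extend), free
    )
    n, m = len(a), len(b)
    ei, ej, st, score = _endpoint(M, X, Y, n, m, free)
    ops = _traceback(PM, PX, PY, ei, ej, st)[::-1]

    out_a: list[str] = []
    out_b: list[str] = []
    ia = ib = 0
    for op in ops:
        if op == _M:
            out_a.append(a[ia]); ia += 1
            out_b.append(b[ib]); ib += 1
        elif op == _X:
            out_a.append(a[ia]); ia += 1
            out_b.append("-")
        else:
            out_a.append("-")
            out_b.append(b[ib]); ib += 1
    # free trailing overhangs past the chosen endpoint
    if ei < n:
        out_a.append(a[ei:])
        out_b.append("-" * (n - ei))
    if ej < m:
        out_a.append("-" * (m - ej))
        out_b.append(b[ej:])
    return "".join(out_a), "".join(out_b), float(score)
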