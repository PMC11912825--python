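"""Affine-gap Smith-Waterman local alignment (numba kernel).

Used as the within/between-sequence similarity screen for designed
sequences.  Returns both the optimal local score and the number of aligned
columns of an optimal alignment.  Tie-breaks are deterministic: among
co-optimal predecessors (and end cells) the longer alignment wins, which is
the conservative choice for a similarity screen.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .seqs import revcomp, validate_dna

#: default scoring: match, mismatch, gap open (first gap base), gap extend
DEFAULT_SCORING = (1, -3, -5, -2)

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[arr]
    if (codes < 0).any():
        raise ValueError("alignment requires plain A/C/G/T sequences")
    return codes.astype(np.int8)


@njit(cache=True)
def _sw_kernel(a, b, match, mismatch, gap_open, gap_extend, exclude_diag):  # pragma: no cover - numba
    n = a.shape[0]
    m = b.shape[0]
    NEG = -(1 << 40)
    # rows of the three affine states: M (match/mismatch), X (gap in b,
    # consumes a), Y (gap in a, consumes b); L* track aligned columns.
    Mp = np.full(m + 1, NEG, np.int64)
    Xp = np.full(m + 1, NEG, np.int64)
    Yp = np.full(m + 1, NEG, np.int64)
    LMp = np.zeros(m + 1, np.int64)
    LXp = np.zeros(m + 1, np.int64)
    LYp = np.zeros(m + 1, np.int64)
    best = 0
    best_len = 0
    for i in range(1, n + 1):
        M = np.full(m + 1, NEG, np.int64)
        X = np.full(m + 1, NEG, np.int64)
        Y = np.full(m + 1, NEG, np.int64)
        LM = np.zeros(m + 1, np.int64)
        LX = np.zeros(m + 1, np.int64)
        LY = np.zeros(m + 1, np.int64)
        for j in range(1, m + 1):
            # M: diagonal step from best of {fresh start, M, X, Y} at (i-1, j-1)
            pv = 0
            pl = 0
            if Mp[j - 1] > pv or (Mp[j - 1] == pv and LMp[j - 1] > pl):
                pv = Mp[j - 1]
                pl = LMp[j - 1]
            if Xp[j - 1] > pv or (Xp[j - 1] == pv and LXp[j - 1] > pl):
                pv = Xp[j - 1]
                pl = LXp[j - 1]
            if Yp[j - 1] > pv or (Yp[j - 1] == pv and LYp[j - 1] > pl):
                pv = Yp[j - 1]
                pl = LYp[j - 1]
            if exclude_diag and i == j:
                M[j] = NEG
                LM[j] = 0
            else:
                s = match if a[i - 1] == b[j - 1] else mismatch
                M[j] = pv + s
                LM[j] = pl + 1
            # X: gap in b (vertical), from row i-1 same column
            xv = Mp[j] + gap_open
            xl = LMp[j] + 1
            if Xp[j] + gap_extend > xv or (Xp[j] + gap_extend == xv and LXp[j] + 1 > xl):
                xv = Xp[j] + gap_extend
                xl = LXp[j] + 1
            X[j] = xv
            LX[j] = xl
            # Y: gap in a (horizontal), from same row column j-1
            yv = M[j - 1] + gap_open
            yl = LM[j - 1] + 1
            if Y[j - 1] + gap_extend > yv or (Y[j - 1] + gap_extend == yv and LY[j - 1] + 1 > yl):
                yv = Y[j - 1] + gap_extend
                yl = LY[j - 1] + 1
            Y[j] = yv
            LY[j] = yl
            # optimal local alignments end in the M state
            if M[j] > best or (M[j] == best and LM[j] > best_len):
                best = M[j]
                best_len = LM[j]
        Mp, Xp, Yp = M, X, Y
        LMp, LXp, LYp = LM, LX, LY
    if best <= 0:
        return 0, 0
    return best, best_len


def sw_local(a: str, b: str, scoring=DEFAULT_SCORING, exclude_diag: bool = False):
    """Optimal local alignment of `a` vs `b` (forward orientation only).

    Returns ``(score, aligned_columns)``.  With ``exclude_diag`` cells on the
    main diagonal are forbidden from the match state, which removes the
    trivial self-hit when ``a is b``.
    """
    match, mismatch, gap_open, gap_extend = scoring
    score, length = _sw_kernel(_encode(a), _encode(b), match, mismatch,
                               gap_open, gap_extend, exclude_diag)
    return int(score), int(length)


def cross_similarity(a: str, b: str, scoring=DEFAULT_SCORING) -> int:
    """Length (aligned columns) of the best local alignment of a vs b.

    Both orientations of `b` are considered.  For a self comparison
    (``a == b``) main-diagonal self-hits are excluded in the forward
    orientation.
    """
    a = validate_dna(a, context="sequence a")
    b = validate_dna(b, context="sequence b")
    self_cmp = a == b
    _, len_fwd = sw_local(a, b, scoring, exclude_diag=self_cmp)
    _, len_rev = sw_local(a, revcomp(b), scoring, exclude_diag=False)
    return max(len_fwd, len_rev)


def longest_shared_substring(a: str, b: str) -> int:
    """Longest exact substring shared by `a` and `b` (forward or revcomp of b).

    For a self comparison the trivial identity (shift 0, forward) is excluded.
    Companion, parameter-free version of the alignment screen.
    """
    self_cmp = a == b
    best = _lcs_shift(a, b, exclude_zero_shift=self_cmp)
    best = max(best, _lcs_shift(a, revcomp(b), exclude_zero_shift=False))
    return best


def _lcs_shift(a: str, b: str, exclude_zero_shift: bool) -> int:
    """Longest common substring by scanning every diagonal of the match grid."""
    x = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    y = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    best = 0
    for shift in range(-(len(y) - 1), len(x)):
        if exclude_zero_shift and shift == 0:
            continue
        if shift >= 0:
            xa = x[shift:shift + len(y)]
            ya = y[:len(xa)]
        else:
            ya = y[-shift:-shift + len(x)]
            xa = x[:len(ya)]
        if len(xa) <= best:
            continue
        run = _max_run(xa == ya)
        if run > best:
            best = run
    return best


def _max_run(eq: np.ndarray) -> int:
    """Longest run of True in a boolean vector."""
    if not eq.any():
        return 0
    edges = np.flatnonzero(np.diff(np.concatenate((
        np.zeros(1, np.int8), eq.astype(np.int8), np.zeros(1, np.int8)))))
    return int((edges[1::2] - edges[::2]).max())
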