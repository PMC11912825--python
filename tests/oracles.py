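"""Independent brute-force oracles used to verify the package's screens.

Deliberately written with different algorithms than the implementations they
check (diagonal scans instead of k-mer binary search, regex instead of set
membership, itertools grouping instead of a manual run loop).
"""

from __future__ import annotations

import itertools
import re

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def oracle_max_homopolymer(seq: str) -> int:
    return max(len(list(g)) for _, g in itertools.groupby(seq))


def _longest_match_on_diagonals(a: str, b: str, exclude_zero_shift=False) -> int:
    """Longest common substring of a and b by scanning every diagonal."""
    x = np.frombuffer(a.encode(), np.uint8)
    y = np.frombuffer(b.encode(), np.uint8)
    best = 0
    for shift in range(-(len(y) - 1), len(x)):
        if exclude_zero_shift and shift == 0:
            continue
        if shift >= 0:
            xa, ya = x[shift:shift + len(y)], y[:max(0, min(len(y), len(x) - shift))]
            xa = xa[:len(ya)]
        else:
            ya = y[-shift:-shift + len(x)]
            xa = x[:len(ya)]
        run = 0
        for e in (xa == ya):
            run = run + 1 if e else 0
            best = max(best, run)
    return best


def oracle_repeats(seq: str) -> tuple[int, int]:
    """(longest direct repeat, longest inverted repeat), 0 if below 2."""
    direct = _longest_match_on_diagonals(seq, seq, exclude_zero_shift=True)
    inverted = _longest_match_on_diagonals(seq, rc(seq))
    return (direct if direct >= 2 else 0, inverted if inverted >= 2 else 0)


def oracle_gc_windows(seq: str, window: int, step: int, reference_gc: float) -> float:
    starts = list(range(0, len(seq) - window + 1, step))
    if starts[-1] != len(seq) - window:
        starts.append(len(seq) - window)
    worst = 0.0
    for s in starts:
        win = seq[s:s + window]
        gc = sum(c in "GC" for c in win) / window
        worst = max(worst, abs(gc - reference_gc) * 100.0)
    return worst


_IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
          "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
          "H": "ACT", "V": "ACG", "N": "ACGT"}
_IUPAC_RC = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def oracle_prohibited_hits(seq: str, primers, k: int) -> int:
    """Regex-based count of positions matching any primer-derived k-mer."""
    kmers = set()
    for p in primers:
        for strand in (p, p.translate(_IUPAC_RC)[::-1]):
            for i in range(len(strand) - k + 1):
                for combo in itertools.product(*[_IUPAC[c] for c in strand[i:i + k]]):
                    kmers.add("".join(combo))
    if not kmers:
        return 0
    pat = re.compile("(?=(" + "|".join(sorted(kmers)) + "))")
    return sum(1 for _ in pat.finditer(seq))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
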