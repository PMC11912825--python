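"""Small DNA-string helpers shared across modules."""

from __future__ import annotations

import itertools

BASES = "ACGT"

#: IUPAC nucleotide codes mapped to the set of plain bases they stand for.
IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                      "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement; degenerate IUPAC codes are complemented too."""
    return seq.translate(_COMP)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def validate_dna(seq: str, *, allow_iupac: bool = False, context: str = "sequence") -> str:
    """Upper-case and validate a DNA string; raises ValueError on bad characters."""
    s = seq.upper()
    allowed = set(IUPAC_SETS) if allow_iupac else set(BASES)
    bad = set(s) - allowed
    if bad:
        raise ValueError(f"invalid character(s) {sorted(bad)} in {context}")
    if not s:
        raise ValueError(f"empty {context}")
    return s


def expand_iupac(seq: str) -> list[str]:
    """All plain A/C/G/T sequences matching a degenerate IUPAC string."""
    s = validate_dna(seq, allow_iupac=True, context="IUPAC string")
    pools = [IUPAC_SETS[c] for c in s]
    return ["".join(p) for p in itertools.product(*pools)]


def iupac_match(base: str, code: str) -> bool:
    """True if plain base `base` is covered by IUPAC code `code`."""
    return base in IUPAC_SETS.get(code, "")
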