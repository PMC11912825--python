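"""Default universal rRNA-gene primer sets.

One set per locus commonly used for eukaryotic/fungal community profiling
(SSU-V9, ITS1, ITS2, LSU-D1D2) plus the bacterial 16S SSU-V4 set.  These are
the field-standard published primers for each locus (1391f/EukBr,
ITS1-F/ITS2, ITS3/ITS4, LR0R/LR3, 515F/806R); any other set can be supplied
through the primer TSV interface.
"""

from __future__ import annotations

from .scaffold import PrimerSet

DEFAULT_PRIMER_SETS: tuple[PrimerSet, ...] = (
    PrimerSet("SSU-V9", "GTACACACCGCCCGTC", "TGATCCTTCTGCAGGTTCACCTAC"),
    PrimerSet("ITS1", "CTTGGTCATTTAGAGGAAGTAA", "GCTGCGTTCTTCATCGATGC"),
    PrimerSet("ITS2", "GCATCGATGAAGAACGCAGC", "TCCTCCGCTTATTGATATGC"),
    PrimerSet("LSU-D1D2", "ACCCGCTGAACTTAAGC", "GGTCCGTGTTTCAAGACGG"),
    PrimerSet("SSU-V4", "GTGYCAGCMGCCGCGGTAA", "GGACTACNVGGGTWTCTAAT"),
)


def get_primer_set(name: str) -> PrimerSet:
    for ps in DEFAULT_PRIMER_SETS:
        if ps.name == name:
            return ps
    raise KeyError(f"unknown primer set {name!r}")


def all_primer_sequences() -> tuple[str, ...]:
    """Every forward and reverse primer sequence, for prohibited-k-mer screens."""
    out = []
    for ps in DEFAULT_PRIMER_SETS:
        out.extend([ps.forward, ps.reverse])
    return tuple(out)
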