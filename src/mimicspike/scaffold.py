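"""Assembly of full synthetic operon constructs.

A construct keeps the conserved primer-binding regions of a natural rRNA
operon verbatim and replaces the intervening variable regions with designed
artificial sequences, so that universal primers amplify it while the
amplified interior is unique.  The module also provides IUPAC-aware primer
site location and a small in-silico PCR to predict amplicons per primer set.
"""

from __future__ import annotations

from dataclasses import dataclass

from .design import ArtificialSequence
from .seqs import IUPAC_SETS, iupac_match, revcomp, validate_dna


class ScaffoldError(ValueError):
    """Ambiguous or impossible construct plan."""


@dataclass(frozen=True)
class PrimerSet:
    name: str
    forward: str
    reverse: str

    def __post_init__(self):
        object.__setattr__(self, "forward",
                           validate_dna(self.forward, allow_iupac=True,
                                        context=f"forward primer {self.name}"))
        object.__setattr__(self, "reverse",
                           validate_dna(self.reverse, allow_iupac=True,
                                        context=f"reverse primer {self.name}"))


@dataclass(frozen=True)
class ReferenceOperon:
    id: str
    sequence: str
    source: str = ""

    def __post_init__(self):
        s = self.sequence.upper()
        if set(s) - set("ACGTN") or not s:
            raise ValueError(f"reference {self.id}: alphabet must be A/C/G/T/N")
        object.__setattr__(self, "sequence", s)


@dataclass(frozen=True)
class Segment:
    """One tile of a construct; coords are 0-based half-open on the construct."""
    label: str  # "conserved" | "artificial"
    seq: str
    origin: str
    start: int
    end: int


@dataclass(frozen=True)
class MimicConstruct:
    id: str
    segments: tuple[Segment, ...]

    def __post_init__(self):
        pos = 0
        for seg in self.segments:
            if seg.start != pos or seg.end - seg.start != len(seg.seq):
                raise ValueError(f"construct {self.id}: segments do not tile")
            if seg.label not in ("conserved", "artificial"):
                raise ValueError(f"construct {self.id}: bad segment label {seg.label}")
            pos = seg.end
        if pos == 0:
            raise ValueError(f"construct {self.id}: empty")

    @property
    def full_sequence(self) -> str:
        return "".join(seg.seq for seg in self.segments)

    def __len__(self) -> int:
        return self.segments[-1].end


@dataclass(frozen=True)
class PredictedAmplicon:
    primer_set: str
    start: int
    end: int  # half-open on the construct; primers included
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PrimerSite:
    position: int  # 0-based start of the match on the forward strand
    strand: str    # "+" if the primer matches the forward strand
    mismatches: int


def locate_primer_sites(ref, primer: str, max_mismatch: int = 0) -> list[PrimerSite]:
    """All matches of a (possibly degenerate) primer on either strand.

    A "-" strand site means the reverse complement of the primer matches the
    forward strand there, i.e. the primer anneals to the forward strand as a
    reverse primer.  Reference N bases count as mismatches unless the primer
    code is N.
    """
    seq = ref.sequence if hasattr(ref, "sequence") else validate_dna(
        ref, allow_iupac=True)
    primer = validate_dna(primer, allow_iupac=True, context="primer")
    sites = []
    for strand, pat in (("+", primer), ("-", revcomp(primer))):
        m = len(pat)
        for i in range(len(seq) - m + 1):
            mm = 0
            for s_base, p_code in zip(seq[i:i + m], pat):
                if not (iupac_match(s_base, p_code)
                        or (s_base == "N" and p_code == "N")):
                    mm += 1
                    if mm > max_mismatch:
                        break
            else:
                sites.append(PrimerSite(i, strand, mm))
    sites.sort(key=lambda s: (s.position, s.strand))
    return sites


def _unique_site(ref: ReferenceOperon, primer: str, max_mismatch: int) -> PrimerSite:
    sites = locate_primer_sites(ref, primer, max_mismatch)
    if len(sites) != 1:
        raise ScaffoldError(
            f"primer {primer!r} has {len(sites)} sites on {ref.id}; "
            "exactly one is required for anchoring")
    return sites[0]


@dataclass(frozen=True)
class PlanStep:
    """One element of a substitution plan.

    ``kind`` is "anchor" (a primer whose unique site defines a conserved
    block), "artificial" (insert the named designed sequence in place of the
    natural region between the flanking anchors) or "natural" (keep the
    natural reference sequence between the flanking anchors).
    """
    kind: str
    value: str  # primer sequence for anchors, sequence id otherwise

    def __post_init__(self):
        if self.kind not in ("anchor", "artificial", "natural"):
            raise ValueError(f"unknown plan step kind {self.kind!r}")


def build_mimic(ref: ReferenceOperon, plan, artificial, construct_id: str,
                flank: int = 20, max_mismatch: int = 0) -> MimicConstruct:
    """Substitute variable regions of a reference operon between primer anchors.

    ``plan`` is an ordered, alternating list of PlanStep anchors and
    artificial/natural fillers, starting and ending with an anchor.  Each
    anchor's conserved block is its primer footprint extended ``flank`` bases
    on both sides (clipped to the reference); the block boundaries facing a
    filler mark where substitution starts.  ``artificial`` maps sequence id →
    ArtificialSequence or plain string.
    """
    plan = list(plan)
    if len(plan) < 1 or plan[0].kind != "anchor" or plan[-1].kind != "anchor":
        raise ScaffoldError("plan must start and end with an anchor")
    for a, b in zip(plan, plan[1:]):
        if (a.kind == "anchor") == (b.kind == "anchor"):
            raise ScaffoldError("plan must alternate anchors and fillers")

    art_seqs: dict[str, str] = {}
    for key, val in dict(artificial).items():
        art_seqs[key] = val.sequence if isinstance(val, ArtificialSequence) else \
            validate_dna(val, context=f"artificial sequence {key}")

    # conserved block (ref coords) per anchor
    blocks = []
    for step in plan:
        if step.kind != "anchor":
            continue
        site = _unique_site(ref, step.value, max_mismatch)
        length = len(step.value)
        a = max(0, site.position - flank)
        b = min(len(ref.sequence), site.position + length + flank)
        blocks.append((a, b))
    for (a1, b1), (a2, b2) in zip(blocks, blocks[1:]):
        if a2 < b1:
            raise ScaffoldError("anchor blocks overlap or are out of order; "
                                "reduce flank or reorder the plan")

    # walk anchor/filler pairs, merging "natural" gaps into conserved spans
    fillers = [s for s in plan if s.kind != "anchor"]
    pieces: list[tuple[str, str, str]] = []  # (label, seq, origin)
    span_start, span_end = blocks[0]  # current conserved reference span

    def flush_span():
        pieces.append(("conserved", ref.sequence[span_start:span_end],
                       f"{ref.id}:{span_start + 1}-{span_end}"))

    for filler, (nxt_a, nxt_b) in zip(fillers, blocks[1:]):
        if filler.kind == "artificial":
            if filler.value not in art_seqs:
                raise ScaffoldError(f"no artificial sequence named {filler.value!r}")
            flush_span()
            pieces.append(("artificial", art_seqs[filler.value], filler.value))
            span_start, span_end = nxt_a, nxt_b
        else:  # natural: keep the reference through the next anchor block
            span_end = nxt_b
    flush_span()

    segments: list[Segment] = []
    pos = 0
    for label, seq, origin in pieces:
        if not seq:
            continue
        segments.append(Segment(label, seq, origin, pos, pos + len(seq)))
        pos += len(seq)
    return MimicConstruct(construct_id, tuple(segments))


def concat_constructs(construct_id: str, *constructs: MimicConstruct,
                      spacer: str = "") -> MimicConstruct:
    """Join constructs end to end (e.g. append a cross-domain 16S cassette)."""
    segments: list[Segment] = []
    pos = 0
    for c in constructs:
        if spacer and segments:
            segments.append(Segment("artificial", spacer, "spacer", pos,
                                    pos + len(spacer)))
            pos += len(spacer)
        for seg in c.segments:
            segments.append(Segment(seg.label, seg.seq,
                                    seg.origin, pos, pos + len(seg.seq)))
            pos += len(seg.seq)
    return MimicConstruct(construct_id, tuple(segments))


def in_silico_pcr(construct: MimicConstruct, primers: PrimerSet,
                  max_mismatch: int = 0, max_length: int = 3000) -> list[PredictedAmplicon]:
    """Predict amplicons: productive forward/reverse site pairs within range.

    An amplicon runs from the 5' end of a forward-primer site (+ strand) to
    the 3' end of a reverse-primer site (- strand) downstream of it, primers
    included.
    """
    seq = construct.full_sequence
    fwd = [s for s in locate_primer_sites(seq, primers.forward, max_mismatch)
           if s.strand == "+"]
    rev = [s for s in locate_primer_sites(seq, primers.reverse, max_mismatch)
           if s.strand == "-"]
    out = []
    for f in fwd:
        for r in rev:
            end = r.position + len(primers.reverse)
            if end - f.position <= max_length and \
                    end - f.position > len(primers.forward) + len(primers.reverse):
                out.append(PredictedAmplicon(primers.name, f.position, end,
                                             seq[f.position:end]))
    out.sort(key=lambda a: (a.start, a.end))
    return out


def amplicon_interior(amplicon: PredictedAmplicon, primers: PrimerSet) -> str:
    """Amplicon sequence with the primer footprints stripped."""
    return amplicon.sequence[len(primers.forward):len(amplicon.sequence) - len(primers.reverse)]
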