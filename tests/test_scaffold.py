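"""Construct assembly, primer location and in-silico PCR."""

import pytest

from mimicspike.design import DesignConfig, assemble_sequence
from mimicspike.scaffold import (PlanStep, PrimerSet, ReferenceOperon,
                                 ScaffoldError, build_mimic, concat_constructs,
                                 in_silico_pcr, locate_primer_sites)
from oracles import random_dna, rc

P_1391F = "GTACACACCGCCCGTC"   # eukaryotic SSU 1391f
P_LR3R = "GGTCCGTGTTTCAAGACGG"  # fungal LSU LR3 reverse primer


@pytest.fixture(scope="module")
def toy_ref(rng=None):
    import numpy as np
    rng = np.random.default_rng(99)
    seq = random_dna(rng, 2000)
    # plant a forward site at 100 and a reverse-primer binding site at 1500
    seq = seq[:100] + P_1391F + seq[100 + len(P_1391F):]
    seq = seq[:1500] + rc(P_LR3R) + seq[1500 + len(P_LR3R):]
    return ReferenceOperon("toy", seq, source="synthetic toy reference")


def test_locate_forward_site(toy_ref):
    sites = locate_primer_sites(toy_ref, P_1391F)
    fwd = [s for s in sites if s.strand == "+"]
    assert any(s.position == 100 and s.mismatches == 0 for s in fwd)


def test_locate_reverse_site(toy_ref):
    sites = locate_primer_sites(toy_ref, P_LR3R)
    rev = [s for s in sites if s.strand == "-"]
    assert any(s.position == 1500 and s.mismatches == 0 for s in rev)


def test_locate_absent_primer_returns_empty(toy_ref):
    assert locate_primer_sites(toy_ref, "TTTTTTTTTTGGGGGGGGGG") == []


def test_degenerate_primer_matching():
    ref = ReferenceOperon("r", "AAAA" + "GTGACAGCAGCCGCGGTAA" + "AAAA")
    sites = locate_primer_sites(ref, "GTGYCAGCMGCCGCGGTAA", max_mismatch=1)
    assert any(s.position == 4 for s in sites)


@pytest.fixture(scope="module")
def artificial_insert():
    return assemble_sequence(DesignConfig(target_gc=0.5, target_length=300,
                                          rng_seed=21), seq_id="ins01")


@pytest.fixture(scope="module")
def toy_construct(toy_ref, artificial_insert):
    plan = [PlanStep("anchor", P_1391F),
            PlanStep("artificial", "ins01"),
            PlanStep("anchor", P_LR3R)]
    return build_mimic(toy_ref, plan, {"ins01": artificial_insert}, "mimicT",
                       flank=20)


def test_toy_construct_layout(toy_construct, toy_ref, artificial_insert):
    labels = [s.label for s in toy_construct.segments]
    assert labels == ["conserved", "artificial", "conserved"]
    # conserved blocks are verbatim reference substrings
    for seg in toy_construct.segments:
        if seg.label == "conserved":
            assert seg.seq in toy_ref.sequence
    # conserved block = primer footprint + 20 bp flank on both sides
    assert toy_construct.segments[0].seq == toy_ref.sequence[80:100 + 16 + 20]
    assert toy_construct.segments[1].seq == artificial_insert.sequence


def test_segments_tile_and_roundtrip(toy_construct):
    full = toy_construct.full_sequence
    for seg in toy_construct.segments:
        assert full[seg.start:seg.end] == seg.seq
    assert len(full) == len(toy_construct)


def test_ambiguous_anchor_is_an_error(artificial_insert):
    import numpy as np
    rng = np.random.default_rng(1)
    seq = P_1391F.join([random_dna(rng, 300)] * 3)  # two primer sites
    ref = ReferenceOperon("dup", seq)
    plan = [PlanStep("anchor", P_1391F), PlanStep("artificial", "ins01"),
            PlanStep("anchor", P_LR3R)]
    with pytest.raises(ScaffoldError):
        build_mimic(ref, plan, {"ins01": artificial_insert}, "bad")


def test_in_silico_pcr_toy_amplicon(toy_construct):
    ps = PrimerSet("toySet", P_1391F, P_LR3R)
    amps = in_silico_pcr(toy_construct, ps)
    assert len(amps) == 1
    amp = amps[0]
    # forward footprint starts 20 bp into the construct (the 5' flank)
    assert amp.start == 20
    assert amp.sequence.startswith(P_1391F)
    assert amp.sequence.endswith(rc(P_LR3R))
    assert amp.length == amp.end - amp.start == len(amp.sequence)


def test_nonproductive_orientation_yields_nothing(toy_construct):
    swapped = PrimerSet("swap", P_LR3R, P_1391F)
    assert in_silico_pcr(toy_construct, swapped) == []


def test_cross_domain_cassette(toy_construct):
    """A bacterial 16S V4 cassette makes only the carrying construct amplifiable."""
    import numpy as np
    rng = np.random.default_rng(55)
    v4f, v4r = "GTGCCAGCAGCCGCGGTAA", "GGACTACACGGGTATCTAAT"
    cassette_seq = v4f + random_dna(rng, 250) + rc(v4r)
    ref = ReferenceOperon("ecoli_v4", random_dna(rng, 100) + cassette_seq
                          + random_dna(rng, 100))
    plan = [PlanStep("anchor", v4f), PlanStep("natural", "keep"),
            PlanStep("anchor", v4r)]
    cassette = build_mimic(ref, plan, {}, "cassette", flank=10)
    cross = concat_constructs("mimicX", toy_construct, cassette)

    fungal = PrimerSet("fungal", P_1391F, P_LR3R)
    v4 = PrimerSet("SSU-V4", v4f, v4r)
    assert in_silico_pcr(cross, fungal)          # fungal set amplifies both
    assert in_silico_pcr(toy_construct, fungal)
    assert in_silico_pcr(cross, v4)              # V4 only on the cross-domain one
    assert in_silico_pcr(toy_construct, v4) == []


def test_natural_filler_keeps_reference_span():
    import numpy as np
    rng = np.random.default_rng(8)
    a, b = "GATTACAGATTACAGAT", "CCGGTTAACCGGTTAAC"
    mid = random_dna(rng, 100)
    ref = ReferenceOperon("r", random_dna(rng, 50) + a + mid + rc(b)
                          + random_dna(rng, 50))
    plan = [PlanStep("anchor", a), PlanStep("natural", "keep"),
            PlanStep("anchor", b)]
    c = build_mimic(ref, plan, {}, "nat", flank=5)
    assert [s.label for s in c.segments] == ["conserved"]
    assert a + mid + rc(b) in c.full_sequence
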