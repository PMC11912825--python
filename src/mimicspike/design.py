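"""Constrained random design of artificial variable-region sequences.

Artificial sequences for synthetic rRNA-operon spike-in standards are built
by progressive assembly of randomly generated 20-mers.  Every intermediate
is screened so that the final sequence has a balanced base composition,
no homopolymers longer than 3 bp, no direct or inverted repeats longer than
8 bp, sliding-window GC content within 2.5 percentage points of the overall
GC content, no 8-mers shared with the intended PCR primers, and no local
alignments longer than 16 bp within the sequence or against other panel
members.  These constraints make the sequences uniformly amplifiable and
unambiguously identifiable in any amplicon dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._align import cross_similarity, longest_shared_substring
from .seqs import BASES, expand_iupac, gc_fraction, revcomp, validate_dna


class DesignError(RuntimeError):
    """Raised when the designer cannot satisfy its constraints."""


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the sequence designer.

    ``target_gc`` is a fraction in (0, 1); the published panels use 0.40,
    0.50 and 0.60.  All repeat/alignment thresholds are maxima that a passing
    sequence may reach but not exceed.
    """

    target_gc: float = 0.5
    target_length: int = 400
    seed_kmer_length: int = 20
    max_homopolymer: int = 3
    max_repeat: int = 8
    gc_window_tolerance: float = 2.5  # percentage points
    gc_window_size: int = 100
    gc_window_step: int = 10
    max_cross_alignment: int = 16
    prohibited_kmer_length: int = 8
    prohibited_sources: tuple[str, ...] = ()
    composition_balance_tolerance: float = 0.05
    rng_seed: int = 0
    max_attempts: int = 200_000
    # assembly strategy knobs: resamples per extension step, backtrack depth
    resamples_per_step: int = 200
    backtrack_steps: int = 5

    def __post_init__(self):
        if not 0.0 < self.target_gc < 1.0:
            raise ValueError("target_gc must be in (0, 1)")
        if self.target_length < self.seed_kmer_length:
            raise ValueError("target_length must be >= seed_kmer_length")
        for name in ("seed_kmer_length", "max_homopolymer", "max_repeat",
                     "gc_window_tolerance", "gc_window_size", "gc_window_step",
                     "max_cross_alignment", "prohibited_kmer_length",
                     "composition_balance_tolerance", "max_attempts",
                     "resamples_per_step", "backtrack_steps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        object.__setattr__(self, "prohibited_sources", tuple(
            validate_dna(p, allow_iupac=True, context="prohibited primer")
            for p in self.prohibited_sources))


@dataclass(frozen=True)
class ScreenReport:
    """Metrics of one sequence against the designer's screening thresholds."""

    max_homopolymer_run: int
    max_direct_repeat: int
    max_inverted_repeat: int
    max_gc_window_deviation: float  # percentage points
    prohibited_kmer_hits: int
    composition_imbalance: float
    passed: bool


@dataclass(frozen=True)
class ArtificialSequence:
    id: str
    sequence: str
    gc: float
    screen: ScreenReport


# ---------------------------------------------------------------------------
# elementary screens


def scan_homopolymers(seq: str) -> int:
    """Length of the longest mononucleotide run."""
    seq = validate_dna(seq)
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        if run > best:
            best = run
    return best


def _has_direct_repeat(seq: str, length: int) -> bool:
    seen = set()
    for i in range(len(seq) - length + 1):
        k = seq[i:i + length]
        if k in seen:
            return True
        seen.add(k)
    return False


def _has_inverted_repeat(seq: str, length: int) -> bool:
    kmers = {seq[i:i + length] for i in range(len(seq) - length + 1)}
    return any(revcomp(k) in kmers for k in kmers)


def _max_true_length(predicate, lo: int, hi: int) -> int:
    """Largest L in [lo, hi] with predicate(L) true; lo-1 if none.

    Valid because both repeat predicates are downward monotone in L.
    """
    if hi < lo or not predicate(lo):
        return lo - 1
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if predicate(mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


def scan_repeats(seq: str, min_len: int = 2) -> tuple[int, int]:
    """(longest direct repeat, longest inverted repeat) within `seq`.

    A direct repeat is a substring occurring at two or more distinct start
    positions (overlap allowed).  An inverted repeat is a substring whose
    reverse complement also occurs in the sequence; self-palindromes count
    and occurrences may overlap — a conservative hairpin proxy.  Lengths
    below ``min_len`` are reported as 0.
    """
    seq = validate_dna(seq)
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    n = len(seq)
    direct = _max_true_length(lambda L: _has_direct_repeat(seq, L), min_len, n - 1)
    inverted = _max_true_length(lambda L: _has_inverted_repeat(seq, L), min_len, n)
    return (max(direct, 0) if direct >= min_len else 0,
            max(inverted, 0) if inverted >= min_len else 0)


def scan_gc_windows(seq: str, window: int, step: int, reference_gc: float) -> float:
    """Max |window GC − reference GC| in percentage points over sliding windows.

    Windows start every ``step`` bases; a final window flush with the 3' end
    is always included so the whole sequence is covered.
    """
    seq = validate_dna(seq)
    n = len(seq)
    if window > n:
        raise ValueError("window longer than sequence")
    if step < 1:
        raise ValueError("step must be >= 1")
    is_gc = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_gc = ((is_gc == ord("G")) | (is_gc == ord("C"))).astype(np.int64)
    csum = np.concatenate(([0], np.cumsum(is_gc)))
    starts = list(range(0, n - window + 1, step))
    if starts[-1] != n - window:
        starts.append(n - window)
    starts = np.asarray(starts)
    win_gc = (csum[starts + window] - csum[starts]) / window
    return float(np.abs(win_gc - reference_gc).max() * 100.0)


def prohibited_kmer_set(primers, k: int) -> frozenset[str]:
    """All plain k-mers derivable from the primers or their reverse complements."""
    kmers: set[str] = set()
    for primer in primers:
        p = validate_dna(primer, allow_iupac=True, context="primer")
        if len(p) < k:
            raise ValueError(f"primer {primer!r} shorter than k={k}")
        for strand in (p, revcomp(p)):
            for i in range(len(strand) - k + 1):
                kmers.update(expand_iupac(strand[i:i + k]))
    return frozenset(kmers)


def scan_prohibited_kmers(seq: str, primers, k: int,
                          kmer_set: frozenset[str] | None = None) -> int:
    """Number of forward-strand positions in `seq` matching a primer k-mer."""
    seq = validate_dna(seq)
    if kmer_set is None:
        kmer_set = prohibited_kmer_set(primers, k)
    return sum(seq[i:i + k] in kmer_set for i in range(len(seq) - k + 1))


def composition_imbalance(seq: str) -> float:
    """max(|freq A − freq T|, |freq G − freq C|)."""
    seq = validate_dna(seq)
    n = len(seq)
    f = {b: seq.count(b) / n for b in BASES}
    return max(abs(f["A"] - f["T"]), abs(f["G"] - f["C"]))


# ---------------------------------------------------------------------------
# full screen and assembly


def screen_sequence(seq: str, cfg: DesignConfig,
                    kmer_set: frozenset[str] | None = None) -> ScreenReport:
    """Run every screen against a sequence's own overall GC content."""
    seq = validate_dna(seq)
    if kmer_set is None:
        kmer_set = prohibited_kmer_set(cfg.prohibited_sources,
                                       cfg.prohibited_kmer_length)
    homopolymer = scan_homopolymers(seq)
    direct, inverted = scan_repeats(seq)
    if len(seq) >= cfg.gc_window_size:
        gc_dev = scan_gc_windows(seq, cfg.gc_window_size, cfg.gc_window_step,
                                 gc_fraction(seq))
    else:
        # sequence shorter than a window: hold whole-sequence GC to target
        gc_dev = abs(gc_fraction(seq) - cfg.target_gc) * 100.0
    hits = scan_prohibited_kmers(seq, (), cfg.prohibited_kmer_length,
                                 kmer_set=kmer_set)
    imbalance = composition_imbalance(seq)
    passed = (homopolymer <= cfg.max_homopolymer
              and direct <= cfg.max_repeat
              and inverted <= cfg.max_repeat
              and gc_dev <= cfg.gc_window_tolerance
              and hits == 0
              and imbalance <= cfg.composition_balance_tolerance)
    return ScreenReport(homopolymer, direct, inverted, gc_dev, hits,
                        imbalance, passed)


def _sample_kmer(rng: np.random.Generator, cfg: DesignConfig) -> str:
    """One k-mer with exact GC count, |G−C| ≤ 1, |A−T| ≤ 1 and short runs."""
    k = cfg.seed_kmer_length
    gc = round(cfg.target_gc * k)
    at = k - gc
    for _ in range(200):
        g = gc // 2 + (int(rng.integers(2)) if gc % 2 else 0)
        a = at // 2 + (int(rng.integers(2)) if at % 2 else 0)
        letters = np.array(list("G" * g + "C" * (gc - g) + "A" * a + "T" * (at - a)))
        rng.shuffle(letters)
        kmer = "".join(letters)
        if scan_homopolymers(kmer) <= cfg.max_homopolymer:
            return kmer
    raise DesignError("could not sample a seed k-mer meeting the homopolymer limit")


def generate_seed_kmers(cfg: DesignConfig, n: int) -> list[str]:
    """Random seed k-mers with the target GC count and bounded homopolymers."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(cfg.rng_seed)
    out = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > cfg.max_attempts:
            raise DesignError("constraints unsatisfiable: seed k-mer sampling "
                              f"exhausted max_attempts={cfg.max_attempts}")
        try:
            out.append(_sample_kmer(rng, cfg))
        except DesignError:
            continue
    return out


def assemble_sequence(cfg: DesignConfig, _rng: np.random.Generator | None = None,
                      seq_id: str = "artificial") -> ArtificialSequence:
    """Progressively assemble seed k-mers into a screened full-length sequence.

    Greedy append-with-rejection: at each step up to ``resamples_per_step``
    candidate k-mers are tried against the full screen on the extended
    prefix; if none passes, up to ``backtrack_steps`` previously accepted
    k-mers are discarded.  The finished sequence must additionally show no
    local self-alignment (off-diagonal, either orientation) longer than
    ``max_cross_alignment``.
    """
    rng = _rng if _rng is not None else np.random.default_rng(cfg.rng_seed)
    kmer_set = prohibited_kmer_set(cfg.prohibited_sources,
                                   cfg.prohibited_kmer_length)
    attempts = 0
    worst: dict[str, int] = {}

    def bump(reason: str):
        worst[reason] = worst.get(reason, 0) + 1

    while True:
        chunks: list[str] = []
        backtracks_left = cfg.backtrack_steps
        while True:
            current = "".join(chunks)
            if len(current) >= cfg.target_length:
                seq = current[:cfg.target_length]
                report = screen_sequence(seq, cfg, kmer_set=kmer_set)
                self_aln = cross_similarity(seq, seq)
                if report.passed and self_aln <= cfg.max_cross_alignment:
                    return ArtificialSequence(seq_id, seq, gc_fraction(seq), report)
                bump("final_screen" if not report.passed else "self_alignment")
                attempts += 1
                break  # restart from scratch
            accepted = False
            for _ in range(cfg.resamples_per_step):
                attempts += 1
                if attempts > cfg.max_attempts:
                    top = max(worst, key=worst.get) if worst else "extension"
                    raise DesignError(
                        "design failed: max_attempts exhausted; most-violated "
                        f"constraint: {top}")
                cand = (current + _sample_kmer(rng, cfg))[:cfg.target_length]
                report = screen_sequence(cand, cfg, kmer_set=kmer_set)
                if report.passed:
                    chunks.append(cand[len(current):])
                    accepted = True
                    break
                bump(_first_violation(report, cfg))
            if accepted:
                continue
            if chunks and backtracks_left > 0:
                chunks.pop()
                backtracks_left -= 1
            else:
                break  # restart from scratch
        if attempts > cfg.max_attempts:
            top = max(worst, key=worst.get) if worst else "extension"
            raise DesignError("design failed: max_attempts exhausted; "
                              f"most-violated constraint: {top}")


def _first_violation(report: ScreenReport, cfg: DesignConfig) -> str:
    if report.max_homopolymer_run > cfg.max_homopolymer:
        return "homopolymer"
    if report.max_direct_repeat > cfg.max_repeat:
        return "direct_repeat"
    if report.max_inverted_repeat > cfg.max_repeat:
        return "inverted_repeat"
    if report.max_gc_window_deviation > cfg.gc_window_tolerance:
        return "gc_window"
    if report.prohibited_kmer_hits > 0:
        return "prohibited_kmer"
    if report.composition_imbalance > cfg.composition_balance_tolerance:
        return "composition_balance"
    return "unknown"


def design_panel(cfg_list, max_panel_retries: int = 20) -> list[ArtificialSequence]:
    """Design a mutually dissimilar panel, one sequence per config.

    After individual assembly, every candidate is screened against the
    already-accepted panel members: both the optimal local alignment and the
    longest shared exact substring (either orientation) must be at most
    ``max_cross_alignment`` columns/bases.  Failing candidates are
    regenerated from a fresh deterministic stream.
    """
    cfg_list = list(cfg_list)
    if not cfg_list:
        raise ValueError("need at least one DesignConfig")
    panel: list[ArtificialSequence] = []
    for idx, cfg in enumerate(cfg_list):
        seq_id = f"art{idx + 1:02d}_gc{round(cfg.target_gc * 100)}_L{cfg.target_length}"
        for retry in range(max_panel_retries):
            rng = np.random.default_rng(
                np.random.SeedSequence(cfg.rng_seed, spawn_key=(retry,)))
            art = assemble_sequence(cfg, _rng=rng, seq_id=seq_id)
            ok = all(
                cross_similarity(art.sequence, other.sequence) <= cfg.max_cross_alignment
                and longest_shared_substring(art.sequence, other.sequence) <= cfg.max_cross_alignment
                for other in panel)
            if ok:
                panel.append(art)
                break
        else:
            raise DesignError(
                f"design failed: could not place panel member {seq_id} "
                f"after {max_panel_retries} regenerations (between-sequence similarity)")
    return panel


def default_panel_configs(seed: int, prohibited_sources=None,
                          gc_targets=(0.40, 0.50, 0.60),
                          lengths=(300, 450, 600)) -> list[DesignConfig]:
    """Standard 9-member panel grid: three GC targets crossed with three lengths.

    Each member gets an independent child seed derived from ``seed`` so the
    panel is reproducible as a whole.
    """
    if prohibited_sources is None:
        from .primers import all_primer_sequences
        prohibited_sources = all_primer_sequences()
    children = np.random.SeedSequence(seed).spawn(len(gc_targets) * len(lengths))
    cfgs = []
    i = 0
    for gc in gc_targets:
        for length in lengths:
            child_seed = int(children[i].generate_state(1)[0] % (2 ** 31))
            cfgs.append(DesignConfig(target_gc=gc, target_length=length,
                                     prohibited_sources=tuple(prohibited_sources),
                                     rng_seed=child_seed))
            i += 1
    return cfgs
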