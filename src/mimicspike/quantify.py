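"""Spike-in-based absolute quantification of amplicon count tables.

Given an ASV count table, a panel of spike-in mimic sequences, and the known
copy numbers added to each sample, this module assigns features to mimics,
forms additive log ratios (ALR) of environmental over spike-in reads, and
converts them to absolute and normalized microbial loads, pairwise
differential loads, and bacterial-to-fungal (BF) load ratios.

The core identities: with ``E`` environmental reads, ``S`` spike-in reads
and ``c`` spike-in copies added,

    alr           = log10(E / S)
    absolute_load = (E / S) * c = 10**alr * c
    normalized    = absolute_load / sample_amount

Amplification efficiency bias multiplies ``E/S`` by a sample-independent
factor and therefore cancels in differential loads and in BF ratios taken
through a single cross-domain construct.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .scaffold import PrimerSet, in_silico_pcr, MimicConstruct, Segment


class QuantError(ValueError):
    pass


class AmbiguousAssignmentError(QuantError):
    """A feature matches two or more mimics above the identity threshold."""


ENVIRONMENTAL = "environmental"


@dataclass
class CountTable:
    """Integer feature × sample matrix plus optional feature sequences."""

    counts: pd.DataFrame
    feature_seqs: dict[str, str] | None = None

    def __post_init__(self):
        df = self.counts
        if not df.index.is_unique or not df.columns.is_unique:
            raise QuantError("duplicate feature or sample ids")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise QuantError("counts must be integers")
            df = df.astype(np.int64)
        if (df.to_numpy() < 0).any():
            raise QuantError("counts must be non-negative")
        self.counts = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)


@dataclass(frozen=True)
class SampleSpike:
    """Spike-in bookkeeping for one sample."""
    copies: dict[str, float]          # mimic id -> copies added
    sample_amount: float = 1.0
    unit: str = "sample"
    amount_basis: str = "pcr"         # "pcr" | "extraction"

    def __post_init__(self):
        if any(c <= 0 for c in self.copies.values()):
            raise QuantError("spike-in copies must be > 0")
        if self.sample_amount <= 0:
            raise QuantError("sample_amount must be > 0")
        if self.amount_basis not in ("pcr", "extraction"):
            raise QuantError("amount_basis must be 'pcr' or 'extraction'")


@dataclass
class SpikeConfig:
    samples: dict[str, SampleSpike]


@dataclass
class AssignmentResult:
    """Feature→mimic assignment and per-sample aggregated counts."""
    feature_assignments: dict[str, str]   # feature id -> mimic id or "environmental"
    mimic_counts: pd.DataFrame            # mimics × samples
    env_counts: pd.Series                 # per sample
    total_counts: pd.Series               # per sample (partition check anchor)


@dataclass(frozen=True)
class LoadEstimate:
    sample: str
    reference: str                        # mimic id or "aggregate"
    env_reads: int
    mimic_reads: int
    copies_added: float
    alr: float
    absolute_load: float
    normalized_load: float
    unit: str
    passed_qc: bool = True
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------


def _identity(feature: str, target: str) -> float:
    """Infix alignment identity of `feature` against `target`."""
    if not feature or not target or len(feature) > len(target) * 1.5:
        return 0.0
    res = edlib.align(feature, target, mode="HW", task="distance")
    return 1.0 - res["editDistance"] / len(feature)


def predicted_mimic_amplicons(panel: dict[str, str] | dict[str, MimicConstruct],
                              primer_set: PrimerSet | None) -> dict[str, str]:
    """Per-mimic amplicon sequence for a primer set (or the raw panel)."""
    out = {}
    for mid, entry in panel.items():
        seq = entry.full_sequence if isinstance(entry, MimicConstruct) else entry
        if primer_set is None:
            out[mid] = seq
            continue
        construct = entry if isinstance(entry, MimicConstruct) else \
            MimicConstruct(mid, (Segment("artificial", seq, mid, 0, len(seq)),))
        amps = in_silico_pcr(construct, primer_set)
        if amps:
            out[mid] = amps[0].sequence
    return out


def assign_features(table: CountTable, panel, primer_set: PrimerSet | None = None,
                    identity_threshold: float = 0.97) -> AssignmentResult:
    """Assign each feature to a mimic (alignment identity) or to the environment.

    A feature is assigned to a mimic iff its sequence matches that mimic's
    predicted amplicon at identity >= threshold; matching two mimics is an
    error because panel members are designed to be globally dissimilar.
    Counts of multiple features assigned to one mimic are summed; everything
    else is summed as environmental.
    """
    if not panel:
        raise QuantError("mimic panel is empty")
    amplicons = predicted_mimic_amplicons(dict(panel), primer_set)
    seqs = table.feature_seqs or {}
    assignments: dict[str, str] = {}
    for fid in table.feature_ids:
        fseq = seqs.get(fid, "")
        hits = [mid for mid, aseq in amplicons.items()
                if _identity(fseq, aseq) >= identity_threshold] if fseq else []
        if len(hits) > 1:
            raise AmbiguousAssignmentError(
                f"feature {fid} matches multiple mimics: {sorted(hits)}")
        assignments[fid] = hits[0] if hits else ENVIRONMENTAL

    mimic_ids = list(dict(panel))
    mimic_counts = pd.DataFrame(0, index=mimic_ids, columns=table.sample_ids,
                                dtype=np.int64)
    env = pd.Series(0, index=table.sample_ids, dtype=np.int64)
    for fid, target in assignments.items():
        row = table.counts.loc[fid]
        if target == ENVIRONMENTAL:
            env += row
        else:
            mimic_counts.loc[target] += row
    return AssignmentResult(assignments, mimic_counts, env,
                            table.counts.sum(axis=0))


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Random subsampling without replacement to `depth` reads per sample."""
    if depth < 1:
        raise QuantError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    out = {}
    for sample in table.sample_ids:
        col = table.counts[sample].to_numpy()
        total = int(col.sum())
        if depth > total:
            raise QuantError(f"depth {depth} exceeds reads in sample {sample} ({total})")
        out[sample] = rng.multivariate_hypergeometric(col, depth)
    df = pd.DataFrame(out, index=table.counts.index)[table.sample_ids]
    return CountTable(df, table.feature_seqs)


def alr_transform(env_count: float, mimic_count: float,
                  pseudocount: float | None = None) -> float:
    """log10(environmental / spike-in reads); the spike-in is the ALR reference."""
    if pseudocount is not None:
        env_count += pseudocount
        mimic_count += pseudocount
    if mimic_count <= 0:
        raise QuantError("insufficient spike-in reads (zero mimic count); "
                         "use the pseudocount mode or exclude the sample")
    if env_count <= 0:
        raise QuantError("no environmental reads")
    return math.log10(env_count / mimic_count)


def estimate_load(assign: AssignmentResult, spike: SpikeConfig,
                  reference: str = "aggregate",
                  min_mimic_reads: int = 50) -> list[LoadEstimate]:
    """Per-sample absolute and normalized loads using one mimic (or all) as reference.

    Samples whose reference mimic reads fall below ``min_mimic_reads`` are
    flagged and carry NaN loads, mirroring exclusion rather than imputation.
    For the aggregate reference, reads and copies are summed over the mimics
    detected (count > 0) in the sample.
    """
    out = []
    for sample in assign.env_counts.index:
        if sample not in spike.samples:
            raise QuantError(f"no spike-in metadata for sample {sample}")
        meta = spike.samples[sample]
        if reference == "aggregate":
            col = assign.mimic_counts[sample]
            detected = [m for m in meta.copies if col.get(m, 0) > 0]
            mimic_reads = int(col[detected].sum()) if detected else 0
            copies = float(sum(meta.copies[m] for m in detected))
        else:
            if reference not in meta.copies:
                raise QuantError(f"mimic {reference} was not spiked into {sample}")
            mimic_reads = int(assign.mimic_counts.at[reference, sample])
            copies = float(meta.copies[reference])
        env_reads = int(assign.env_counts[sample])
        flags = []
        if mimic_reads < min_mimic_reads:
            flags.append("low_spike_reads")
        if flags:
            out.append(LoadEstimate(sample, reference, env_reads, mimic_reads,
                                    copies, math.nan, math.nan, math.nan,
                                    meta.unit, passed_qc=False,
                                    flags=tuple(flags)))
            continue
        alr = alr_transform(env_reads, mimic_reads)
        absolute = (10.0 ** alr) * copies
        out.append(LoadEstimate(sample, reference, env_reads, mimic_reads,
                                copies, alr, absolute,
                                absolute / meta.sample_amount, meta.unit))
    return out


def differential_load(loads: list[LoadEstimate]) -> pd.DataFrame:
    """log10 fold differences in absolute load between all ordered sample pairs.

    delta = alr_a − alr_b + log10(copies_a / copies_b); antisymmetric in the
    pair order.  All estimates must share the same reference mimic.
    """
    refs = {l.reference for l in loads}
    if len(refs) > 1:
        raise QuantError(f"mixed references in differential_load: {sorted(refs)}")
    usable = [l for l in loads if l.passed_qc]
    rows = []
    for a, b in itertools.permutations(usable, 2):
        delta = a.alr - b.alr + math.log10(a.copies_added / b.copies_added)
        rows.append((a.sample, b.sample, delta))
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "delta_log10_load"])


def gmafd(measured, expected) -> float:
    """Geometric mean of absolute fold differences between paired values.

    exp(mean(|ln(measured/expected)|)); equals 1 for perfect agreement and is
    symmetric in its arguments.
    """
    m = np.asarray(measured, dtype=float)
    e = np.asarray(expected, dtype=float)
    if m.shape != e.shape or m.size == 0:
        raise QuantError("gmafd needs paired, nonempty inputs")
    if (m <= 0).any() or (e <= 0).any():
        raise QuantError("gmafd requires strictly positive values")
    return float(np.exp(np.abs(np.log(m / e)).mean()))


def bf_ratio(bact_load: LoadEstimate, fung_load: LoadEstimate) -> float:
    """Bacterial-to-fungal absolute load ratio for one sample.

    When both loads use the same cross-domain construct as reference the
    spike copies cancel exactly and the ratio reduces to
    (bact env/mimic) / (fung env/mimic).
    """
    if bact_load.sample != fung_load.sample:
        raise QuantError("BF ratio requires loads from the same sample")
    if not (bact_load.passed_qc and fung_load.passed_qc):
        raise QuantError("BF ratio requires QC-passing load estimates")
    if fung_load.absolute_load == 0:
        raise QuantError("zero fungal load")
    return bact_load.absolute_load / fung_load.absolute_load
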