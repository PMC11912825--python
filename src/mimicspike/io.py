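"""Readers and writers for the package's file formats.

FASTA (via Bio.SeqIO, wrapped at 80 columns), TSV count tables / primer
tables / spike-in metadata (pandas), GFF3 segment annotation (1-based
inclusive coordinates per the GFF3 standard) and YAML run configs.  Reads
validate alphabets and integer counts and raise with file context; writes
round-trip losslessly on canonicalized content.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import DesignConfig
from .quantify import CountTable, QuantError, SampleSpike, SpikeConfig
from .scaffold import MimicConstruct, PrimerSet
from .seqs import validate_dna


class FormatError(ValueError):
    pass


# ------------------------------------------------------------------ FASTA

def read_fasta(path, allow_iupac: bool = False) -> dict[str, str]:
    """Ordered id → sequence mapping; alphabet validated."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        try:
            out[rec.id] = validate_dna(str(rec.seq), allow_iupac=allow_iupac,
                                       context=f"record {rec.id}")
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not out:
        raise FormatError(f"{path}: no FASTA records")
    return out


def write_fasta(path, records: dict[str, str], width: int = 80) -> None:
    recs = [SeqRecord(Seq(seq), id=rid, description="")
            for rid, seq in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ------------------------------------------------------------------ TSV

def read_counts_tsv(path, feature_fasta=None) -> CountTable:
    """Feature × sample TSV (header row of sample ids, first column ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"{path}: empty count table")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or \
            not np.allclose(arr, np.round(arr)) or (arr < 0).any():
        raise FormatError(f"{path}: counts must be non-negative integers")
    seqs = read_fasta(feature_fasta) if feature_fasta else None
    try:
        return CountTable(df.astype(np.int64), seqs)
    except QuantError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_counts_tsv(path, table: CountTable) -> None:
    table.counts.rename_axis("feature_id").to_csv(path, sep="\t")


def read_primer_tsv(path) -> list[PrimerSet]:
    df = pd.read_csv(path, sep="\t")
    required = {"name", "forward", "reverse"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: primer TSV needs columns {sorted(required)}")
    try:
        return [PrimerSet(r["name"], r["forward"], r["reverse"])
                for _, r in df.iterrows()]
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_spike_tsv(path) -> SpikeConfig:
    """Columns: sample, mimic, copies [, sample_amount, unit, basis]."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "mimic", "copies"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: spike TSV needs columns {sorted(required)}")
    samples = {}
    for sample, grp in df.groupby("sample", sort=False):
        amounts = grp.get("sample_amount", pd.Series([1.0] * len(grp))).unique()
        units = grp.get("unit", pd.Series(["sample"] * len(grp))).unique()
        bases = grp.get("basis", pd.Series(["pcr"] * len(grp))).unique()
        if len(amounts) > 1 or len(units) > 1 or len(bases) > 1:
            raise FormatError(f"{path}: inconsistent metadata for sample {sample}")
        try:
            samples[str(sample)] = SampleSpike(
                copies={str(r["mimic"]): float(r["copies"]) for _, r in grp.iterrows()},
                sample_amount=float(amounts[0]), unit=str(units[0]),
                amount_basis=str(bases[0]))
        except QuantError as exc:
            raise FormatError(f"{path}: sample {sample}: {exc}") from exc
    return SpikeConfig(samples)


def write_spike_tsv(path, spike: SpikeConfig) -> None:
    rows = []
    for sample, meta in spike.samples.items():
        for mimic, copies in meta.copies.items():
            rows.append((sample, mimic, copies, meta.sample_amount, meta.unit,
                         meta.amount_basis))
    pd.DataFrame(rows, columns=["sample", "mimic", "copies", "sample_amount",
                                "unit", "basis"]).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ GFF3

def write_gff3(path, constructs: list[MimicConstruct]) -> None:
    """Segment annotation; GFF3 coordinates are 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in constructs:
            fh.write(f"##sequence-region {c.id} 1 {len(c)}\n")
        for c in constructs:
            for i, seg in enumerate(c.segments):
                attrs = (f"ID={c.id}.seg{i + 1};label={seg.label};"
                         f"origin={seg.origin}")
                fh.write("\t".join([c.id, "mimicspike", "sequence_feature",
                                    str(seg.start + 1), str(seg.end), ".", "+",
                                    ".", attrs]) + "\n")


def read_gff3_segments(path) -> list[tuple[str, str, int, int]]:
    """(seqid, label, start0, end0) tuples, converted back to 0-based half-open."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{ln}: expected 9 GFF3 columns")
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            out.append((parts[0], attrs.get("label", parts[2]),
                        int(parts[3]) - 1, int(parts[4])))
    return out


# ------------------------------------------------------------------ configs

_DESIGN_KEYS = {f.name for f in dataclasses.fields(DesignConfig)}


def load_design_config(path, seed: int | None = None) -> DesignConfig:
    """YAML mirror of DesignConfig; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: design config must be a mapping")
    unknown = set(raw) - _DESIGN_KEYS
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    if "prohibited_sources" in raw:
        raw["prohibited_sources"] = tuple(raw["prohibited_sources"])
    if seed is not None:
        raw["rng_seed"] = seed
    return DesignConfig(**raw)


def write_run_metadata(path, config, seed: int | None = None, **extra) -> None:
    """Resolved-config JSON record so a run can be reproduced bit for bit."""
    payload = {"config": dataclasses.asdict(config)
               if dataclasses.is_dataclass(config) else config,
               "seed": seed}
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
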