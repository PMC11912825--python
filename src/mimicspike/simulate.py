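"""Synthetic spike-in amplicon experiments with known ground truth.

The simulator emulates the experimental designs used to validate spike-in
mimics: an equimolar pool diluted against a fixed environmental background,
a staggered pool forming a per-sample standard curve, and a cross-domain
series with varying bacterial-to-fungal load ratios.  Read counts are drawn
multinomially at fixed depth with probabilities proportional to copy number
times a per-feature amplification-efficiency bias that is constant across
samples — the mechanism that lets bias cancel in differential analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import CountTable, SampleSpike, SpikeConfig

_DEF_MIMICS = tuple(f"mimic{i + 1:02d}" for i in range(12))


@dataclass(frozen=True)
class SimScenario:
    """One simulated experiment.

    Defaults emulate an equimolar 12-member pool ("mix E"-style, 2e5 total
    copies) spiked into a soil-like environmental pool of 50 taxa with a
    lognormal composition, sequenced to 200 000 reads per sample.
    """
    n_env_taxa: int = 50
    env_total_copies: float = 1.0e6
    env_lognormal_sigma: float = 1.5
    mimic_copies: dict[str, float] = field(
        default_factory=lambda: {m: 2.0e5 / 12 for m in _DEF_MIMICS})
    depth: int = 200_000
    n_samples: int = 4
    efficiency_bias_sigma: float = 0.0
    feature_length: int = 150
    seed: int = 0

    def __post_init__(self):
        if min(self.n_env_taxa, self.depth, self.n_samples) < 1 or \
                self.env_total_copies <= 0 or self.env_lognormal_sigma < 0 or \
                self.efficiency_bias_sigma < 0:
            raise ValueError("scenario parameters must be positive")
        if any(c <= 0 for c in self.mimic_copies.values()):
            raise ValueError("mimic copies must be > 0")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated count table."""
    env_copies: pd.Series               # per env taxon (shared by samples)
    mimic_copies: pd.DataFrame          # mimics × samples
    total_env_copies: pd.Series         # per sample
    bias: pd.Series                     # per feature efficiency multiplier
    spike: SpikeConfig                  # ready-made metadata for quantify

    def to_frame(self) -> pd.DataFrame:
        rows = [("env_total", s, v) for s, v in self.total_env_copies.items()]
        rows += [(m, s, self.mimic_copies.at[m, s])
                 for m in self.mimic_copies.index
                 for s in self.mimic_copies.columns]
        return pd.DataFrame(rows, columns=["feature", "sample", "true_copies"])


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _env_pool(rng, scenario) -> pd.Series:
    rel = rng.lognormal(0.0, scenario.env_lognormal_sigma, scenario.n_env_taxa)
    rel /= rel.sum()
    ids = [f"env{i + 1:03d}" for i in range(scenario.n_env_taxa)]
    return pd.Series(rel * scenario.env_total_copies, index=ids)


def simulate_counts(scenario: SimScenario,
                    mimic_copies_per_sample: pd.DataFrame | None = None,
                    panel_seqs: dict[str, str] | None = None
                    ) -> tuple[CountTable, SimTruth]:
    """Draw a count table from the scenario; returns (table, ground truth).

    ``mimic_copies_per_sample`` (mimics × samples) overrides the scenario's
    per-sample-constant spike levels, enabling dilution-series designs.
    ``panel_seqs`` supplies real mimic sequences for the feature FASTA; by
    default random tag sequences are generated (and recorded).
    """
    rng = np.random.default_rng(scenario.seed)
    env = _env_pool(rng, scenario)
    samples = [f"S{i + 1:02d}" for i in range(scenario.n_samples)]
    if mimic_copies_per_sample is None:
        mimic_copies_per_sample = pd.DataFrame(
            {s: pd.Series(scenario.mimic_copies) for s in samples})
    else:
        samples = list(mimic_copies_per_sample.columns)
    mimics = list(mimic_copies_per_sample.index)

    features = list(env.index) + mimics
    bias = pd.Series(
        rng.lognormal(0.0, scenario.efficiency_bias_sigma, len(features))
        if scenario.efficiency_bias_sigma > 0 else np.ones(len(features)),
        index=features)

    counts = {}
    for s in samples:
        copies = np.concatenate([env.to_numpy(),
                                 mimic_copies_per_sample[s].to_numpy()])
        p = copies * bias.to_numpy()
        counts[s] = rng.multinomial(scenario.depth, p / p.sum())
    df = pd.DataFrame(counts, index=features)[samples]

    seqs = {}
    for fid in features:
        if panel_seqs and fid in panel_seqs:
            seqs[fid] = panel_seqs[fid]
        else:
            seqs[fid] = _random_dna(rng, scenario.feature_length)

    spike = SpikeConfig({
        s: SampleSpike(copies={m: float(mimic_copies_per_sample.at[m, s])
                               for m in mimics})
        for s in samples})
    truth = SimTruth(env, mimic_copies_per_sample,
                     pd.Series({s: float(env.sum()) for s in samples}),
                     bias, spike)
    return CountTable(df, seqs), truth


def simulate_dilution_series(base: SimScenario, levels,
                             panel_seqs: dict[str, str] | None = None
                             ) -> tuple[CountTable, SimTruth]:
    """Fixed environmental pool, total spike copies varying over `levels`.

    The pool composition of the scenario's mimics is preserved while the
    total is scaled to each level, one sample per level.  By design the ALR
    of environmental over spike reads falls on a line of slope −1 against
    log10(spike copies).
    """
    levels = list(levels)
    if len(levels) < 2:
        raise ValueError("need at least 2 spike levels")
    base_pool = pd.Series(base.mimic_copies, dtype=float)
    frac = base_pool / base_pool.sum()
    samples = [f"S{i + 1:02d}" for i in range(len(levels))]
    copies = pd.DataFrame({s: frac * lvl for s, lvl in zip(samples, levels)})
    scenario = SimScenario(**{**base.__dict__, "n_samples": len(levels)})
    return simulate_counts(scenario, mimic_copies_per_sample=copies,
                           panel_seqs=panel_seqs)


def simulate_staggered_mix(copies: dict[str, float], depth: int, seed: int,
                           env_total_copies: float = 0.0,
                           n_env_taxa: int = 30,
                           efficiency_bias_sigma: float = 0.0
                           ) -> tuple[CountTable, SimTruth]:
    """Single-sample staggered pool, optionally on an environmental background."""
    if len(set(copies.values())) < 3:
        raise ValueError("staggered design needs >=3 distinct levels")
    scenario = SimScenario(
        n_env_taxa=max(n_env_taxa, 1),
        env_total_copies=env_total_copies if env_total_copies > 0 else 1e-9,
        mimic_copies=dict(copies), depth=depth, n_samples=1,
        efficiency_bias_sigma=efficiency_bias_sigma, seed=seed)
    table, truth = simulate_counts(scenario)
    if env_total_copies <= 0:
        keep = [f for f in table.feature_ids if f in copies]
        table = CountTable(table.counts.loc[keep],
                           {f: table.feature_seqs[f] for f in keep})
    return table, truth


def staggered_levels(n: int = 8, low: float = 200.0, high: float = 2.5e4,
                     prefix: str = "mimic") -> dict[str, float]:
    """Geometric ladder of spike levels, low to high, one per pool member."""
    levels = np.geomspace(low, high, n)
    return {f"{prefix}{i + 1:02d}": float(v) for i, v in enumerate(levels)}


def simulate_bf_series(bf_ratios, total_load: float = 1.0e6,
                       mimic_copies: float = 1.0e4, depth: int = 100_000,
                       seed: int = 0, n_taxa: int = 30,
                       efficiency_bias_sigma: float = 0.5):
    """Cross-domain series: fixed total mock load split into bacteria and fungi.

    Each sample has bacterial load B and fungal load F with B + F =
    ``total_load`` and B/F equal to the requested ratio.  Both domains are
    observed through their own primer channel (separate count tables) that
    also contains the same cross-domain mimic construct at ``mimic_copies``
    copies.  Per-feature efficiency bias is constant across samples within a
    channel.  Returns (fungal CountTable, bacterial CountTable, truth dict).
    """
    ratios = list(bf_ratios)
    if len(ratios) < 2:
        raise ValueError("need >=2 BF ratios")
    rng = np.random.default_rng(seed)
    samples = [f"BF{i + 1:02d}" for i in range(len(ratios))]
    mimic = "xdom01"

    tables = {}
    for channel in ("fungal", "bacterial"):
        comp = rng.lognormal(0.0, 1.0, n_taxa)
        comp /= comp.sum()
        bias = rng.lognormal(0.0, efficiency_bias_sigma, n_taxa + 1) \
            if efficiency_bias_sigma > 0 else np.ones(n_taxa + 1)
        counts = {}
        for s, r in zip(samples, ratios):
            fung = total_load / (1.0 + r)
            bact = total_load - fung
            load = fung if channel == "fungal" else bact
            copies = np.concatenate([comp * load, [mimic_copies]])
            p = copies * bias
            counts[s] = rng.multinomial(depth, p / p.sum())
        ids = [f"{channel[:4]}{i + 1:03d}" for i in range(n_taxa)] + [mimic]
        df = pd.DataFrame(counts, index=ids)[samples]
        seqs = {fid: _random_dna(rng, 150) for fid in ids}
        tables[channel] = CountTable(df, seqs)

    spike = SpikeConfig({s: SampleSpike(copies={mimic: mimic_copies})
                         for s in samples})
    truth = {"bf_ratios": pd.Series(ratios, index=samples, dtype=float),
             "total_load": total_load, "mimic": mimic, "spike": spike}
    return tables["fungal"], tables["bacterial"], truth
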