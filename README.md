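# mimicspike

Tools for **absolute quantification of microbiomes with synthetic rRNA-operon
spike-in standards**, covering both the design of the standards and the
downstream analysis of amplicon count data.

Amplicon sequencing yields relative abundances only: a change in any taxon's
absolute abundance shifts every other taxon's proportion, and profiles
obtained with different primer sets (e.g. fungal ITS vs bacterial 16S) are
proportions of different wholes and cannot be compared directly.  Adding a
known number of copies of a synthetic standard — a construct that carries the
conserved primer-binding regions of a natural rRNA operon around artificial,
globally unique variable regions — anchors read counts to absolute copy
numbers.  With `E` environmental reads, `S` spike-in reads and `c` spike-in
copies added to a sample, the package works with

- the additive log ratio **ALR = log10(E / S)** (the spike-in is the
  reference component of the composition),
- the absolute microbial load **L = (E / S) · c = 10^ALR · c**, optionally
  normalized per unit of sample material,
- pairwise **differential loads** Δ = ALR₁ − ALR₂ + log10(c₁/c₂),
- agreement expressed as the **gmAFD**, the geometric mean of absolute fold
  differences, exp(mean |ln(measured/expected)|),
- cross-domain **bacterial-to-fungal (BF) load ratios**, which are perfectly
  calibrated when both domains are quantified through a single cross-domain
  construct (the spike copies cancel).

Because the standards are processed together with the sample through PCR,
sequencing and denoising, amplification bias affects them and the natural
templates alike; bias that is constant across samples cancels exactly in
differential loads and BF ratios — the property the whole framework exploits,
and the property the bundled simulator reproduces.

## What is in the package

| module | purpose |
|---|---|
| `mimicspike.design` | constrained random design of artificial variable regions: 20-mer seeds assembled under screens for homopolymers (≤3 bp), direct/inverted repeats (≤8 bp), GC uniformity (sliding-window deviation ≤2.5 points), primer-derived 8-mers (none), balanced composition, and mutual dissimilarity (local alignments ≤16 bp) |
| `mimicspike.scaffold` | building full constructs from natural conserved primer-binding blocks plus artificial inserts; IUPAC-aware primer-site location; in-silico PCR |
| `mimicspike.quantify` | feature→mimic assignment, rarefaction, ALR, load and differential-load estimation, gmAFD, BF ratios |
| `mimicspike.qc` | staggered-pool standard curves (log–log OLS), rectangular-hyperbola dose–response fits, per-sample QC flags |
| `mimicspike.simulate` | multinomial read-count simulator with known ground truth (dilution series, staggered pools, cross-domain BF series) |
| `mimicspike.io` / `mimicspike.cli` | FASTA/TSV/GFF3/YAML formats and the `mimicspike` subcommand CLI |

## Worked example

Design one artificial sequence and quantify a simulated spike-in dilution
series (four samples sharing one environmental pool of 10⁶ rRNA-operon
copies, spiked with 10³…10⁶ total standard copies, 200 000 reads each):

```python
import numpy as np
from scipy import stats
from mimicspike import (DesignConfig, assemble_sequence, SimScenario,
                        simulate_dilution_series, assign_features,
                        estimate_load, differential_load)

art = assemble_sequence(DesignConfig(target_gc=0.5, target_length=400, rng_seed=42))
print(len(art.sequence), f"{art.gc:.3f}", art.screen.passed)
# 400 0.500 True

table, truth = simulate_dilution_series(SimScenario(seed=7, depth=200_000),
                                        [1e3, 1e4, 1e5, 1e6])
panel = {m: table.feature_seqs[m] for m in truth.mimic_copies.index}
loads = estimate_load(assign_features(table, panel), truth.spike)
for l in loads:
    print(f"{l.sample}  spike={l.copies_added:9.0f}  ALR={l.alr:6.3f}  "
          f"load={l.absolute_load:.3e}")
```

```
S01  spike=     1000  ALR= 2.980  load=9.559e+05
S02  spike=    10000  ALR= 1.999  load=9.976e+05
S03  spike=   100000  ALR= 1.004  load=1.009e+06
S04  spike=  1000000  ALR=-0.002  load=9.965e+05
```

Each sample recovers the true environmental load of 10⁶ copies to within a
few percent regardless of how much standard was added; the ALR falls by one
unit per 10-fold spike increase (fitted slope −0.994, design expectation −1),
and the largest pairwise differential load is 0.023 log10 units where the
truth is 0:

```python
slope = stats.linregress(np.log10([1e3, 1e4, 1e5, 1e6]),
                         [l.alr for l in loads]).slope   # -0.994
differential_load(loads)["delta_log10_load"].abs().max() # 0.0234
```

The same workflow is available from the shell:

```bash
mimicspike design --seed 4 --out-prefix out/panel
mimicspike simulate --seed 2 --dilution-levels 1e3,1e4,1e5,1e6 --out-prefix out/sim
mimicspike quantify --counts out/sim.counts.tsv --features out/sim.features.fasta \
    --panel out/sim.panel.fasta --spike out/sim.spike.tsv --out-prefix out/quant
```

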