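# Methods

## Sequence design model

Artificial variable-region sequences are built by progressive assembly of
random 20-mers.  Each seed 20-mer is drawn with an exact GC count
(`round(target_gc × 20)`), near-equal A/T and G/C splits (|G−C| ≤ 1 base,
|A−T| ≤ 1 base), and no homopolymer longer than 3 bp.  Assembly is greedy
append-with-rejection: a candidate 20-mer is appended, the whole prefix is
re-screened, and the candidate is resampled on failure (up to 200 resamples
per step).  If no candidate passes, up to 5 previously accepted 20-mers are
discarded (bounded backtracking); a global `max_attempts` cap turns a
persistently unsatisfiable configuration into an explicit `DesignError`
naming the most-violated constraint.

Screens applied to every prefix and to the final sequence:

| screen | threshold (default) | notes |
|---|---|---|
| homopolymer run | ≤ 3 bp | exact longest-run scan |
| direct repeat | ≤ 8 bp | substring at ≥2 distinct start positions; overlap allowed |
| inverted repeat | ≤ 8 bp | substring whose reverse complement also occurs; self-palindromes count; conservative hairpin proxy that also stands in for thermodynamic secondary-structure assessment, which is out of scope |
| windowed GC | ≤ 2.5 points | window 100 bp, step 10 bp, final flush window included; reference is the sequence's own overall GC; while the sequence is shorter than one window the whole-sequence GC is held to the target instead |
| prohibited k-mers | 0 hits | all 8-mers of each primer and its reverse complement, IUPAC-expanded, matched on the designed forward strand (amplicons are double-stranded) |
| composition balance | |A−T|, |G−C| ≤ 0.05 | frequency differences; the only balance notion compatible with fixed GC targets |
| self/pairwise local alignment | ≤ 16 columns | see below |

Window 100/step 10 is the standard scale for GC-uniformity scans; it is not
externally prescribed, so it is configurable.

### Similarity screen

Local alignments use affine-gap Smith–Waterman with match +1, mismatch −3,
gap open −5, gap extend −2 (BLAST-like defaults; first gap base costs 5,
each additional 2).  "Alignment length" is the number of aligned columns of
an optimal local alignment; among co-optimal alignments the tie-break prefers
the longer one, which is conservative for a screen.  For self-comparisons,
match cells on the main diagonal are excluded.  Both orientations of the
second sequence are scored.  In addition to the alignment screen, the longest
*exact* shared substring (forward or reverse complement) between panel
members must also be ≤ 16 bp — a stricter, parameter-free companion, because
"alignment longer than 16" is ambiguous between aligned columns and exact
matches; the package enforces the union of both readings.

Panel design regenerates a member from a fresh deterministic substream
(`SeedSequence(rng_seed, spawn_key=(retry,))`) whenever it violates the
between-sequence screen against already-accepted members.  Each panel member
draws its seeds from its own config's generator (a fresh pool per sequence,
not a shared pool).

The default panel grid is 3 GC targets (0.40/0.50/0.60) × 3 lengths
(300/450/600 bp) = 9 sequences, screened against the package's built-in
primer sets.  Of those, 1391f (`GTACACACCGCCCGTC`) and LR3 reverse
(`GGTCCGTGTTTCAAGACGG`) are the canonical eukaryotic SSU/fungal LSU primers;
the remaining defaults (EukBr, ITS1-F/ITS2, ITS3/ITS4, LR0R, 515F/806R) are
the field-standard choices for the SSU-V9, ITS1, ITS2, LSU-D1D2 and SSU-V4
loci.  Any primer set can be supplied via TSV.

## Construct scaffolding

A construct plan is an alternating list of primer anchors and fillers.  Each
anchor must have exactly one site on the reference (ambiguity is a hard
error: silent mis-anchoring corrupts constructs); its conserved block is the
primer footprint extended 20 bp on both sides by default (configurable).
`artificial` fillers replace the natural region between adjacent anchor
blocks; `natural` fillers keep it verbatim, merging into a single conserved
segment.  Coordinates are 0-based half-open internally and 1-based inclusive
in GFF3 output.  Primer-site matching is IUPAC-aware with a configurable
mismatch allowance (default 0 — references are exact by construction);
reference `N` bases count as mismatches unless the primer code is `N`.
In-silico PCR pairs every forward-orientation forward-primer site with every
downstream reverse-orientation reverse-primer site within a maximum amplicon
length (default 3000 bp), primers included.

## Quantification

Features (ASVs) are assigned to a mimic when their sequence aligns to that
mimic's predicted amplicon at ≥ 0.97 identity (infix edit-distance
alignment, so primer-trimmed reads match untrimmed amplicons).  Panel
members are designed to be globally dissimilar, so the threshold is
uncritical; a feature matching two mimics indicates a broken panel and is an
error, not a tie-break.  Counts of multiple features assigned to one mimic
are summed; all other counts are summed as environmental.  The partition
(mimic + environmental = table total, per sample) is exact by construction
and asserted in tests.

Loads: `absolute_load = (env_reads / mimic_reads) × copies_added`;
`normalized_load` divides by the declared sample amount.  Samples with fewer
than `min_mimic_reads` (default 50) reference reads are flagged and carry
NaN loads — exclusion, not imputation, mirroring practice; an optional
+0.5-pseudocount ALR path exists and is clearly labelled.  The aggregate
reference sums reads and copies over the mimics detected (count > 0) in each
sample.  Differential load between samples is
Δ = ALR₁ − ALR₂ + log10(c₁/c₂), antisymmetric by construction.  gmAFD is
computed in natural log internally (`exp(mean|ln m/e|)`), identical to the
log10 formulation.  Copies may be declared per PCR or per extraction;
normalized loads require the matching basis and mismatches are an error
rather than a silent conversion.

Rarefaction draws each sample column from a multivariate hypergeometric
distribution (subsampling without replacement) with a recorded seed.  Where
a rarefaction depth is configured, environmental totals are summed after
rarefaction (both orders are available).

## QC fits

Standard curves for staggered pools regress log10(within-pool read
percentage) on log10(copies) by ordinary least squares; percentages are
taken within the subcomposition of all detected pool members, members with
zero reads are dropped from the fit, fewer than 3 usable points yields a
flagged fit, and a per-fit exclusion list supports leaving out members with
known primer-site differences without hard-coding taxonomy.  Dose–response
curves are fit as two-parameter rectangular hyperbolas y = a·x/(b+x)
(asymptote a = read ceiling at fixed depth, half-saturation b in copies) by
bounded least squares from (max(y), median(x)); constant responses and
non-convergence are flagged, not raised.  QC flags: total mimic reads below
threshold, mimic read fraction above a saturation warning (default 95 %, at
which point environmental counts are too depleted to quantify), and curve
slope/R² outside configured bands.

## Simulator

The simulator emulates the validation designs for spike-in standards: reads
are multinomial at fixed depth with probabilities proportional to copy
number × per-feature amplification-efficiency bias, where the bias is
lognormal(0, σ_bias) and **constant across samples** — the mechanism by
which bias cancels in differential analyses, and the property end-to-end
tests rely on.  Default conditions, chosen once: an environmental pool of 50
taxa with lognormal(σ = 1.5) composition totalling 10⁶ operon copies; an
equimolar 12-member spike pool of 2×10⁵ total copies; 200 000 reads per
sample; dilution series at 10³–10⁶ total spike copies (10-fold steps);
staggered pools of 8 members from 200 to 2.5×10⁴ copies; cross-domain series
of 7 samples spanning BF ratios 0.025–40 at fixed total mock load, observed
through separate fungal and bacterial primer channels sharing one
cross-domain construct, with σ_bias = 0.5.

What the simulator does **not** model: read-level errors, chimeras,
denoising artifacts, PCR-cycle-explicit amplification, amplicon-length bias,
primer-template mismatches, and cross-sample bias drift.  Passing the
simulation-based tests therefore demonstrates the correctness of the
quantification algebra and its robustness to sampling noise and consistent
efficiency bias — not robustness to the full error structure of real
sequencing runs.

## Numerical and determinism notes

- All randomness flows from one recorded integer seed per run;
  `numpy.random.Generator` streams are derived via `SeedSequence.spawn`, so
  identical config + seed reproduces panels and tables byte for byte.
- Repeat scans use binary search over substring length (valid by
  monotonicity); their correctness is checked against exhaustive
  diagonal-scan oracles in the test suite.
- The alignment kernel is integer-scored; scores were verified to agree with
  an independent exhaustive dynamic-programming implementation across random
  sequence pairs.
- Problem sizes in tests and in the acceptance script (panels of 9 sequences
  of 300–600 bp; simulations at 2×10⁵ reads × 4–7 samples) were chosen so
  the statistical criteria have comfortable margins at a single fixed seed;
  a full run of the suite completes in well under a minute.

## Known limitations

- The designer's constraint system becomes infeasible at extreme GC targets
  combined with long sequences (a 2-letter alphabet cannot avoid >8 bp
  repeats beyond ~250 bp); this surfaces as an explicit design failure.
- BLAST novelty screening against public databases is a manual step: the
  designer emits FASTA for it but does not call external services.
- No correction for rRNA-operon copy-number variation between taxa: loads
  are operon copies, not cell counts.
- Amplicon-length bias correction is out of scope.
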