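# Methods

## The depletion-kinetics model

A randomized-PAM cleavage assay starts from a pool of 256 double-stranded
150-bp substrates, identical except for the 4 PAM bases 5′ of a shared
23-nt protospacer. With nuclease in excess and substrate concentrations
far below saturation, each PAM's substrate pool decays independently and
exponentially: if `f0(p)` is PAM `p`'s share of the uncleaved library,
its expected share of the *surviving* pool at quench time `t` is

    f_t(p) = f0(p) · exp(−k(p)·t) / Z(t),   Z(t) = Σ_q f0(q) · exp(−k(q)·t),

because sequencing samples from whatever remains. Dividing `p`'s sample
frequency by its control frequency gives `exp(−k·t)/Z(t)`; the `1/Z(t)`
survivorship factor is common to all PAMs and is removed by dividing by
the median ratio of the 12 VRRT PAMs (`V∈{A,C,G}, R∈{A,G}`), which have
`k = 0`. The normalized series is then `y(t) ≈ A·exp(−k·t)` with `A ≈ 1`,
and `(A, k)` are estimated per PAM by bounded nonlinear least squares.

Key numerical choices:

- **Pseudocount 0.5** on raw counts in both numerator and denominator keeps
  ratios finite when a strongly cleaved PAM reaches zero reads at late time
  points. Configurable; at typical depths (~400 reads/PAM) its bias is
  negligible.
- **Per-time-point VRRT normalization.** The null-set median is computed and
  applied independently at each quench time, so `y(0) ≈ 1` by construction
  and slow drifts in library composition cancel per sample.
- **No clamping of ratios above 1.** Sampling noise pushes some ratios past
  1; clamping would bias `k` upward. The amplitude bound `A ≤ 2` absorbs
  this instead.
- **Fit**: `scipy.optimize.least_squares` (trust-region reflective), bounds
  `k ∈ [0, ∞)`, `A ∈ (0, 2]`, tolerances 1e-8, ≤ 1000 evaluations.
  Initialization `A₀ = y(0)` (1 if `y(0) ≤ 0`) and `k₀` from a log-linear
  regression on the positive points; on noiseless data the initializer is
  already exact, so recovery is exact to optimizer tolerance for any
  `k ∈ [0, 2]` on the nine-point grid. A failed optimization is reported
  with `converged = False` rather than raised; non-converged PAMs are
  excluded from max-normalization.
- **Normalization denominator**: the maximum fitted `k` over converged PAMs
  (ties reported lexicographically). If all rates are zero the normalized
  rates are reported as zero.

## What the synthetic generator emulates — and what it does not

`simulate_depletion_run` reproduces the experiment's observable structure:
near-uniform control composition (symmetric Dirichlet, α = 200 — enough
inequality to be realistic, never zero), multinomial read sampling from the
surviving pool at each of the nine quench times {0, 1, 2, 4, 6, 8, 10, 16,
32} min, 75-bp single-end reads covering flank+PAM+protospacer, i.i.d.
substitution errors (default 0.2% per base) with two-level Phred qualities
(37 for correct calls, 11 for errors), a 1% fraction of reads carrying one
low-quality-but-correct PAM base (so the Phred ≥ 30 filter path is
exercised), and 10% of reads reported on the opposite strand (so
orientation handling is exercised). Identical configs produce byte-identical
FASTQ.

It deliberately does **not** model PCR amplification bias or duplicates
(amplification is treated as unbiased resampling), position-dependent
quality decay, realistic Illumina error spectra, indels in reads, or
paired-end structure. Passing tests therefore demonstrate correctness of
the estimators under the model's idealizations — multinomial counting
noise, uniform substitution error, known decay — not robustness to every
artifact of real libraries.

### Activity presets

The presets plant rate-constant surfaces that mimic the qualitative
behaviour of characterized orthologs, with `k_max = 0.5 min⁻¹` by default:

| class | stringent | permissive |
|---|---|---|
| TTTV | `k_max` | `k_max` |
| CTTV | `0.1·k_max` | U(0.2, 0.4)·`k_max` |
| TCTV, TTCV | background | U(0.2, 0.4)·`k_max` |
| CCTV, TCCV, CCCV | background | `0.1·k_max` |
| TTTT | `0.05·k_max` | `0.2·k_max` |
| VRRT (12 PAMs) | 0 exactly | 0 exactly |
| all others | background | background |

"Background" is log-uniform in `[0.02, 0.08]·k_max` rather than exactly
zero. This is a deliberate design choice: a rate *spectrum* with 250 exact
zeros has no recoverable rank structure (rank correlation saturates far
below 1 from ties alone), whereas real randomized libraries show a graded
continuum of weak activities. The graded background makes "the pipeline
recovers the full rate ranking" a falsifiable claim: Spearman agreement
between true and fitted `k` across all 256 PAMs is ~0.97 at 100,000
reads/time point. The uncleavable VRRT set stays at exactly zero because it
is the normalization null.

### Sequencing depth and precision

At 100,000 reads per time point each PAM receives ~400 reads, so a single
depletion ratio has ~7% counting noise. For fast PAMs (`k = 0.5 min⁻¹`)
only the first few time points are informative and the fitted `k` carries
~10% statistical error; mid-range rates (0.05–0.2 min⁻¹) spread information
across the whole grid and are recovered within a few percent. The
acceptance checks therefore evaluate the median relative error over all
PAMs with true `k ∈ [0.05, 1] min⁻¹`, pooled across the stringent and
permissive runs.

## Read processing

The protospacer is a constant library region, so anchoring is an exact
string match (configurable length), tried forward then reverse-complement;
reads with zero or multiple anchor occurrences are discarded with a tallied
reason, as are reads with fewer than 4 bases 5′ of the anchor, any PAM base
below Phred 30, or an ambiguous PAM base. "Normalized to total reads" means
total reads passing all filters in that sample. All 256 PAMs are always
present in the output table (zeros allowed), and accounting is conserved:
reads used + reads discarded = reads in.

## PAM logos and stringency

Logo weights default to fitted rate constants, which integrate the whole
time course; weighting by terminal depletion `(1 − y(t_final))` is a
one-line alternative the caller can pass instead, since the choice of
weight is a convention rather than part of the model. No small-sample logo
correction is applied — the weights are rates, not counts. Stringency
ratios accept either in vitro `k` values keyed by PAM or in vivo
percent-modified values keyed by site (with an explicit site→class map).

## Indel quantification

Reads are globally aligned to the wild-type amplicon (match +1, mismatch
−1, gap open −4, gap extend −1, free end gaps on the read) with Biopython's
`PairwiseAligner`. A read is modified iff an insertion or deletion footprint
intersects the cut window: centre at protospacer position 19 from the
PAM-proximal end — inside the 18–23 region where Cas12a's staggered cut
leaves 4–5-nt 5′ overhangs distal to the PAM — half-width 10 bp, both
configurable. Substitutions never count. Reads scoring below 50% of a
perfect match are dropped as unalignable and excluded from the denominator.
The T7E1 estimator is provided in two variants: the standard corrected form
`100·(1 − √(1 − (b+c)/(a+b+c)))` (default) and a literal form
`100·(1 − √(b+c)/(a+b+c))` that reproduces a common transcription of the
formula; the literal form returns 100% at zero cleavage product, which is
why the corrected form is the default.

## Off-target scanning

The scanner reports every locus (both strands) where a 4-mer matching the
IUPAC PAM pattern (default TTTN) sits immediately 5′ of a 23-mer within
the Hamming-distance budget of the query spacer — mismatch-only, no bulges,
matching the default mode of mismatch-enumeration tools. Coordinates are
BED-style 0-based half-open forward-strand intervals over PAM+protospacer.
Windows containing N never match and are excluded from the density
denominator. The implementation is a vectorized O(L·W) sweep per strand; at
the scale this package targets (simulated genomes, candidate-site
nomination for amplicon panels) no index structure is warranted. Density
counts overlapping occurrences on both strands; on an i.i.d. uniform genome
the expected TTTN spacing is 32 bp (2·(1/4)³ per position), and on a genome
with human-like base composition (29.5% A/T, 20.5% G/C) about 19.5 bp —
consistent with the rule of thumb that a TTTN PAM occurs at least once per
25 bp in the human genome. The human-composition genome used by the
acceptance script is synthetic; the package ships no reference data.

## Problem sizes used in validation

The test suite and acceptance script run the full pipeline at 100,000
reads per time point (the assay's native depth) for two presets; scanner
validation uses 10-kb genomes with planted sites at and beyond the
mismatch budget against a position-by-position brute-force oracle; indel
recovery uses 1,000-read amplicon sets at planted fractions 5/30/60% with
0.5% substitution error; density checks use 1-Mb synthetic genomes. These
sizes make every estimator's statistical behaviour visible while keeping a
full validation run around a minute.

## Known limitations

- Single-replicate point estimates of `k`, no confidence intervals, and no
  plateau (`A + C·e^(−kt)`) variant.
- The percent-modified caller produces per-site totals, not allele tables;
  HDR and base-editing outcomes are out of scope.
- The scanner does not score cleavage likelihood (no CFD/MIT-style
  weights) and does not model DNA/RNA bulges.
- Anchor matching tolerates no mismatches by default; a highly error-prone
  platform would lose reads rather than miscount them (the discard log
  makes this visible).
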