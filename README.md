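# pamkit

PAM specificity profiling for Cas12a nucleases from depletion-sequencing
time courses — plus amplicon indel quantification and PAM-aware off-target
site scanning.

## The problem

Cas12a (Cpf1) nucleases require a short T-rich protospacer adjacent motif
(PAM) 5′ of their 23-nt protospacer. How *strictly* a given ortholog reads
that motif determines both its targetable sequence space and its off-target
behaviour: a nuclease that tolerates C-containing variants of the canonical
TTTV PAM (V = A, C, G) will also cut unintended loci whose only deviation is
in the PAM. The standard in vitro assay to measure this mixes all 256
substrates carrying a randomized 4-nt PAM ahead of a fixed protospacer,
incubates them with the nuclease, quenches aliquots at
t = 0, 1, 2, 4, 6, 8, 10, 16, 32 min, and deep-sequences the surviving
substrates alongside an uncleaved negative-control library.

`pamkit` is the analysis side of that experiment, built for people running
or simulating PAM-library cleavage assays:

1. **Read processing** — anchor each 75-bp read on the protospacer (either
   strand), extract the 4 PAM bases, apply the Phred ≥ 30 filter to those
   bases, and tally counts over all 256 PAMs.
2. **Depletion kinetics** — per PAM *p* and time *t*, the depletion ratio
   is the PAM's read frequency in the cleavage sample over its frequency in
   the negative control, then divided by the median ratio of the 12
   uncleavable **VRRT** PAMs (V ∈ {A,C,G}, R ∈ {A,G}), which pins the null
   set at 1. Each PAM's series is fit by bounded nonlinear least squares to

   *y*(*t*) = *A* e^(−*k t*),  *k* ≥ 0 min⁻¹, 0 < *A* ≤ 2,

   and rates are reported normalized to the maximum fitted *k*.
3. **Profiles** — rate-weighted PAM logos (position probability matrix and
   per-position information content, IC = 2 − H bits) and class-wise
   stringency ratios (mean activity of each C-containing class / TTTV).
4. **Indel quantification** — percent-modified from amplicon reads
   (alignment-based, indels only, cut window at protospacer position 19
   ± 10 bp), the T7E1 band-intensity estimator, and on/off-target
   specificity ratios.
5. **Off-target scanning** — mismatch-only search for PAM+spacer loci on
   both strands (Cas-OFFinder-style), and genome-wide PAM density.
6. **Synthetic data** — generators for every input above with known ground
   truth (per-PAM rate constants, planted indel fractions, planted target
   sites), so the whole pipeline is testable end to end without downloads.

## Worked example

```python
import pamkit as pk

profile = pk.make_rate_profile("stringent", k_max=0.5, seed=1)
config = pk.SimulationConfig(profile=profile, reads_per_sample=20_000, seed=1)
run = pk.simulate_depletion_run(config)

control = pk.count_pams(run.control.iter_reads(), run.anchor)
samples = {t: pk.count_pams(s.iter_reads(), run.anchor)
           for t, s in run.samples.items()}
table = pk.estimate_rates(samples, control)
for pam in pk.rank_pams(table, 5):
    print(pam, pk.classify_pam(pam), round(table.estimates[pam].k, 3))
```

prints

```
TTTA TTTV 0.483
TTTC TTTV 0.42
TTTG TTTV 0.399
CTTA CTTV 0.054
CTTG CTTV 0.053
```

The three canonical TTTV PAMs lead with fitted rate constants near the
planted 0.5 min⁻¹, and the CTTV class recovers its planted 10%-of-maximum
activity — the signature of a stringent PAM reader. The `examples/`
directory has one short script per capability (PAM taxonomy, kinetics,
logos/stringency, indel quantification, off-target scanning); each prints
the numbers it computes and what they mean. A thin CLI wraps the same
stages (`pamkit simulate | count | kinetics | profile | indel | scan |
demo`).

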