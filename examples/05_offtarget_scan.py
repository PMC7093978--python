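"""Scan a genome for PAM-aware candidate off-target sites.

A candidate site is a TTTN PAM immediately 5' of a 23-mer within a
Hamming-distance budget of the query spacer, on either strand — the
mismatch-only search used to nominate off-target loci for targeted deep
sequencing. Also reports genome-wide TTTN density.
"""

import numpy as np

import pamkit as pk

rng = np.random.default_rng(3)
spacer = "".join(rng.choice(list("ACGT"), size=23))

genome = pk.simulate_genome(
    50_000,
    [pk.PlantedSite(spacer, "TTTA", "+", n_mismatches=0),   # on-target
     pk.PlantedSite(spacer, "TTTG", "-", n_mismatches=2),   # off-target
     pk.PlantedSite(spacer, "TTTC", "+", n_mismatches=4)],  # distant off-target
    seed=3,
)
hits = pk.scan_genome(genome.sequences, spacer, pam_pattern="TTTN", max_mismatches=4)
print(f"query spacer: {spacer}")
print(f"{len(hits)} candidate site(s):")
for h in hits:
    print(f"  {h.chrom}:{h.start}-{h.end} ({h.strand}) PAM={h.pam} "
          f"mismatches={h.n_mismatches}")

density = pk.pam_density(genome.sequences, "TTTN")
print(f"TTTN density: one PAM per {density.mean_spacing:.1f} bp "
      f"({density.n_occurrences} occurrences on both strands) — "
      f"targetable sites are never far apart")
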