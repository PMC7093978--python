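"""Quantify editing from amplicon reads and T7E1 band intensities.

percent_modified aligns each read to the wild-type amplicon and counts
reads with an insertion or deletion overlapping the Cas12a cut window
(protospacer position 19 +/- 10 bp). The T7E1 formula estimates the same
quantity from gel band intensities.
"""

import numpy as np

import pamkit as pk
from pamkit.indel import BandIntensities

rng = np.random.default_rng(42)
reference = "".join(rng.choice(list("ACGT"), size=200))
protospacer = reference[80:103]

sim = pk.simulate_amplicon_reads(
    reference, protospacer, indel_fraction=0.30,
    indel=pk.IndelSpec(size=4, kind="deletion"),
    n_reads=1000, error_rate=0.005, seed=7,
)
call = pk.percent_modified(sim.reads, reference, protospacer)
print(f"planted indel fraction 30% -> percent modified = "
      f"{call.percent_modified:.1f}% ({call.reads_with_indel}/{call.reads_total} reads)")

t7e1 = pk.t7e1_percent(BandIntensities(a=150, b=25, c=25))
print(f"T7E1 bands a=150, b=25, c=25 -> {t7e1:.3f}% indels "
      f"(corrected estimator, cut fraction 25%)")

ratio = pk.specificity_ratio(off_target_pct=0.5, on_target_pct=50.0)
print(f"off-target 0.5% vs on-target 50% -> specificity ratio {ratio:.3f} "
      f"(smaller = more specific)")
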