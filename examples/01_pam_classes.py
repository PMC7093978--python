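"""Enumerate the 4-mer PAM library and its class taxonomy.

Cas12a reads a 4-nt PAM 5' of the protospacer; the library of all 256
PAMs partitions into the canonical TTTV class, six C-containing classes,
TTTT, and OTHER. The 12 VRRT PAMs are never cleaved and serve as the
normalization null set in depletion experiments.
"""

from collections import Counter

from pamkit import classify_pam, enumerate_pams, iupac_match, vrrt_pams

pams = enumerate_pams(4)
print(f"library size: {len(pams)} PAMs ({pams[0]} .. {pams[-1]})")

sizes = Counter(classify_pam(p) for p in pams)
for cls in ("TTTV", "CTTV", "TCTV", "TTCV", "CCTV", "TCCV", "CCCV", "TTTT", "OTHER"):
    print(f"  class {cls:5s}: {sizes[cls]:3d} PAMs")

null_set = vrrt_pams()
print(f"VRRT null set ({len(null_set)} uncleavable PAMs): {', '.join(null_set)}")
print("TTTA matches TTTV:", iupac_match("TTTV", "TTTA"), "| TTTT matches TTTV:",
      iupac_match("TTTV", "TTTT"))
# The class sizes sum to 256: every PAM belongs to exactly one class.
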