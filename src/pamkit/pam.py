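"""PAM alphabet, enumeration, IUPAC matching, and the PAM-class taxonomy.

Cas12a nucleases read a short T-rich protospacer adjacent motif (PAM)
immediately 5' of the protospacer. Here a PAM is a 4-mer over {A,C,G,T};
the canonical optimal motif is TTTV (V = A, C, or G), and single- or
double-C substitutions of the three T positions define the non-canonical
"C-containing" classes used when comparing PAM stringency between
orthologs. The 12 PAMs matching VRRT are not cleaved by Cas12a and serve
as the normalization null set in depletion experiments.
"""

from __future__ import annotations

from itertools import product

__all__ = [
    "PAM_ALPHABET",
    "PAM_LENGTH",
    "IUPAC",
    "PAM_CLASSES",
    "VRRT_PATTERN",
    "enumerate_pams",
    "iupac_match",
    "classify_pam",
    "reverse_complement",
    "vrrt_pams",
    "class_table",
]

PAM_ALPHABET = "ACGT"
PAM_LENGTH = 4

#: IUPAC nucleotide ambiguity codes mapped to their base sets.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Class patterns in precedence order. TTTT is tested before the V-classes
#: so that the nine labels (these eight plus OTHER) partition the 256 PAMs.
PAM_CLASSES: tuple[str, ...] = (
    "TTTT",
    "TTTV",
    "CTTV",
    "TCTV",
    "TTCV",
    "CCTV",
    "TCCV",
    "CCCV",
)

OTHER_CLASS = "OTHER"

#: The uncleavable null set used for depletion-ratio normalization.
VRRT_PATTERN = "VRRT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def enumerate_pams(length: int = PAM_LENGTH) -> list[str]:
    """Return all 4**length PAM sequences in lexicographic order (A<C<G<T).

    >>> enumerate_pams(1)
    ['A', 'C', 'G', 'T']
    """
    if not isinstance(length, int) or length < 1:
        raise ValueError(f"PAM length must be a positive integer, got {length!r}")
    return ["".join(p) for p in product(PAM_ALPHABET, repeat=length)]


def iupac_match(pattern: str, seq: str) -> bool:
    """True iff every base of ``seq`` is in the base set of the matching
    ``pattern`` symbol. ``seq`` must be unambiguous (A/C/G/T only)."""
    if len(pattern) != len(seq):
        raise ValueError(
            f"pattern length {len(pattern)} != sequence length {len(seq)}"
        )
    for sym, base in zip(pattern, seq):
        if base not in PAM_ALPHABET:
            raise ValueError(f"ambiguous or invalid base {base!r} in sequence")
        try:
            allowed = IUPAC[sym]
        except KeyError:
            raise ValueError(f"invalid IUPAC symbol {sym!r} in pattern") from None
        if base not in allowed:
            return False
    return True


def classify_pam(seq: str) -> str:
    """Map a 4-mer PAM to its class label.

    Labels are TTTT, the seven V-class patterns (TTTV, CTTV, TCTV, TTCV,
    CCTV, TCCV, CCCV), or OTHER. TTTT is matched first so the labels are
    disjoint; every PAM maps to exactly one label.
    """
    if len(seq) != PAM_LENGTH or any(b not in PAM_ALPHABET for b in seq):
        raise ValueError(f"not a valid PAM sequence: {seq!r}")
    for label in PAM_CLASSES:
        if iupac_match(label, seq):
            return label
    return OTHER_CLASS


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}."""
    s = seq.upper()
    if any(b not in "ACGTN" for b in s):
        bad = next(b for b in s if b not in "ACGTN")
        raise ValueError(f"invalid character {bad!r} in DNA sequence")
    return s.translate(_COMPLEMENT)[::-1]


def vrrt_pams() -> list[str]:
    """The 12 VRRT-matching PAMs (V in {A,C,G}, R in {A,G}), sorted."""
    return [p for p in enumerate_pams(PAM_LENGTH) if iupac_match(VRRT_PATTERN, p)]


def class_table() -> dict[str, str]:
    """PAM -> class label for all 256 PAMs, in lexicographic PAM order."""
    return {p: classify_pam(p) for p in enumerate_pams(PAM_LENGTH)}
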