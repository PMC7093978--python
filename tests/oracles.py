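"""Independent brute-force oracles used only by the test suite."""

from itertools import product

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def expand_pattern(pattern: str) -> list[str]:
    """All unambiguous sequences matching an IUPAC pattern, by expansion."""
    return ["".join(p) for p in product(*(IUPAC_SETS[s] for s in pattern))]


def pattern_matches(pattern: str, seq: str) -> bool:
    return len(pattern) == len(seq) and all(
        b in IUPAC_SETS[s] for s, b in zip(pattern, seq)
    )


def brute_force_scan(
    sequences: dict[str, str],
    spacer: str,
    pam_pattern: str = "TTTN",
    max_mismatches: int = 4,
) -> set[tuple]:
    """Position-by-position scan for PAM+spacer sites on both strands.

    Returns a set of (chrom, start, end, strand, pam, protospacer, n_mm)
    tuples in forward BED coordinates, for comparison against the scanner.
    """
    pl, sl = len(pam_pattern), len(spacer)
    width = pl + sl
    found = set()
    for chrom, seq in sequences.items():
        seq = seq.upper()
        for strand in "+-":
            s = seq if strand == "+" else rc(seq)
            for i in range(len(s) - width + 1):
                window = s[i : i + width]
                if "N" in window:
                    continue
                if not pattern_matches(pam_pattern, window[:pl]):
                    continue
                mm = sum(a != b for a, b in zip(window[pl:], spacer))
                if mm > max_mismatches:
                    continue
                if strand == "+":
                    start = i
                else:
                    start = len(s) - i - width
                found.add(
                    (chrom, start, start + width, strand, window[:pl],
                     window[pl:], mm)
                )
    return found


def brute_force_density(sequences: dict[str, str], pattern: str) -> int:
    """Count pattern windows on both strands, skipping windows with N."""
    total = 0
    w = len(pattern)
    for seq in sequences.values():
        for s in (seq.upper(), rc(seq.upper())):
            for i in range(len(s) - w + 1):
                window = s[i : i + w]
                if "N" not in window and pattern_matches(pattern, window):
                    total += 1
    return total
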