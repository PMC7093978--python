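"""Editing quantification: amplicon percent-modified, the T7E1 band
formula, and on/off-target specificity ratios.

Percent modified is the fraction of reads whose global alignment to the
wild-type amplicon contains at least one insertion or deletion overlapping
a window around the Cas12a cut site. Cas12a cleaves with a staggered cut
leaving 4-5 nt 5' overhangs distal to the PAM, so the window is centred at
protospacer position 19 (counting the PAM-proximal base as position 1)
with a default half-width of 10 bp. Substitutions never count as edits.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Iterable, Literal

from Bio import Align

from .pam import reverse_complement

__all__ = [
    "BandIntensities",
    "IndelCall",
    "t7e1_percent",
    "percent_modified",
    "specificity_ratio",
    "DEFAULT_CUT_OFFSET",
]

#: Protospacer coordinate of the cut centre, PAM-proximal base = position 1.
DEFAULT_CUT_OFFSET = 19


@dataclass(frozen=True)
class BandIntensities:
    """T7E1 gel band intensities: a = undigested, b and c = cleavage products."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("band intensities must be nonnegative")
        if self.a + self.b + self.c <= 0:
            raise ValueError("total band intensity must be positive")


def t7e1_percent(
    bands: BandIntensities,
    variant: Literal["corrected", "as_printed"] = "corrected",
) -> float:
    """Indel percentage from T7E1 band intensities.

    ``"corrected"`` (default) is the standard estimator
    100 * (1 - sqrt(1 - (b+c)/(a+b+c))), which is 0 with no cleavage
    product and 100 at complete digestion. ``"as_printed"`` computes
    100 * (1 - sqrt(b+c)/(a+b+c)) literally; note that form returns 100%
    when b = c = 0, an anomaly of the printed formula kept for
    reproducibility.
    """
    total = bands.a + bands.b + bands.c
    cut_fraction = (bands.b + bands.c) / total
    if variant == "corrected":
        return 100.0 * (1.0 - sqrt(1.0 - cut_fraction))
    if variant == "as_printed":
        return 100.0 * (1.0 - sqrt(bands.b + bands.c) / total)
    raise ValueError(f"unknown variant {variant!r}")


@dataclass(frozen=True)
class IndelCall:
    """Indel quantification at one amplicon locus."""

    site: str
    reads_total: int
    reads_with_indel: int
    reads_unaligned: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.reads_with_indel <= self.reads_total:
            raise ValueError("reads_with_indel must be within [0, reads_total]")

    @property
    def percent_modified(self) -> float:
        if self.reads_total == 0:
            return float("nan")
        return 100.0 * self.reads_with_indel / self.reads_total


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.0
    # free end gaps on the read: partial reference coverage is tolerated
    try:
        aligner.end_deletion_score = 0.0
    except AttributeError:  # Biopython < 1.86 name
        aligner.query_end_gap_score = 0.0
    return aligner


def _alignment_indels(alignment) -> list[tuple[int, int]]:
    """Internal indels as reference-coordinate footprints [start, end).

    Deletions have end > start; insertions are zero-length points.
    """
    t_blocks, q_blocks = alignment.aligned
    out: list[tuple[int, int]] = []
    for (t_end, q_end), (t_next, q_next) in zip(
        zip(t_blocks[:-1, 1], q_blocks[:-1, 1]),
        zip(t_blocks[1:, 0], q_blocks[1:, 0]),
    ):
        if t_next > t_end:  # deletion in the read
            out.append((int(t_end), int(t_next)))
        if q_next > q_end:  # insertion in the read
            out.append((int(t_end), int(t_end)))
    return out


def percent_modified(
    reads: Iterable[tuple[str, str, str] | str],
    reference: str,
    protospacer: str,
    window_halfwidth: int = 10,
    cut_offset: int = DEFAULT_CUT_OFFSET,
    min_score_fraction: float = 0.5,
    site: str = "site",
) -> IndelCall:
    """Count reads whose alignment has an indel inside the cut window.

    Each read is aligned to the wild-type reference (match +1, mismatch -1,
    gap open -4, gap extend -1, free end gaps on the read). A read is
    modified iff any insertion or deletion footprint intersects
    [cut - w, cut + w] on the reference, where cut is the protospacer
    position ``cut_offset`` from the PAM-proximal end. Reads scoring below
    ``min_score_fraction`` of a perfect match are discarded and excluded
    from the denominator. The protospacer must occur exactly once in the
    reference (either strand).
    """
    ref = reference.upper()
    fwd = ref.count(protospacer)
    rev = ref.count(reverse_complement(protospacer))
    if fwd + rev != 1:
        raise ValueError(
            f"protospacer must occur exactly once in the reference "
            f"(found {fwd} forward, {rev} reverse)"
        )
    if fwd:
        start = ref.index(protospacer)
        cut = start + cut_offset
    else:
        start = ref.index(reverse_complement(protospacer))
        cut = start + len(protospacer) - cut_offset
    lo, hi = cut - window_halfwidth, cut + window_halfwidth

    aligner = _make_aligner()
    total = modified = unaligned = 0
    for read in reads:
        seq = read if isinstance(read, str) else read[1]
        alignments = aligner.align(ref, seq.upper())
        best = alignments[0]
        if best.score < min_score_fraction * len(seq):
            unaligned += 1
            continue
        total += 1
        for ds, de in _alignment_indels(best):
            intersects = (ds <= hi and de > lo) if de > ds else (lo <= ds <= hi)
            if intersects:
                modified += 1
                break
    return IndelCall(
        site=site,
        reads_total=total,
        reads_with_indel=modified,
        reads_unaligned=unaligned,
    )


def specificity_ratio(off_target_pct: float, on_target_pct: float) -> float:
    """Off-target activity divided by on-target activity (dimensionless)."""
    if on_target_pct <= 0:
        raise ValueError("on-target percent must be positive")
    if off_target_pct < 0:
        raise ValueError("off-target percent must be nonnegative")
    return off_target_pct / on_target_pct
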