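"""FASTQ -> per-sample PAM count/frequency tables.

Each library read carries 4 randomized PAM bases immediately 5' of a fixed
23-nt protospacer. Processing anchors on the protospacer (exact match, on
either strand), extracts the 4 preceding bases in PAM-strand orientation,
applies the Phred >= 30 filter to those 4 bases only, and tallies counts
over all 256 PAMs. Frequencies are counts normalized to the total reads
passing all filters in the sample.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .pam import PAM_LENGTH, enumerate_pams, reverse_complement

__all__ = [
    "PamCountTable",
    "EmptyTableError",
    "DISCARD_REASONS",
    "read_fastq",
    "locate_pam",
    "extract_pam",
    "count_pams",
]

#: Reasons a read can be excluded from the tally.
DISCARD_REASONS = (
    "no_anchor",
    "ambiguous_anchor",
    "short_flank",
    "low_quality",
    "pam_ambiguous",
)


class EmptyTableError(ValueError):
    """Raised when no read in a sample yields a usable PAM."""


@dataclass
class PamCountTable:
    """Per-sample PAM counts over all 256 4-mers plus discard accounting."""

    sample_id: str
    counts: dict[str, int]
    total_reads_used: int
    discards: dict[str, int] = field(default_factory=dict)

    @property
    def frequencies(self) -> dict[str, float]:
        if self.total_reads_used <= 0:
            return {p: 0.0 for p in self.counts}
        return {p: c / self.total_reads_used for p, c in self.counts.items()}

    @property
    def total_discarded(self) -> int:
        return sum(self.discards.values())

    def to_frame(self) -> pd.DataFrame:
        pams = enumerate_pams(PAM_LENGTH)
        freq = self.frequencies
        return pd.DataFrame(
            {
                "count": [self.counts[p] for p in pams],
                "frequency": [freq[p] for p in pams],
            },
            index=pd.Index(pams, name="pam"),
        )

    @classmethod
    def from_counts(
        cls,
        sample_id: str,
        counts: dict[str, int],
        discards: dict[str, int] | None = None,
    ) -> "PamCountTable":
        full = {p: int(counts.get(p, 0)) for p in enumerate_pams(PAM_LENGTH)}
        return cls(
            sample_id=sample_id,
            counts=full,
            total_reads_used=sum(full.values()),
            discards=discards or {},
        )


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, phred33 quality string) from FASTQ(.gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield title.split()[0], seq.upper(), qual


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def locate_pam(
    sequence: str, anchor: str, rc_anchor: str | None = None,
    pam_length: int = PAM_LENGTH,
) -> tuple[str, list[int]] | str:
    """Locate the PAM 5' of the protospacer anchor on either strand.

    Returns ``(pam, quality_indices)`` where ``pam`` is in PAM-strand
    orientation and ``quality_indices`` index the 4 PAM bases within the
    read as given. On failure returns the discard reason string.
    """
    if rc_anchor is None:
        rc_anchor = reverse_complement(anchor)
    fwd = _find_all(sequence, anchor)
    rev = _find_all(sequence, rc_anchor)
    n = len(fwd) + len(rev)
    if n == 0:
        return "no_anchor"
    if n > 1:
        return "ambiguous_anchor"
    if fwd:
        i = fwd[0]
        if i < pam_length:
            return "short_flank"
        idx = list(range(i - pam_length, i))
        return sequence[i - pam_length : i], idx
    j = rev[0] + len(anchor)
    if j + pam_length > len(sequence):
        return "short_flank"
    idx = list(range(j, j + pam_length))
    return reverse_complement(sequence[j : j + pam_length]), idx


def extract_pam(sequence: str, anchor: str, pam_length: int = PAM_LENGTH) -> str | None:
    """The 4-mer PAM 5' of the anchor on either strand, or None."""
    result = locate_pam(sequence, anchor, pam_length=pam_length)
    return None if isinstance(result, str) else result[0]


def count_pams(
    reads: Iterable[tuple[str, str, str]],
    anchor: str,
    min_phred: int = 30,
    sample_id: str = "sample",
    pam_length: int = PAM_LENGTH,
) -> PamCountTable:
    """Extract, quality-filter, and tally PAMs from reads.

    ``reads`` yields (id, sequence, phred33 quality string) — the shape of
    :func:`read_fastq`. A read contributes iff the anchor occurs exactly
    once across both orientations, at least ``pam_length`` bases flank it
    5', every PAM base has Phred >= ``min_phred``, and no PAM base is
    ambiguous. Frequencies are normalized to the reads passing all filters.

    Raises :class:`EmptyTableError` if no read is usable.
    """
    rc_anchor = reverse_complement(anchor)
    qmin = chr(min_phred + 33)
    counts: dict[str, int] = {p: 0 for p in enumerate_pams(pam_length)}
    discards = {reason: 0 for reason in DISCARD_REASONS}
    used = 0
    for _rid, seq, qual in reads:
        located = locate_pam(seq, anchor, rc_anchor, pam_length)
        if isinstance(located, str):
            discards[located] += 1
            continue
        pam, idx = located
        if any(qual[i] < qmin for i in idx):
            discards["low_quality"] += 1
            continue
        if pam not in counts:  # contains N or other ambiguity
            discards["pam_ambiguous"] += 1
            continue
        counts[pam] += 1
        used += 1
    if used == 0:
        raise EmptyTableError(
            f"sample {sample_id!r}: no usable reads "
            f"(discards: { {k: v for k, v in discards.items() if v} })"
        )
    return PamCountTable(
        sample_id=sample_id, counts=counts, total_reads_used=used, discards=discards
    )
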