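"""PAM-aware genome scanning for candidate (off-)target sites, and
genome-wide PAM density.

A candidate site is a 4-mer PAM immediately 5' of a 23-mer protospacer on
either strand: the PAM must match an IUPAC pattern (default TTTN)
categorically, and the protospacer must be within a Hamming-distance
budget of the query spacer (mismatches counted in the spacer only). This
is the mismatch-only search mode of tools like Cas-OFFinder; bulges are
not modeled. Coordinates follow the BED convention: 0-based, half-open,
forward-strand intervals spanning PAM + protospacer as laid out on the
hit strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .pam import IUPAC, reverse_complement

__all__ = [
    "OffTargetHit",
    "PamDensityResult",
    "scan_genome",
    "pam_density",
    "hits_to_frame",
]


@dataclass(frozen=True)
class OffTargetHit:
    """One candidate target locus (BED-style forward coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str
    pam: str  # 5'->3' on the hit strand
    protospacer_seq: str  # 5'->3' on the hit strand
    n_mismatches: int


@dataclass(frozen=True)
class PamDensityResult:
    """Occurrence count of a PAM pattern on both strands of a genome."""

    n_occurrences: int
    genome_length: int  # non-N length used as the density denominator

    @property
    def mean_spacing(self) -> float | None:
        """Mean bp per occurrence; None when the pattern never occurs."""
        if self.n_occurrences == 0:
            return None
        return self.genome_length / self.n_occurrences


def _as_sequences(genome: Mapping[str, str] | str | Path) -> dict[str, str]:
    if isinstance(genome, Mapping):
        return {str(k): str(v).upper() for k, v in genome.items()}
    path = Path(genome)
    if path.exists():
        return {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
    # a bare sequence string
    return {"seq": str(genome).upper()}


def _pattern_mask(arr: np.ndarray, pattern: str, starts: int) -> np.ndarray:
    """Boolean over window start positions: pattern matches arr[i:i+len]."""
    ok = np.ones(starts, dtype=bool)
    for j, sym in enumerate(pattern):
        allowed = np.frombuffer("".join(sorted(IUPAC[sym])).encode(), np.uint8)
        ok &= np.isin(arr[j : j + starts], allowed)
    return ok


def _scan_strand(
    seq: str, chrom: str, strand: str, spacer: str, pam_pattern: str,
    max_mismatches: int,
) -> list[OffTargetHit]:
    """Scan one strand; ``seq`` is already the hit-strand 5'->3' sequence."""
    pl, sl = len(pam_pattern), len(spacer)
    width = pl + sl
    n = len(seq) - width + 1
    if n <= 0:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    pam_ok = _pattern_mask(arr, pam_pattern, n)
    spacer_bytes = np.frombuffer(spacer.encode("ascii"), dtype=np.uint8)
    mismatches = np.zeros(n, dtype=np.int32)
    has_n = np.zeros(n, dtype=bool)
    n_byte = ord("N")
    for j in range(sl):
        col = arr[pl + j : pl + j + n]
        mismatches += col != spacer_bytes[j]
        has_n |= col == n_byte
    candidate = pam_ok & ~has_n & (mismatches <= max_mismatches)
    hits = []
    for i in np.flatnonzero(candidate):
        i = int(i)
        if strand == "+":
            start, end = i, i + width
        else:
            start, end = len(seq) - i - width, len(seq) - i
        hits.append(
            OffTargetHit(
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                pam=seq[i : i + pl],
                protospacer_seq=seq[i + pl : i + width],
                n_mismatches=int(mismatches[i]),
            )
        )
    return hits


def scan_genome(
    genome: Mapping[str, str] | str | Path,
    spacer: str,
    pam_pattern: str = "TTTN",
    max_mismatches: int = 4,
    spacer_length: int = 23,
) -> list[OffTargetHit]:
    """Find every PAM+protospacer locus compatible with the query.

    ``genome`` may be a FASTA path, a {name: sequence} mapping, or a bare
    sequence. Windows containing N never match. Hits are sorted by
    (chrom, start, strand).
    """
    if len(spacer) != spacer_length:
        raise ValueError(
            f"spacer length {len(spacer)} != configured length {spacer_length}"
        )
    if any(b not in "ACGT" for b in spacer.upper()):
        raise ValueError("spacer must be unambiguous DNA")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    spacer = spacer.upper()
    hits: list[OffTargetHit] = []
    for chrom, seq in _as_sequences(genome).items():
        hits.extend(
            _scan_strand(seq, chrom, "+", spacer, pam_pattern, max_mismatches)
        )
        hits.extend(
            _scan_strand(
                reverse_complement(seq), chrom, "-", spacer, pam_pattern,
                max_mismatches,
            )
        )
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def pam_density(
    genome: Mapping[str, str] | str | Path, pam_pattern: str = "TTTN"
) -> PamDensityResult:
    """Count all (possibly overlapping) pattern occurrences on both strands.

    The denominator of the density is the total non-N genome length;
    windows containing N are skipped.
    """
    total = 0
    non_n_length = 0
    for _chrom, seq in _as_sequences(genome).items():
        if not seq:
            continue
        non_n_length += len(seq) - seq.count("N")
        for strand_seq in (seq, reverse_complement(seq)):
            w = len(pam_pattern)
            n = len(strand_seq) - w + 1
            if n <= 0:
                continue
            arr = np.frombuffer(strand_seq.encode("ascii"), dtype=np.uint8)
            ok = _pattern_mask(arr, pam_pattern, n)
            has_n = np.zeros(n, dtype=bool)
            n_byte = ord("N")
            for j in range(w):
                has_n |= arr[j : j + n] == n_byte
            total += int((ok & ~has_n).sum())
    if non_n_length == 0:
        raise ValueError("genome is empty")
    return PamDensityResult(n_occurrences=total, genome_length=non_n_length)


def hits_to_frame(hits: list[OffTargetHit]) -> pd.DataFrame:
    """BED6+ layout: chrom, start, end, name, score(=mismatches), strand, seq."""
    return pd.DataFrame(
        [
            {
                "chrom": h.chrom,
                "start": h.start,
                "end": h.end,
                "name": f"{h.pam}|{h.n_mismatches}mm",
                "score": h.n_mismatches,
                "strand": h.strand,
                "protospacer_seq": h.protospacer_seq,
            }
            for h in hits
        ],
        columns=["chrom", "start", "end", "name", "score", "strand", "protospacer_seq"],
    )
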