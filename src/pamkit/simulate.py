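"""Synthetic data generation for every pipeline stage.

Three generators with known ground truth:

* :func:`simulate_depletion_run` — a randomized-PAM-library cleavage time
  course: 150-bp substrates carrying 4 randomized PAM nucleotides 5' of a
  fixed 23-nt protospacer, sampled as 75-bp single-end reads at the nine
  quench times {0,1,2,4,6,8,10,16,32} min plus an uncleaved negative
  control. Each PAM's substrate pool decays as f0(p)*exp(-k(p)*t); reads
  are multinomial draws from the surviving pool with i.i.d. substitution
  errors and two-level Phred qualities.
* :func:`simulate_amplicon_reads` — amplicon reads with an exactly known
  fraction carrying a planted indel at the Cas12a cut site.
* :func:`simulate_genome` — an i.i.d. background genome with planted
  (spacer, PAM) target sites for scanner tests.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .pam import (
    PAM_LENGTH,
    VRRT_PATTERN,
    classify_pam,
    enumerate_pams,
    iupac_match,
    reverse_complement,
)

__all__ = [
    "DEFAULT_PROTOSPACER",
    "DEFAULT_TIME_GRID",
    "SubstrateLayout",
    "RateProfile",
    "SimulationConfig",
    "ReadSample",
    "DepletionRun",
    "IndelSpec",
    "AmpliconReads",
    "PlantedSite",
    "SimulatedGenome",
    "make_rate_profile",
    "simulate_depletion_run",
    "simulate_amplicon_reads",
    "simulate_genome",
]

#: Fixed 23-nt protospacer shared by all 256 substrates.
DEFAULT_PROTOSPACER = "CTGATGGTCCATGTCTGTTACTC"

#: Quench times of the cleavage time course, in minutes.
DEFAULT_TIME_GRID = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 16.0, 32.0)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP_LUT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_LUT[_a] = _b


@dataclass(frozen=True)
class SubstrateLayout:
    """Geometry of one library substrate: flank | PAM | protospacer | flank."""

    total_length: int = 150
    left_flank: int = 30
    protospacer: str = DEFAULT_PROTOSPACER
    pam_length: int = PAM_LENGTH

    @property
    def right_flank(self) -> int:
        return (
            self.total_length
            - self.left_flank
            - self.pam_length
            - len(self.protospacer)
        )

    @property
    def pam_start(self) -> int:
        return self.left_flank

    def __post_init__(self) -> None:
        if any(b not in "ACGT" for b in self.protospacer):
            raise ValueError("protospacer must be unambiguous DNA")
        if self.right_flank < 0:
            raise ValueError(
                "left_flank + pam_length + protospacer exceed total_length"
            )


@dataclass(frozen=True)
class RateProfile:
    """Cleavage rate constant k (per minute) for every 4-mer PAM."""

    k_by_pam: Mapping[str, float]
    preset: str = "custom"
    k_max: float = float("nan")

    def __post_init__(self) -> None:
        pams = enumerate_pams(PAM_LENGTH)
        missing = set(pams) - set(self.k_by_pam)
        if missing:
            raise ValueError(f"rate profile missing {len(missing)} PAMs")
        if any(v < 0 for v in self.k_by_pam.values()):
            raise ValueError("rate constants must be nonnegative")

    def as_series(self) -> pd.Series:
        pams = enumerate_pams(PAM_LENGTH)
        return pd.Series([self.k_by_pam[p] for p in pams], index=pams, name="k")


def make_rate_profile(
    preset: Literal["stringent", "permissive", "uniform"],
    k_max: float = 0.5,
    seed: int = 0,
) -> RateProfile:
    """Build a per-PAM rate-constant profile emulating ortholog behaviour.

    ``"stringent"`` mimics a nuclease with tight PAM recognition
    (CeCas12a-like): full rate at TTTV, ~10% at CTTV, near-zero elsewhere.
    ``"permissive"`` mimics a relaxed nuclease (LbCas12a/AsCas12a-like):
    full rate at TTTV, 20-40% at the single-C classes CTTV/TCTV/TTCV and
    ~10% at the double-C classes. ``"uniform"`` gives every non-VRRT PAM
    the same rate. In all presets the 12 VRRT PAMs have k = 0 exactly
    (the uncleavable null set).

    Unnamed-class PAMs receive a small log-uniform background rate in
    [0.02, 0.08]*k_max rather than exactly zero, so that the full 256-PAM
    rate spectrum is a graded, rank-recoverable surface (see methods note).
    """
    if k_max <= 0:
        raise ValueError("k_max must be positive")
    if preset not in ("stringent", "permissive", "uniform"):
        raise ValueError(f"unknown preset {preset!r}")
    rng = np.random.default_rng(seed)
    k: dict[str, float] = {}
    for pam in enumerate_pams(PAM_LENGTH):
        if iupac_match(VRRT_PATTERN, pam):
            k[pam] = 0.0
            continue
        cls = classify_pam(pam)
        background = float(
            np.exp(rng.uniform(np.log(0.02), np.log(0.08))) * k_max
        )
        if preset == "uniform":
            k[pam] = k_max
        elif preset == "stringent":
            if cls == "TTTV":
                k[pam] = k_max
            elif cls == "CTTV":
                k[pam] = 0.1 * k_max
            elif cls == "TTTT":
                k[pam] = 0.05 * k_max
            else:
                k[pam] = background
        else:  # permissive
            if cls == "TTTV":
                k[pam] = k_max
            elif cls in ("CTTV", "TCTV", "TTCV"):
                k[pam] = float(rng.uniform(0.2, 0.4) * k_max)
            elif cls in ("CCTV", "TCCV", "CCCV"):
                k[pam] = 0.1 * k_max
            elif cls == "TTTT":
                k[pam] = 0.2 * k_max
            else:
                k[pam] = background
    return RateProfile(k_by_pam=k, preset=preset, k_max=k_max)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one depletion-sequencing run."""

    layout: SubstrateLayout = field(default_factory=SubstrateLayout)
    profile: RateProfile | None = None
    time_grid: tuple[float, ...] = DEFAULT_TIME_GRID
    reads_per_sample: int = 100_000
    read_length: int = 75
    error_rate: float = 0.002
    phred_high: int = 37
    phred_low: int = 11
    low_quality_pam_fraction: float = 0.01
    reverse_fraction: float = 0.10
    control_alpha: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        grid = tuple(self.time_grid)
        if grid[0] != 0 or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("time grid must be strictly increasing and start at 0")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        if not 0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")
        needed = (
            self.layout.left_flank
            + self.layout.pam_length
            + len(self.layout.protospacer)
        )
        if self.read_length < needed:
            raise ValueError(
                f"read_length {self.read_length} too short to cover the PAM and "
                f"protospacer anchor (needs >= {needed})"
            )


@dataclass
class ReadSample:
    """One sequencing sample held as packed byte matrices."""

    name: str
    time: float | None  # None for the negative control
    seq: np.ndarray  # (n_reads, read_length) uint8 ASCII
    qual: np.ndarray  # (n_reads, read_length) uint8 Phred+33

    @property
    def n_reads(self) -> int:
        return self.seq.shape[0]

    def iter_reads(self) -> Iterator[tuple[str, str, str]]:
        """Yield (read_id, sequence, phred33_quality) tuples."""
        seq_bytes = self.seq.tobytes()
        qual_bytes = self.qual.tobytes()
        L = self.seq.shape[1]
        for i in range(self.n_reads):
            yield (
                f"{self.name}:{i}",
                seq_bytes[i * L : (i + 1) * L].decode("ascii"),
                qual_bytes[i * L : (i + 1) * L].decode("ascii"),
            )

    def write_fastq(self, path: str | Path) -> Path:
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as fh:
            for rid, seq, qual in self.iter_reads():
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
        return path


@dataclass
class DepletionRun:
    """Output of :func:`simulate_depletion_run`: samples plus ground truth.

    ``truth`` has one row per PAM with its rate constant ``k``, the control
    composition ``f0``, and the expected surviving frequency ``f_t<t>`` at
    every time point. ``sampled_counts`` holds the realized multinomial PAM
    tally per sample — the exact truth against which read counting can be
    checked.
    """

    config: SimulationConfig
    substrates: dict[str, str]
    control: ReadSample
    samples: dict[float, ReadSample]
    truth: pd.DataFrame
    sampled_counts: pd.DataFrame

    @property
    def anchor(self) -> str:
        return self.config.layout.protospacer

    def all_samples(self) -> list[ReadSample]:
        return [self.control] + [self.samples[t] for t in sorted(self.samples)]

    def write(self, outdir: str | Path, gzipped: bool = True) -> dict[str, Path]:
        """Write FASTQ per sample plus TSV truth tables; return the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ext = ".fastq.gz" if gzipped else ".fastq"
        paths: dict[str, Path] = {}
        for sample in self.all_samples():
            paths[sample.name] = sample.write_fastq(outdir / f"{sample.name}{ext}")
        truth_path = outdir / "truth.tsv"
        self.truth.to_csv(truth_path, sep="\t", index_label="pam")
        paths["truth"] = truth_path
        counts_path = outdir / "sampled_counts.tsv"
        self.sampled_counts.to_csv(counts_path, sep="\t", index_label="pam")
        paths["sampled_counts"] = counts_path
        return paths


def _draw_flanks(layout: SubstrateLayout, rng: np.random.Generator) -> tuple[str, str]:
    """Draw flank sequences such that the protospacer anchor occurs exactly
    once (forward) and never on the reverse strand, for every PAM choice."""
    anchor = layout.protospacer
    rc_anchor = reverse_complement(anchor)
    for _ in range(100):
        left = "".join(rng.choice(list("ACGT"), size=layout.left_flank))
        right = "".join(rng.choice(list("ACGT"), size=layout.right_flank))
        ok = all(
            (left + pam + anchor + right).count(anchor) == 1
            and rc_anchor not in (left + pam + anchor + right)
            for pam in enumerate_pams(layout.pam_length)
        )
        if ok:
            return left, right
    raise RuntimeError("could not draw anchor-unique flanks")  # pragma: no cover


def _substitution_errors(
    seq: np.ndarray, error_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Apply i.i.d. substitutions in place; return the boolean error mask."""
    if error_rate <= 0:
        return np.zeros(seq.shape, dtype=bool)
    mask = rng.random(seq.shape) < error_rate
    if mask.any():
        # replace with one of the three other bases, uniformly
        idx = np.searchsorted(_BASES, seq[mask])
        shift = rng.integers(1, 4, size=mask.sum())
        seq[mask] = _BASES[(idx + shift) % 4]
    return mask


def _build_sample(
    name: str,
    time: float | None,
    pam_counts: np.ndarray,
    substrates_arr: np.ndarray,
    layout: SubstrateLayout,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> ReadSample:
    n = int(pam_counts.sum())
    L = config.read_length
    pam_idx = np.repeat(np.arange(256), pam_counts)
    rng.shuffle(pam_idx)
    seq = substrates_arr[pam_idx, :L].copy()
    err = _substitution_errors(seq, config.error_rate, rng)
    qual = np.full(seq.shape, config.phred_high + 33, dtype=np.uint8)
    qual[err] = config.phred_low + 33
    # a small fraction of reads carries one low-quality (but correct) PAM base,
    # to exercise the downstream Phred filter
    if config.low_quality_pam_fraction > 0:
        dip = rng.random(n) < config.low_quality_pam_fraction
        pos = layout.pam_start + rng.integers(0, layout.pam_length, size=n)
        qual[dip, pos[dip]] = config.phred_low + 33
    # a fraction of reads is reported on the opposite strand
    if config.reverse_fraction > 0:
        rev = rng.random(n) < config.reverse_fraction
        seq[rev] = _COMP_LUT[seq[rev][:, ::-1]]
        qual[rev] = qual[rev][:, ::-1]
    return ReadSample(name=name, time=time, seq=seq, qual=qual)


def simulate_depletion_run(config: SimulationConfig | None = None) -> DepletionRun:
    """Simulate a full PAM-library cleavage time course.

    The negative-control composition ``f0`` is drawn once from a symmetric
    Dirichlet (near-uniform). At quench time t the surviving pool has PAM p
    at expected frequency f0(p)*exp(-k(p)*t) / Z(t); each sample is a
    multinomial draw of ``reads_per_sample`` reads from its pool. Identical
    configs (same seed) produce byte-identical output.
    """
    config = config or SimulationConfig()
    if config.profile is None:
        config = replace(config, profile=make_rate_profile("stringent", seed=config.seed))
    layout = config.layout
    rng = np.random.default_rng(config.seed)
    pams = enumerate_pams(layout.pam_length)
    left, right = _draw_flanks(layout, rng)
    substrates = {p: left + p + layout.protospacer + right for p in pams}
    substrates_arr = np.frombuffer(
        "".join(substrates[p] for p in pams).encode("ascii"), dtype=np.uint8
    ).reshape(len(pams), layout.total_length).copy()

    k = config.profile.as_series().to_numpy()
    f0 = rng.dirichlet(np.full(len(pams), config.control_alpha))
    truth = pd.DataFrame({"k": k, "f0": f0}, index=pd.Index(pams, name="pam"))

    counts: dict[str, np.ndarray] = {}
    counts["control"] = rng.multinomial(config.reads_per_sample, f0)
    control = _build_sample(
        "control", None, counts["control"], substrates_arr, layout, config, rng
    )
    samples: dict[float, ReadSample] = {}
    for t in config.time_grid:
        surviving = f0 * np.exp(-k * t)
        f_t = surviving / surviving.sum()
        truth[f"f_t{t:g}"] = f_t
        name = f"t{t:g}min"
        counts[name] = rng.multinomial(config.reads_per_sample, f_t)
        samples[float(t)] = _build_sample(
            name, float(t), counts[name], substrates_arr, layout, config, rng
        )
    sampled_counts = pd.DataFrame(counts, index=pd.Index(pams, name="pam"))
    return DepletionRun(
        config=config,
        substrates=substrates,
        control=control,
        samples=samples,
        truth=truth,
        sampled_counts=sampled_counts,
    )


@dataclass(frozen=True)
class IndelSpec:
    """A planted indel, positioned relative to the Cas12a cut site.

    ``offset`` shifts the indel from the default cut coordinate
    (protospacer position 19 from the PAM-proximal end, i.e. within the
    PAM-distal staggered-cut region). ``kind`` is "deletion" or "insertion".
    """

    size: int = 4
    kind: Literal["deletion", "insertion"] = "deletion"
    offset: int = 0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("indel size must be >= 1")
        if self.kind not in ("deletion", "insertion"):
            raise ValueError(f"unknown indel kind {self.kind!r}")


@dataclass
class AmpliconReads:
    """Simulated amplicon reads plus per-read ground-truth edit labels."""

    reads: list[tuple[str, str, str]]  # (id, sequence, phred33 quality)
    edited: np.ndarray  # bool per read
    reference: str
    edited_reference: str
    cut_position: int

    @property
    def n_edited(self) -> int:
        return int(self.edited.sum())

    def write_fastq(self, path: str | Path) -> Path:
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as fh:
            for rid, seq, qual in self.reads:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
        return path


def simulate_amplicon_reads(
    reference: str,
    protospacer: str,
    indel_fraction: float,
    indel: IndelSpec = IndelSpec(),
    n_reads: int = 1000,
    error_rate: float = 0.001,
    seed: int = 0,
    phred_high: int = 37,
    phred_low: int = 11,
    cut_offset: int = 19,
) -> AmpliconReads:
    """Simulate amplicon sequencing of an edited locus.

    Exactly ``round(n_reads * indel_fraction)`` reads carry the planted
    indel; the rest are wild type apart from substitution errors. The indel
    is placed at ``cut_offset`` bases from the PAM-proximal protospacer end
    (default 19, the Cas12a staggered-cut region) plus ``indel.offset``.
    """
    if not 0 <= indel_fraction <= 1:
        raise ValueError("indel_fraction must be in [0, 1]")
    ref = reference.upper()
    if ref.count(protospacer) != 1:
        raise ValueError("protospacer must occur exactly once in the reference")
    rng = np.random.default_rng(seed)
    proto_start = ref.index(protospacer)
    cut = proto_start + cut_offset
    pos = cut + indel.offset
    if indel.kind == "deletion":
        if pos < 0 or pos + indel.size > len(ref):
            raise ValueError("indel extends outside the reference")
        edited_ref = ref[:pos] + ref[pos + indel.size :]
    else:
        if pos < 0 or pos > len(ref):
            raise ValueError("indel position outside the reference")
        ins = "".join(rng.choice(list("ACGT"), size=indel.size))
        edited_ref = ref[:pos] + ins + ref[pos:]

    n_edit = round(n_reads * indel_fraction)
    labels = np.zeros(n_reads, dtype=bool)
    labels[rng.permutation(n_reads)[:n_edit]] = True

    reads: list[tuple[str, str, str]] = []
    for i, is_edit in enumerate(labels):
        template = edited_ref if is_edit else ref
        arr = np.frombuffer(template.encode("ascii"), dtype=np.uint8).copy()
        err = _substitution_errors(arr, error_rate, rng)
        qual = np.full(arr.shape, phred_high + 33, dtype=np.uint8)
        qual[err] = phred_low + 33
        tag = "edit" if is_edit else "wt"
        reads.append(
            (f"amplicon:{i}:{tag}", arr.tobytes().decode("ascii"),
             qual.tobytes().decode("ascii"))
        )
    return AmpliconReads(
        reads=reads,
        edited=labels,
        reference=ref,
        edited_reference=edited_ref,
        cut_position=cut,
    )


@dataclass(frozen=True)
class PlantedSite:
    """A target site to overwrite into a simulated genome.

    The site occupies PAM (4 nt) immediately 5' of the 23-nt protospacer on
    the requested strand. ``n_mismatches`` spacer positions are mutated away
    from the query spacer. ``position`` is the forward-strand start of the
    full PAM+protospacer window; if None, sites are placed evenly.
    """

    spacer: str
    pam: str
    strand: Literal["+", "-"] = "+"
    n_mismatches: int = 0
    position: int | None = None


@dataclass
class SimulatedGenome:
    """An i.i.d. background genome with planted sites and their manifest."""

    sequences: dict[str, str]
    manifest: pd.DataFrame

    def write_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        return path


def simulate_genome(
    length: int,
    planted_sites: Sequence[PlantedSite] = (),
    base_probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    chrom: str = "chr1",
) -> SimulatedGenome:
    """Generate a background genome and plant target sites at known loci."""
    probs = np.asarray(base_probs, dtype=float)
    if probs.shape != (4,) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("base_probs must be 4 probabilities summing to 1")
    rng = np.random.default_rng(seed)
    genome = rng.choice(list("ACGT"), size=length, p=probs)

    site_len = None
    records = []
    occupied: list[tuple[int, int]] = []
    n_sites = len(planted_sites)
    for i, site in enumerate(planted_sites):
        site_len = len(site.pam) + len(site.spacer)
        if site.position is not None:
            start = site.position
        else:
            start = (i + 1) * length // (n_sites + 1)
        end = start + site_len
        if start < 0 or end > length:
            raise ValueError("planted site does not fit within the genome")
        if any(s < end and start < e for s, e in occupied):
            raise ValueError("planted sites overlap")
        occupied.append((start, end))
        spacer = list(site.spacer)
        if site.n_mismatches:
            if site.n_mismatches > len(spacer):
                raise ValueError("more mismatches than spacer positions")
            mpos = rng.choice(len(spacer), size=site.n_mismatches, replace=False)
            for p in mpos:
                choices = [b for b in "ACGT" if b != spacer[p]]
                spacer[p] = choices[rng.integers(0, 3)]
        hit_strand_seq = site.pam + "".join(spacer)
        fwd = hit_strand_seq if site.strand == "+" else reverse_complement(hit_strand_seq)
        genome[start:end] = list(fwd)
        records.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": site.strand,
                "pam": site.pam,
                "protospacer_seq": "".join(spacer),
                "n_mismatches": site.n_mismatches,
            }
        )
    manifest = pd.DataFrame(
        records,
        columns=[
            "chrom", "start", "end", "strand", "pam", "protospacer_seq",
            "n_mismatches",
        ],
    )
    return SimulatedGenome(sequences={chrom: "".join(genome)}, manifest=manifest)
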