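"""Seeded synthetic data: genome, contigs, error-prone long reads, truth.

The generator emulates the standard hybrid-assembly benchmark setup at
desk scale: a random genome (optionally with planted tandem repeats), a
contig set obtained by cutting gap intervals out of that genome (as if a
short-read assembler had broken at those points), and long reads sampled
from either strand at a chosen coverage with independent per-base
substitution/insertion/deletion errors. Everything is reproducible from
the seed. The ground truth (contig intervals, true adjacencies with gap
lengths and gap sequences, read origins) supports parameter-recovery
tests: on error-free reads the pipeline must rediscover every
read-spanned adjacency with the exact gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .io import SeqRecord, write_fasta, write_fastq

__all__ = [
    "SimConfig",
    "Adjacency",
    "ReadOrigin",
    "TruthSet",
    "simulate_instance",
    "write_instance",
    "spanning_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic instance.

    Defaults describe a small but realistic desk-scale scenario: a 100 kb
    genome broken at 4 points with sub-kilobase gaps, covered 10-fold by
    reads of ~6 kb — long enough that reads regularly span whole gaps.
    """

    genome_length: int = 100_000
    n_gaps: int = 4
    gap_length_range: Tuple[int, int] = (100, 500)
    read_length_mean: int = 6000
    read_length_spread: int = 1000
    coverage: float = 10.0
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    repeat_spec: Optional[Sequence[Tuple[int, float]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            r = getattr(self, name)
            if not (0.0 <= r < 1.0):
                raise ValueError(f"{name} must lie in [0, 1), got {r}")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.genome_length <= self.read_length_mean:
            raise ValueError("genome_length must exceed read_length_mean")
        lo, hi = self.gap_length_range
        if not (0 < lo <= hi):
            raise ValueError("gap_length_range must satisfy 0 < min <= max")
        if self.n_gaps < 0:
            raise ValueError("n_gaps must be >= 0")
        # each of the n_gaps+1 contigs needs room besides its gap
        if self.n_gaps and self.genome_length // self.n_gaps < 2 * hi + 4:
            raise ValueError(
                "gaps do not fit: genome_length too small for n_gaps of "
                "up to {} bp".format(hi)
            )


@dataclass(frozen=True)
class Adjacency:
    """A true neighbouring contig pair with the gap between them."""

    left_id: str
    right_id: str
    gap_start: int  # genome coords, half-open
    gap_end: int
    gap_sequence: str

    @property
    def gap_length(self) -> int:
        return self.gap_end - self.gap_start


@dataclass(frozen=True)
class ReadOrigin:
    """Where a simulated read came from (genome coords, half-open)."""

    read_id: str
    start: int
    end: int
    strand: int  # +1 forward, -1 reverse complement


@dataclass
class TruthSet:
    """Ground truth of a simulated instance."""

    genome: str
    contig_intervals: List[Tuple[str, int, int]] = field(default_factory=list)
    adjacencies: List[Adjacency] = field(default_factory=list)
    read_origins: List[ReadOrigin] = field(default_factory=list)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _apply_errors(
    codes: np.ndarray, rng: np.random.Generator,
    sub: float, ins: float, dele: float,
) -> np.ndarray:
    """Independent per-base errors: deletions skip, substitutions replace
    with a uniformly chosen different base, insertions add a uniform base."""
    if dele > 0:
        codes = codes[rng.random(codes.size) >= dele]
    if sub > 0:
        mask = rng.random(codes.size) < sub
        n = int(mask.sum())
        if n:
            codes = codes.copy()
            codes[mask] = (codes[mask] + rng.integers(1, 4, n)) % 4
    if ins > 0:
        mask = rng.random(codes.size) < ins
        n = int(mask.sum())
        if n:
            codes = np.insert(
                codes, np.nonzero(mask)[0] + 1,
                rng.integers(0, 4, n).astype(codes.dtype),
            )
    return codes


def simulate_instance(
    config: SimConfig,
) -> Tuple[List[SeqRecord], List[SeqRecord], TruthSet]:
    """Generate (contigs, reads, truth) for one seeded instance.

    The genome is uniform over {A,C,G,T} with any requested tandem
    repeats planted at random positions. Gap intervals are placed one per
    equal-width genome segment (away from segment edges), so the layout is
    always feasible and contigs keep substantial length. Reads take a
    truncated-normal length (min 200 bp), a uniform start, and a uniform
    strand; errors are applied per base.
    """
    rng = np.random.default_rng(config.seed)
    G = config.genome_length
    genome = rng.integers(0, 4, G, dtype=np.int8)

    if config.repeat_spec:
        for motif_len, copies in config.repeat_spec:
            motif = rng.integers(0, 4, int(motif_len), dtype=np.int8)
            total = int(round(motif_len * copies))
            tile = np.tile(motif, int(np.ceil(total / motif_len)))[:total]
            pos = int(rng.integers(0, G - total + 1))
            genome[pos : pos + total] = tile

    # one gap per equal-width segment, away from the segment edges
    gaps: List[Tuple[int, int]] = []
    if config.n_gaps:
        seg = G // config.n_gaps
        lo_len, hi_len = config.gap_length_range
        for i in range(config.n_gaps):
            glen = int(rng.integers(lo_len, hi_len + 1))
            margin = max(seg // 4, 1)
            lo = i * seg + margin
            hi = (i + 1) * seg - margin - glen
            pos = int(rng.integers(lo, max(hi, lo + 1)))
            gaps.append((pos, pos + glen))

    genome_str = _codes_to_str(genome.astype(np.uint8) & 3)

    truth = TruthSet(genome=genome_str)
    contigs: List[SeqRecord] = []
    bounds = [0] + [b for g in gaps for b in g] + [G]
    idx = 0
    for i in range(0, len(bounds), 2):
        start, end = bounds[i], bounds[i + 1]
        idx += 1
        cid = f"contig_{idx}"
        contigs.append(
            SeqRecord(id=cid, sequence=genome_str[start:end], source="contig")
        )
        truth.contig_intervals.append((cid, start, end))
    for j, (gs, ge) in enumerate(gaps):
        truth.adjacencies.append(
            Adjacency(
                left_id=f"contig_{j + 1}",
                right_id=f"contig_{j + 2}",
                gap_start=gs,
                gap_end=ge,
                gap_sequence=genome_str[gs:ge],
            )
        )

    n_reads = int(round(config.coverage * G / config.read_length_mean))
    reads: List[SeqRecord] = []
    for i in range(n_reads):
        length = int(
            np.clip(
                rng.normal(config.read_length_mean, config.read_length_spread),
                200, G,
            )
        )
        start = int(rng.integers(0, G - length + 1))
        strand = 1 if rng.integers(0, 2) == 0 else -1
        frag = genome[start : start + length].astype(np.int8)
        if strand == -1:
            frag = (3 - frag)[::-1]
        frag = _apply_errors(
            frag, rng, config.sub_rate, config.ins_rate, config.del_rate
        )
        rid = f"read_{i:05d}"
        reads.append(
            SeqRecord(
                id=rid,
                sequence=_codes_to_str(frag.astype(np.uint8) & 3),
                source="read",
            )
        )
        truth.read_origins.append(ReadOrigin(rid, start, start + length, strand))
    return contigs, reads, truth


def spanning_reads(
    truth: TruthSet, adjacency: Adjacency, k: int, d: int, t: int
) -> List[str]:
    """Reads that, if error-free, must yield at least one linking pair for
    the given true adjacency.

    A read spans the junction iff some genome position ``y`` exists with
    the first k-mer ``[y, y+k)`` inside the left contig, the second
    ``[y+d, y+d+k)`` inside the right contig, both inside the read, and
    ``y`` on the read's t-grid (which differs between strands).
    """
    left = next(iv for iv in truth.contig_intervals if iv[0] == adjacency.left_id)
    right = next(iv for iv in truth.contig_intervals if iv[0] == adjacency.right_id)
    _, ls, le = left
    _, rs, re = right
    out: List[str] = []
    for ro in truth.read_origins:
        s, e = ro.start, ro.end
        lo = max(ls, s, rs - d)
        hi = min(le - k, e - d - k, re - d - k)
        if hi < lo:
            continue
        if ro.strand == 1:
            # pair starts at read offset y - s, must be a multiple of t
            first = s + ((lo - s + t - 1) // t) * t
        else:
            # read offset is e - (y + d + k); multiples of t from the e end
            rem = (e - (lo + d + k)) % t
            first = lo + rem
        if first <= hi:
            out.append(ro.read_id)
    return out


def write_instance(
    contigs: List[SeqRecord],
    reads: List[SeqRecord],
    truth: TruthSet,
    prefix: Union[str, Path],
) -> None:
    """Write genome/contigs/reads/truth files for a simulated instance."""
    prefix = str(prefix)
    write_fasta(
        [SeqRecord(id="genome", sequence=truth.genome, source="contig")],
        prefix + ".genome.fasta",
    )
    write_fasta(contigs, prefix + ".contigs.fasta")
    write_fastq(reads, prefix + ".reads.fastq")
    with open(prefix + ".truth.tsv", "wt") as out:
        out.write("# type\tid\tstart\tend\textra\n")
        for cid, s, e in truth.contig_intervals:
            out.write(f"contig\t{cid}\t{s}\t{e}\t.\n")
        for adj in truth.adjacencies:
            out.write(
                f"adjacency\t{adj.left_id}>{adj.right_id}\t{adj.gap_start}\t"
                f"{adj.gap_end}\t{adj.gap_sequence}\n"
            )
        for ro in truth.read_origins:
            strand = "+" if ro.strand == 1 else "-"
            out.write(f"read\t{ro.read_id}\t{ro.start}\t{ro.end}\t{strand}\n")
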