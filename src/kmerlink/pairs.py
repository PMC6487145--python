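"""Paired k-mer generation from long reads, filtering, and mapping.

From every long read, k-mer pairs are taken at a fixed start-to-start
distance ``d``, sliding by ``t`` bases. A pair survives filtering iff both
k-mers pass the Bloom filter, both are unique in the contig set, and their
unique occurrences lie on two *different* contigs — such a pair is direct
evidence that the read bridges the two contigs.

Reads are scanned forward only; the strand of each contig relative to the
read is recovered at lookup time through canonical k-mer keys.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

from .index import BloomFilter, KmerOccurrence, UniqueKmerMap, canonical_kmer
from .io import SeqRecord
from .params import Parameters

__all__ = ["KmerPair", "LinkObservation", "generate_pairs", "filter_and_map"]


@dataclass(frozen=True)
class KmerPair:
    """Two k-mers taken from one read, starts exactly ``d`` apart."""

    read_id: str
    start1: int  # 0-based start of the first k-mer on the read
    k1: str
    k2: str


@dataclass(frozen=True)
class LinkObservation:
    """A k-mer pair resolved to unique positions on two distinct contigs.

    ``rel1``/``rel2`` give each contig's orientation relative to the read
    (+1: contig forward strand matches the read; -1: the contig occurs
    reverse-complemented in the read). ``oriented_offset1/2`` are the k-mer
    start offsets re-expressed in that read-frame orientation of the contig
    (``o' = o`` for +1, ``o' = L - k - o`` for -1).

    ``gap`` is this pair's estimate of the distance between the end of the
    first contig and the start of the second, in read order:
    ``d - (L1 - o1') - o2'`` (negative means overlap). ``left_end_in_read``
    is the read coordinate where the first contig ends, used to locate the
    gap fragment on the read.
    """

    pair: KmerPair
    occ1: KmerOccurrence
    occ2: KmerOccurrence
    rel1: int
    rel2: int
    oriented_offset1: int
    oriented_offset2: int
    gap: int
    left_end_in_read: int


def generate_pairs(read: SeqRecord, params: Parameters) -> List[KmerPair]:
    """Generate k-mer pairs from a read at starts 0, t, 2t, ...

    A start position is admissible while ``start + d + k <= len(read)``.
    Pairs whose k-mers contain ``N`` are skipped. Reads shorter than
    ``d + k`` yield an empty list.
    """
    k, d, t = params.k, params.d, params.t
    seq = read.sequence
    last = len(seq) - d - k
    pairs: List[KmerPair] = []
    for start in range(0, last + 1, t):
        k1 = seq[start : start + k]
        k2 = seq[start + d : start + d + k]
        if "N" in k1 or "N" in k2:
            continue
        pairs.append(KmerPair(read.id, start, k1, k2))
    return pairs


def filter_and_map(
    pairs: List[KmerPair],
    bloom: BloomFilter,
    unique_map: UniqueKmerMap,
    params: Parameters,
) -> List[LinkObservation]:
    """Filter pairs through the Bloom filter and uniqueness map and resolve
    survivors to contig positions, preserving read order.

    A pair survives iff both k-mers pass the Bloom filter, both are unique
    in the contig set, and the two occurrences lie on distinct contigs.
    Bloom false positives are harmless: the uniqueness map performs an
    exact check immediately after, so the survivors are exact.
    """
    obs, _, _, _ = _filter_stages(pairs, bloom, unique_map, params)
    return obs


def _filter_stages(
    pairs: List[KmerPair],
    bloom: BloomFilter,
    unique_map: UniqueKmerMap,
    params: Parameters,
) -> Tuple[List[LinkObservation], int, int, int]:
    k, d = params.k, params.d
    lengths = unique_map.contig_lengths
    out: List[LinkObservation] = []
    n_bloom = 0
    n_unique = 0
    n_same = 0
    for pair in pairs:
        c1, s1 = canonical_kmer(pair.k1)
        c2, s2 = canonical_kmer(pair.k2)
        if c1 not in bloom or c2 not in bloom:
            continue
        n_bloom += 1
        occ1 = unique_map.get(c1)
        occ2 = unique_map.get(c2)
        if occ1 is None or occ2 is None:
            continue
        n_unique += 1
        if occ1.contig_id == occ2.contig_id:
            n_same += 1
            continue
        rel1 = s1 * occ1.strand
        rel2 = s2 * occ2.strand
        L1 = lengths[occ1.contig_id]
        L2 = lengths[occ2.contig_id]
        oo1 = occ1.offset if rel1 == 1 else L1 - k - occ1.offset
        oo2 = occ2.offset if rel2 == 1 else L2 - k - occ2.offset
        gap = d - (L1 - oo1) - oo2
        left_end = pair.start1 + (L1 - oo1)
        out.append(
            LinkObservation(
                pair=pair,
                occ1=occ1,
                occ2=occ2,
                rel1=rel1,
                rel2=rel2,
                oriented_offset1=oo1,
                oriented_offset2=oo2,
                gap=gap,
                left_end_in_read=left_end,
            )
        )
    return out, n_bloom, n_unique, n_same
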