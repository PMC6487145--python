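"""Contig k-spectrum index.

Two structures are built from the input contigs:

* a Bloom filter holding every canonical k-mer of every contig, used as a
  fast prefilter for read k-mers (no false negatives; false positives are
  harmless because an exact map is consulted next);
* a unique-k-mer map: for every canonical k-mer occurring exactly once in
  the whole contig set (both strands collapsed by canonicalization), its
  single position. K-mers occurring more than once are repeats and carry no
  unambiguous positional signal, so they are dropped from linking.

Only the contig spectrum is counted exactly (a hash table), never the much
larger read spectrum — this is what keeps memory modest.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

import numpy as np

from .io import SeqRecord, _rc
from .params import Parameters

__all__ = [
    "BloomFilter",
    "KmerOccurrence",
    "UniqueKmerMap",
    "canonical_kmer",
    "build_index",
]

_BIT_MASKS = np.array([1, 2, 4, 8, 16, 32, 64, 128], dtype=np.uint8)


def canonical_kmer(s: str) -> Tuple[str, int]:
    """Return the canonical form of a k-mer and its strand flag.

    The canonical form is the lexicographic minimum of ``s`` and its
    reverse complement; the strand flag is ``+1`` if ``s`` itself is
    canonical, ``-1`` otherwise. With odd k a k-mer never equals its own
    reverse complement, so the flag is well defined.
    """
    if not s:
        raise ValueError("empty k-mer")
    if "N" in s:
        raise ValueError("k-mer contains N")
    rc = _rc(s)
    if s <= rc:
        return s, 1
    return rc, -1


class BloomFilter:
    """Plain Bloom filter over string keys.

    Bits are held in a numpy uint8 array. Per-key indices come from
    blake2b-based double hashing (two 64-bit halves of one digest combined
    as ``h1 + i*h2``), so the structure is fully deterministic across runs
    and platforms.
    """

    def __init__(self, n_keys: int, fpr: float):
        if not (0.0 < fpr < 1.0):
            raise ValueError("fpr must lie in (0, 1)")
        n = max(int(n_keys), 1)
        m = math.ceil(-n * math.log(fpr) / (math.log(2) ** 2))
        self.bit_count: int = max(m, 8)
        self.hash_count: int = max(1, round(self.bit_count / n * math.log(2)))
        self.bits = np.zeros((self.bit_count + 7) // 8, dtype=np.uint8)
        self.n_inserted: int = 0

    def _indices(self, key: str) -> List[int]:
        digest = hashlib.blake2b(key.encode("ascii"), digest_size=16).digest()
        h1 = int.from_bytes(digest[:8], "little")
        h2 = int.from_bytes(digest[8:], "little") | 1
        m = self.bit_count
        return [(h1 + i * h2) % m for i in range(self.hash_count)]

    def add(self, key: str) -> None:
        for idx in self._indices(key):
            self.bits[idx >> 3] |= _BIT_MASKS[idx & 7]
        self.n_inserted += 1

    def __contains__(self, key: str) -> bool:
        bits = self.bits
        for idx in self._indices(key):
            if not bits[idx >> 3] & _BIT_MASKS[idx & 7]:
                return False
        return True

    def theoretical_fpr(self, n_keys: int) -> float:
        """Standard false-positive estimate for ``n_keys`` inserted keys."""
        h, m = self.hash_count, self.bit_count
        return (1.0 - math.exp(-h * n_keys / m)) ** h


@dataclass(frozen=True)
class KmerOccurrence:
    """A single placement of a canonical k-mer on a contig.

    ``strand`` is +1 when the contig's forward-strand k-mer at ``offset``
    is itself the canonical form, -1 when the canonical form is its
    reverse complement.
    """

    contig_id: str
    offset: int
    strand: int


@dataclass
class UniqueKmerMap:
    """Canonical k-mer -> single occurrence, for count-1 k-mers only.

    ``counts`` holds total occurrences across all contigs (both strands via
    canonicalization) for every canonical k-mer seen; ``unique`` contains
    exactly the keys with count 1.
    """

    k: int
    unique: Dict[str, KmerOccurrence] = field(default_factory=dict)
    counts: Dict[str, int] = field(default_factory=dict)
    contig_lengths: Dict[str, int] = field(default_factory=dict)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.unique

    def get(self, kmer: str):
        return self.unique.get(kmer)


def build_index(
    contigs: Iterable[SeqRecord], params: Parameters
) -> Tuple[BloomFilter, UniqueKmerMap]:
    """Index the contig k-spectrum.

    Every N-free k-mer of every contig (of length >= k) is canonicalized,
    counted exactly, and inserted into a Bloom filter sized from the
    distinct-key count and ``params.bloom_fpr_target``. The unique map
    holds the count-1 canonical k-mers with their single position.
    Contigs shorter than k contribute nothing (they cannot host a k-mer).
    """
    k = params.k
    counts: Dict[str, int] = {}
    first_occ: Dict[str, KmerOccurrence] = {}
    lengths: Dict[str, int] = {}
    for contig in contigs:
        seq = contig.sequence
        lengths[contig.id] = len(seq)
        for off in range(len(seq) - k + 1):
            kmer = seq[off : off + k]
            if "N" in kmer:
                continue
            canon, strand = canonical_kmer(kmer)
            c = counts.get(canon, 0)
            counts[canon] = c + 1
            if c == 0:
                first_occ[canon] = KmerOccurrence(contig.id, off, strand)
    unique = {km: occ for km, occ in first_occ.items() if counts[km] == 1}
    bloom = BloomFilter(len(counts), params.bloom_fpr_target)
    for km in counts:
        bloom.add(km)
    umap = UniqueKmerMap(k=k, unique=unique, counts=counts, contig_lengths=lengths)
    return bloom, umap
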