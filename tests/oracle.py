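"""Independent brute-force reference implementations.

These deliberately avoid the package's index/filter machinery: k-mer
occurrences are found by exhaustive substring scanning over every contig
(forward and reverse-complement), and uniqueness is decided by counting
scan hits. Used to validate the Bloom-filter + unique-map pipeline and the
edge statistics on random small instances.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

from kmerlink.io import SeqRecord, reverse_complement

ObsTuple = Tuple[str, int, str, int, int, int, str, int, int, int, int]


def brute_occurrences(kmer: str, contigs: List[SeqRecord]) -> List[Tuple[str, int, int]]:
    """All placements of ``kmer`` on any contig, either strand, by scanning."""
    k = len(kmer)
    rc = reverse_complement(kmer)
    occs = []
    for c in contigs:
        seq = c.sequence
        for off in range(len(seq) - k + 1):
            sub = seq[off : off + k]
            if sub == kmer:
                occs.append((c.id, off, 1))
            elif sub == rc:
                occs.append((c.id, off, -1))
    return occs


def brute_link_observations(
    contigs: List[SeqRecord], reads: List[SeqRecord], k: int, d: int, t: int
) -> List[ObsTuple]:
    """Surviving link observations computed without Bloom filter or map.

    Tuple layout: (read_id, start1, contig1, offset1, rel1, oo1,
    contig2, offset2, rel2, oo2, gap).
    """
    lengths = {c.id: len(c.sequence) for c in contigs}
    out: List[ObsTuple] = []
    for read in reads:
        seq = read.sequence
        for start in range(0, len(seq) - d - k + 1, t):
            k1 = seq[start : start + k]
            k2 = seq[start + d : start + d + k]
            if "N" in k1 or "N" in k2:
                continue
            occ1 = brute_occurrences(k1, contigs)
            occ2 = brute_occurrences(k2, contigs)
            if len(occ1) != 1 or len(occ2) != 1:
                continue
            (c1, o1, r1), (c2, o2, r2) = occ1[0], occ2[0]
            if c1 == c2:
                continue
            L1, L2 = lengths[c1], lengths[c2]
            oo1 = o1 if r1 == 1 else L1 - k - o1
            oo2 = o2 if r2 == 1 else L2 - k - o2
            gap = d - (L1 - oo1) - oo2
            out.append((read.id, start, c1, o1, r1, oo1, c2, o2, r2, oo2, gap))
    return out


def brute_edge_stats(
    observations: List[ObsTuple], per_read_pair_min: int
) -> Dict[tuple, Tuple[int, int, int]]:
    """Recount (n_pairs, n_reads, n_strong_reads) per oriented contig pair."""
    groups: Dict[tuple, Dict[str, int]] = {}
    for (rid, _s, c1, _o1, r1, _oo1, c2, _o2, r2, _oo2, _g) in observations:
        fwd = ((c1, r1), (c2, r2))
        rev = ((c2, -r2), (c1, -r1))
        key = min(fwd, rev)
        per_read = groups.setdefault(key, {})
        per_read[rid] = per_read.get(rid, 0) + 1
    return {
        key: (
            sum(pr.values()),
            len(pr),
            sum(1 for v in pr.values() if v > per_read_pair_min),
        )
        for key, pr in groups.items()
    }


def random_small_instance(
    rng: np.random.Generator,
) -> Tuple[List[SeqRecord], List[SeqRecord]]:
    """A random genome cut into a few contigs, plus reads from both strands.

    Occasionally duplicates a genome segment so that repeated (nonunique)
    k-mers genuinely occur, and adds one read of unrelated random sequence.
    """
    bases = "ACGT"
    g_len = int(rng.integers(600, 1500))
    genome = "".join(bases[i] for i in rng.integers(0, 4, g_len))
    if rng.random() < 0.5:  # plant a repeat: copy a segment elsewhere
        seg_len = int(rng.integers(30, 80))
        src = int(rng.integers(0, g_len - seg_len))
        dst = int(rng.integers(0, g_len - seg_len))
        genome = genome[:dst] + genome[src : src + seg_len] + genome[dst + seg_len :]
    n_contigs = int(rng.integers(2, 5))
    cut_points = sorted(rng.choice(range(100, g_len - 100), n_contigs - 1,
                                   replace=False)) if n_contigs > 1 else []
    bounds = [0] + [int(c) for c in cut_points] + [g_len]
    contigs = []
    for i in range(n_contigs):
        gap_trim = int(rng.integers(0, 30))  # trim to create real gaps
        s, e = bounds[i], bounds[i + 1] - gap_trim
        if e - s < 60:
            e = bounds[i + 1]
        contigs.append(SeqRecord(f"c{i}", genome[s:e], "contig"))
    reads = []
    n_reads = int(rng.integers(3, 7))
    for i in range(n_reads):
        r_len = int(rng.integers(150, min(2000, g_len)))
        start = int(rng.integers(0, g_len - r_len + 1))
        frag = genome[start : start + r_len]
        if rng.random() < 0.5:
            frag = reverse_complement(frag)
        reads.append(SeqRecord(f"r{i}", frag, "read"))
    junk = "".join(bases[i] for i in rng.integers(0, 4, 300))
    reads.append(SeqRecord("junk", junk, "read"))
    return contigs, reads
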