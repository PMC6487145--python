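"""Tiny built-in datasets for demos and tests."""

from __future__ import annotations

from typing import List, Tuple

from .io import SeqRecord
from .params import Parameters

__all__ = ["tiny_example"]


def tiny_example() -> Tuple[List[SeqRecord], List[SeqRecord], Parameters]:
    """A five-contig, seven-read miniature dataset.

    Small enough to trace by hand, yet it exercises every stage of the
    algorithm: one clean two-contig join with a 3 bp gap (fillable with
    ``AAA`` from the best-supported read), one junction left unjoined
    because two candidate neighbours tie at a 0.5 pair-count share, and
    reads whose k-mers miss the contigs entirely. Parameters: k=5, d=10,
    t=1, edge thresholds 1/1/1 with per-read strong threshold 1, ambiguity
    ratio 0.3.
    """
    contig_seqs = [
        ("ctg1", "ACCGAAT"),
        ("ctg2", "ACTGAAA"),
        ("ctg3", "GACTTTACGATAACTG"),
        ("ctg4", "TGGATCTAGC"),
        ("ctg5", "ACTGGGACAAAT"),
    ]
    read_seqs = [
        ("read1", "ACCGAATAAAGACTTTACGATAACT"),
        ("read2", "GCCGAACAACGACTTTACGAT"),
        ("read3", "ACTGATTCCCTTTACAACT"),
        ("read4", "TAACTGAAAATGGATC"),
        ("read5", "TAACTGCCCCTGGATC"),
        ("read6", "TAACTGAAAAACTGGG"),
        ("read7", "TAACTGCCCCACTGGG"),
    ]
    contigs = [SeqRecord(id=i, sequence=s, source="contig") for i, s in contig_seqs]
    reads = [SeqRecord(id=i, sequence=s, source="read") for i, s in read_seqs]
    params = Parameters(
        k=5, d=10, t=1,
        min_pair_links=1, min_read_links=1,
        per_read_pair_min=1, min_strong_reads=1,
        ratio_threshold=0.3,
    )
    return contigs, reads, params
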