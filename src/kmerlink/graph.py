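"""Contig connection graph.

Vertices are contigs; edges are read-supported adjacencies. Each edge
carries three support statistics:

1. ``n_pairs`` — the number of k-mer pairs connecting the two contigs;
2. ``n_reads`` — the number of distinct reads contributing such pairs;
3. ``n_strong_reads`` — the number of reads whose pair count on this edge
   is strictly greater than ``per_read_pair_min``.

Edges are keyed by contig pair *and* orientation signature (which end of
one contig joins which end of the other). Observations with conflicting
geometry form separate edges so that contradictory evidence never pools —
pooling would corrupt both support counts and gap estimates.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple, Union
from pathlib import Path

from .io import SeqRecord
from .pairs import LinkObservation
from .params import Parameters

__all__ = [
    "EdgeObservation",
    "ConnectionEdge",
    "ConnectionGraph",
    "build_graph",
    "filter_edges",
    "write_links_tsv",
]

# ((contig_a, orient_a), (contig_b, orient_b)) — canonical geometry:
# contig_a oriented orient_a, immediately followed by contig_b oriented
# orient_b. The flipped reading (b reversed, then a reversed) is the same
# physical junction; the lexicographically smaller of the two is stored.
EdgeKey = Tuple[Tuple[str, int], Tuple[str, int]]


@dataclass(frozen=True)
class EdgeObservation:
    """A link observation attached to an edge.

    ``flipped`` is True when the read saw the junction in the direction
    opposite to the edge's canonical geometry.
    """

    obs: LinkObservation
    flipped: bool


@dataclass
class ConnectionEdge:
    """One oriented adjacency between two contigs with its evidence."""

    contig_a: str
    contig_b: str
    orient_a: int
    orient_b: int
    per_read_counts: Dict[str, int] = field(default_factory=dict)
    observations: List[EdgeObservation] = field(default_factory=list)
    n_strong_reads: int = 0

    @property
    def key(self) -> EdgeKey:
        return ((self.contig_a, self.orient_a), (self.contig_b, self.orient_b))

    @property
    def n_pairs(self) -> int:
        return sum(self.per_read_counts.values())

    @property
    def n_reads(self) -> int:
        return len(self.per_read_counts)

    @property
    def mean_gap(self) -> float:
        return statistics.fmean(eo.obs.gap for eo in self.observations)

    def recompute_strong(self, per_read_pair_min: int) -> None:
        self.n_strong_reads = sum(
            1 for c in self.per_read_counts.values() if c > per_read_pair_min
        )


@dataclass
class ConnectionGraph:
    """Contigs as vertices (with lengths, in input order) plus edges."""

    contig_lengths: Dict[str, int]
    contig_order: Dict[str, int]
    edges: Dict[EdgeKey, ConnectionEdge] = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edges_of(self, contig_id: str) -> List[ConnectionEdge]:
        return [
            e
            for e in self.edges.values()
            if contig_id in (e.contig_a, e.contig_b)
        ]


def _canonical_key(obs: LinkObservation) -> Tuple[EdgeKey, bool]:
    a = (obs.occ1.contig_id, obs.rel1)
    b = (obs.occ2.contig_id, obs.rel2)
    fwd: EdgeKey = (a, b)
    rev: EdgeKey = ((b[0], -b[1]), (a[0], -a[1]))
    if fwd <= rev:
        return fwd, False
    return rev, True


def build_graph(
    observations: Iterable[LinkObservation],
    contigs: Iterable[SeqRecord],
    params: Parameters,
) -> ConnectionGraph:
    """Group link observations into edges and compute support statistics.

    Every input contig becomes a vertex (including contigs with no edges,
    which later become singleton scaffolds). Deterministic: edge insertion
    order follows observation order, which follows read input order.
    """
    lengths: Dict[str, int] = {}
    order: Dict[str, int] = {}
    for i, c in enumerate(contigs):
        lengths[c.id] = len(c.sequence)
        order[c.id] = i
    graph = ConnectionGraph(contig_lengths=lengths, contig_order=order)
    for obs in observations:
        key, flipped = _canonical_key(obs)
        edge = graph.edges.get(key)
        if edge is None:
            (ca, oa), (cb, ob) = key
            edge = ConnectionEdge(ca, cb, oa, ob)
            graph.edges[key] = edge
        rid = obs.pair.read_id
        edge.per_read_counts[rid] = edge.per_read_counts.get(rid, 0) + 1
        edge.observations.append(EdgeObservation(obs, flipped))
    for edge in graph.edges.values():
        edge.recompute_strong(params.per_read_pair_min)
    return graph


def filter_edges(graph: ConnectionGraph, params: Parameters) -> ConnectionGraph:
    """Apply the three user thresholds; vertices are never removed.

    An edge is retained iff ``n_pairs >= min_pair_links`` and
    ``n_reads >= min_read_links`` and ``n_strong_reads >= min_strong_reads``.
    Monotone in every threshold and idempotent at fixed thresholds.
    """
    kept = {
        key: e
        for key, e in graph.edges.items()
        if e.n_pairs >= params.min_pair_links
        and e.n_reads >= params.min_read_links
        and e.n_strong_reads >= params.min_strong_reads
    }
    return ConnectionGraph(
        contig_lengths=graph.contig_lengths,
        contig_order=graph.contig_order,
        edges=kept,
    )


_ORIENT = {1: "+", -1: "-"}


def write_links_tsv(graph: ConnectionGraph, path: Union[str, Path]) -> None:
    """Write one row per retained edge to a TSV link report.

    Coordinates reported anywhere in this file are 1-based inclusive;
    orientation ``x/y`` means contig_a oriented x immediately followed by
    contig_b oriented y.
    """
    with open(path, "wt") as out:
        out.write("# kmerlink link report; coordinates are 1-based inclusive\n")
        out.write(
            "contig_a\tcontig_b\torientation\tn_pairs\tn_reads\t"
            "n_strong_reads\tmean_gap\n"
        )
        for edge in graph.edges.values():
            out.write(
                f"{edge.contig_a}\t{edge.contig_b}\t"
                f"{_ORIENT[edge.orient_a]}/{_ORIENT[edge.orient_b]}\t"
                f"{edge.n_pairs}\t{edge.n_reads}\t{edge.n_strong_reads}\t"
                f"{edge.mean_gap:.2f}\n"
            )
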