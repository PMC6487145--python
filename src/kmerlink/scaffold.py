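"""Greedy seed-and-extend scaffold construction.

Contigs are visited in descending length order; each unseen contig seeds a
new scaffold (oriented +) and is extended first to the right, then to the
left, by attaching unseen neighbours from the filtered connection graph.
At each active end, a single candidate is always accepted; with several
candidates, the one with the most supporting k-mer pairs is accepted only
if every *competing* candidate's share of the total pair count stays below
``ratio_threshold`` — otherwise the evidence is ambiguous and extension
stops. Ties for the best candidate never extend.

Adjacent contigs are never concatenated directly: each junction holds a
gap placeholder resolved later by gap estimation/filling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Set, Tuple

from .graph import ConnectionEdge, ConnectionGraph
from .params import Parameters

__all__ = ["Candidate", "Junction", "ScaffoldLayout", "build_scaffolds",
           "choose_extension"]


@dataclass(frozen=True)
class Candidate:
    """A possible extension at a scaffold end.

    ``partner``/``orient`` give the contig that would be attached and its
    orientation in the layout; ``forward`` is True when the edge's
    canonical geometry already reads in the layout's left-to-right
    direction.
    """

    edge: ConnectionEdge
    partner: str
    orient: int
    forward: bool

    @property
    def n_pairs(self) -> int:
        return self.edge.n_pairs


@dataclass(frozen=True)
class Junction:
    """An edge placed between two consecutive layout slots.

    ``forward`` is True when the edge's canonical geometry matches the
    layout direction (contig_a on the left), False when it is reversed.
    """

    edge: ConnectionEdge
    forward: bool


@dataclass
class ScaffoldLayout:
    """An ordered, oriented chain of contigs with junction placeholders."""

    slots: List[Tuple[str, int]] = field(default_factory=list)
    junctions: List[Junction] = field(default_factory=list)

    @property
    def contig_ids(self) -> List[str]:
        return [cid for cid, _ in self.slots]


def _candidates_right(
    graph: ConnectionGraph, contig: str, orient: int, seen: Set[str]
) -> List[Candidate]:
    out: List[Candidate] = []
    for edge in graph.edges.values():
        if edge.contig_a == contig and edge.orient_a == orient:
            if edge.contig_b not in seen:
                out.append(Candidate(edge, edge.contig_b, edge.orient_b, True))
        elif edge.contig_b == contig and edge.orient_b == -orient:
            if edge.contig_a not in seen:
                out.append(Candidate(edge, edge.contig_a, -edge.orient_a, False))
    return out


def _candidates_left(
    graph: ConnectionGraph, contig: str, orient: int, seen: Set[str]
) -> List[Candidate]:
    out: List[Candidate] = []
    for edge in graph.edges.values():
        if edge.contig_b == contig and edge.orient_b == orient:
            if edge.contig_a not in seen:
                out.append(Candidate(edge, edge.contig_a, edge.orient_a, True))
        elif edge.contig_a == contig and edge.orient_a == -orient:
            if edge.contig_b not in seen:
                out.append(Candidate(edge, edge.contig_b, -edge.orient_b, False))
    return out


def choose_extension(
    candidates: List[Candidate], ratio_threshold: float
) -> Optional[Candidate]:
    """Pick the extension edge among candidates at an active end, or None.

    A single candidate is accepted outright. Among several, let each
    candidate's share be ``n_pairs / total n_pairs``; the candidate with
    the most pairs is accepted iff every other candidate's share is
    strictly below ``ratio_threshold``. A tie for the most pairs is always
    ambiguous (no extension).
    """
    if not candidates:
        return None
    if len(candidates) == 1:
        return candidates[0]
    total = sum(c.n_pairs for c in candidates)
    if total == 0:
        return None
    best = max(candidates, key=lambda c: c.n_pairs)
    n_best = sum(1 for c in candidates if c.n_pairs == best.n_pairs)
    if n_best > 1:
        return None
    for c in candidates:
        if c is best:
            continue
        if c.n_pairs / total >= ratio_threshold:
            return None
    return best


def build_scaffolds(
    graph: ConnectionGraph, params: Parameters
) -> List[ScaffoldLayout]:
    """Partition the contigs of a filtered graph into scaffold layouts.

    Seeds are chosen by descending contig length (ties by input order);
    every contig ends up in exactly one layout. Deterministic for a fixed
    graph.
    """
    order = sorted(
        graph.contig_lengths,
        key=lambda c: (-graph.contig_lengths[c], graph.contig_order[c]),
    )
    seen: Set[str] = set()
    layouts: List[ScaffoldLayout] = []
    for seed in order:
        if seed in seen:
            continue
        layout = ScaffoldLayout(slots=[(seed, 1)])
        seen.add(seed)
        # extend right
        while True:
            c_end, o_end = layout.slots[-1]
            cand = choose_extension(
                _candidates_right(graph, c_end, o_end, seen),
                params.ratio_threshold,
            )
            if cand is None:
                break
            layout.slots.append((cand.partner, cand.orient))
            layout.junctions.append(Junction(cand.edge, cand.forward))
            seen.add(cand.partner)
        # extend left (prepending slot and junction)
        while True:
            c_start, o_start = layout.slots[0]
            cand = choose_extension(
                _candidates_left(graph, c_start, o_start, seen),
                params.ratio_threshold,
            )
            if cand is None:
                break
            layout.slots.insert(0, (cand.partner, cand.orient))
            layout.junctions.insert(0, Junction(cand.edge, cand.forward))
            seen.add(cand.partner)
        layouts.append(layout)
    return layouts
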