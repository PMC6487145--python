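"""Gap size estimation, gap filling, and scaffold rendering.

Every junction's gap is estimated per supporting k-mer pair as
``d - (L_left - o1') - o2'`` (pair distance minus the stretch of the left
contig after the first k-mer minus the stretch of the right contig before
the second k-mer). Sequencing errors make the per-pair values differ; the
arithmetic mean, rounded half away from zero, is the consensus estimate.

A non-positive estimate means the contigs overlap: a single ``N`` is
placed between them. A positive gap is rendered as a run of ``N`` of the
estimated length, or — in gap-fill mode — replaced by a fragment of the
read that supports the junction with the greatest number of k-mer pairs,
cut at the read coordinates where the left contig ends.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .graph import EdgeObservation
from .io import SeqRecord, _rc
from .scaffold import ScaffoldLayout

__all__ = [
    "GapRecord",
    "round_half_away",
    "estimate_gap",
    "select_fill",
    "render_scaffold_sequence",
]

logger = logging.getLogger("kmerlink")


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


@dataclass(frozen=True)
class GapRecord:
    """Resolved junction between two consecutive scaffold slots."""

    left_contig: str
    right_contig: str
    per_pair_gaps: Tuple[int, ...]
    mean_gap: float
    rounded_gap: int
    fill_read_id: Optional[str] = None
    fill_interval: Optional[Tuple[int, int]] = None  # half-open, read coords
    rendered: str = "N"


def estimate_gap(
    observations: Sequence[EdgeObservation],
    left_contig: str,
    right_contig: str,
) -> GapRecord:
    """Average the per-pair gap estimates of one junction (sizes only).

    The rendered string defaults to the N-run form: a single ``N`` for a
    non-positive (overlap) estimate, otherwise ``rounded_gap`` Ns.
    """
    if not observations:
        raise ValueError("a junction cannot exist without supporting pairs")
    gaps = tuple(eo.obs.gap for eo in observations)
    mean = statistics.fmean(gaps)
    rounded = round_half_away(mean)
    rendered = "N" if rounded <= 0 else "N" * rounded
    return GapRecord(
        left_contig=left_contig,
        right_contig=right_contig,
        per_pair_gaps=gaps,
        mean_gap=mean,
        rounded_gap=rounded,
        rendered=rendered,
    )


def select_fill(
    gap: GapRecord,
    observations: Sequence[EdgeObservation],
    junction_forward: bool,
    reads_by_id: Dict[str, SeqRecord],
    read_order: Dict[str, int],
) -> GapRecord:
    """Fill a positive gap with a fragment of the best-supported read.

    The chosen read is the one contributing the most k-mer pairs to this
    junction (ties broken by read input order). The fragment starts at the
    read coordinate where the left contig ends — the mean over that read's
    pairs of ``start1 + (L_left - o1')``, rounded half away from zero —
    and has length ``rounded_gap`` (the consensus gap size, so the
    scaffold length stays consistent with the reported gap). The fragment
    is reverse-complemented when the read saw the junction in the
    direction opposite to the scaffold. If the interval falls outside the
    read, the N-run is kept and a warning logged.
    """
    if gap.rounded_gap <= 0:
        return gap
    by_read: Dict[str, List[EdgeObservation]] = {}
    for eo in observations:
        by_read.setdefault(eo.obs.pair.read_id, []).append(eo)
    best_read = min(
        by_read, key=lambda rid: (-len(by_read[rid]), read_order[rid])
    )
    eos = by_read[best_read]
    start = round_half_away(
        statistics.fmean(eo.obs.left_end_in_read for eo in eos)
    )
    end = start + gap.rounded_gap
    read = reads_by_id[best_read]
    if start < 0 or end > len(read.sequence):
        logger.warning(
            "gap fill interval [%d, %d) outside read %s (length %d); "
            "keeping N-run", start, end, best_read, len(read.sequence),
        )
        return gap
    fragment = read.sequence[start:end]
    # the read's junction direction relative to the layout: the read
    # matches the edge's canonical geometry iff not flipped, and the
    # canonical geometry matches the layout iff junction_forward.
    same_as_layout = (not eos[0].flipped) == junction_forward
    if not same_as_layout:
        fragment = _rc(fragment)
    return replace(
        gap,
        fill_read_id=best_read,
        fill_interval=(start, end),
        rendered=fragment,
    )


def render_scaffold_sequence(
    layout: ScaffoldLayout,
    gaps: Sequence[GapRecord],
    contigs_by_id: Dict[str, SeqRecord],
) -> str:
    """Concatenate oriented contig sequences interleaved with gap strings."""
    if len(gaps) != len(layout.slots) - 1:
        raise ValueError("need exactly one gap record per junction")
    parts: List[str] = []
    for i, (cid, orient) in enumerate(layout.slots):
        seq = contigs_by_id[cid].sequence
        parts.append(seq if orient == 1 else _rc(seq))
        if i < len(gaps):
            parts.append(gaps[i].rendered)
    return "".join(parts)
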