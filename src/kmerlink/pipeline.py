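"""End-to-end orchestration of the linking pipeline.

Stages: index the contig k-spectrum -> generate k-mer pairs from every
long read -> filter pairs (Bloom, uniqueness, distinct contigs) -> build
and filter the connection graph -> seed-and-extend scaffolding -> gap
estimation (and optional gap filling) -> rendered scaffold FASTA plus a
TSV link report. Per-stage counts are logged to standard error and
returned in a summary. The pipeline is deterministic: re-running with
identical inputs and parameters produces byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Union

from . import gapfill as _gapfill
from . import graph as _graph
from . import index as _index
from . import pairs as _pairs
from . import scaffold as _scaffold
from .gapfill import GapRecord
from .graph import ConnectionGraph
from .io import SeqRecord, read_sequences, write_scaffolds
from .params import Parameters
from .scaffold import ScaffoldLayout

__all__ = ["PipelineSummary", "LinkResult", "link_contigs", "run_pipeline"]

logger = logging.getLogger("kmerlink")


@dataclass
class PipelineSummary:
    """Per-stage counts of one pipeline run."""

    n_contigs: int = 0
    n_contigs_indexed: int = 0
    n_reads: int = 0
    pairs_generated: int = 0
    pairs_after_bloom: int = 0
    pairs_after_unique: int = 0
    pairs_same_contig: int = 0
    linking_pairs: int = 0
    edges_before_filter: int = 0
    edges_after_filter: int = 0
    n_scaffolds: int = 0


@dataclass
class LinkResult:
    """Full in-memory result of a pipeline run."""

    scaffolds: List[SeqRecord]
    layouts: List[ScaffoldLayout]
    gap_records: List[List[GapRecord]]  # per layout, one per junction
    graph: ConnectionGraph  # unfiltered
    filtered_graph: ConnectionGraph
    summary: PipelineSummary = field(default_factory=PipelineSummary)


def link_contigs(
    contigs: List[SeqRecord],
    reads: List[SeqRecord],
    params: Parameters,
) -> LinkResult:
    """Run the complete linking algorithm in memory.

    Contigs shorter than k cannot host a k-mer: they are excluded from
    indexing (with a warning) but carried through verbatim as
    single-contig scaffolds, so every input contig appears exactly once
    across the output.
    """
    summary = PipelineSummary(n_contigs=len(contigs), n_reads=len(reads))

    indexable = [c for c in contigs if len(c.sequence) >= params.k]
    for c in contigs:
        if len(c.sequence) < params.k:
            logger.warning(
                "contig %s (length %d) is shorter than k=%d; excluded from "
                "indexing, passed through unscaffolded", c.id,
                len(c.sequence), params.k,
            )
    summary.n_contigs_indexed = len(indexable)

    bloom, umap = _index.build_index(indexable, params)
    logger.info(
        "indexed %d contigs: %d distinct canonical k-mers, %d unique",
        len(indexable), len(umap.counts), len(umap.unique),
    )

    observations: List[_pairs.LinkObservation] = []
    for read in reads:
        generated = _pairs.generate_pairs(read, params)
        summary.pairs_generated += len(generated)
        obs, n_bloom, n_unique, n_same = _pairs._filter_stages(
            generated, bloom, umap, params
        )
        summary.pairs_after_bloom += n_bloom
        summary.pairs_after_unique += n_unique
        summary.pairs_same_contig += n_same
        observations.extend(obs)
    summary.linking_pairs = len(observations)
    logger.info(
        "pairs: %d generated, %d after Bloom, %d after uniqueness, "
        "%d same-contig dropped, %d linking",
        summary.pairs_generated, summary.pairs_after_bloom,
        summary.pairs_after_unique, summary.pairs_same_contig,
        summary.linking_pairs,
    )

    graph = _graph.build_graph(observations, contigs, params)
    summary.edges_before_filter = graph.n_edges
    fgraph = _graph.filter_edges(graph, params)
    summary.edges_after_filter = fgraph.n_edges
    logger.info(
        "connection graph: %d edges before filtering, %d after",
        summary.edges_before_filter, summary.edges_after_filter,
    )

    layouts = _scaffold.build_scaffolds(fgraph, params)
    summary.n_scaffolds = len(layouts)

    contigs_by_id = {c.id: c for c in contigs}
    reads_by_id = {r.id: r for r in reads}
    read_order = {r.id: i for i, r in enumerate(reads)}

    scaffolds: List[SeqRecord] = []
    all_gaps: List[List[GapRecord]] = []
    for i, layout in enumerate(layouts, start=1):
        gaps: List[GapRecord] = []
        for j, junction in enumerate(layout.junctions):
            left_id, _ = layout.slots[j]
            right_id, _ = layout.slots[j + 1]
            gap = _gapfill.estimate_gap(
                junction.edge.observations, left_id, right_id
            )
            if params.gap_fill and gap.rounded_gap > 0:
                gap = _gapfill.select_fill(
                    gap, junction.edge.observations, junction.forward,
                    reads_by_id, read_order,
                )
            gaps.append(gap)
        seq = _gapfill.render_scaffold_sequence(layout, gaps, contigs_by_id)
        members = ",".join(
            f"{cid}({'+' if o == 1 else '-'})" for cid, o in layout.slots
        )
        scaffolds.append(
            SeqRecord(
                id=f"scaffold_{i}",
                sequence=seq,
                source="scaffold",
                description=f"members={members}",
            )
        )
        all_gaps.append(gaps)
    logger.info("built %d scaffolds from %d contigs",
                len(scaffolds), len(contigs))

    return LinkResult(
        scaffolds=scaffolds,
        layouts=layouts,
        gap_records=all_gaps,
        graph=graph,
        filtered_graph=fgraph,
        summary=summary,
    )


def run_pipeline(
    contigs_path: Union[str, Path],
    reads_path: Union[str, Path],
    params: Parameters,
    out_prefix: Union[str, Path],
) -> PipelineSummary:
    """File-to-file pipeline: read inputs, link, write outputs.

    Writes ``<prefix>.scaffolds.fasta`` and ``<prefix>.links.tsv`` and
    returns the per-stage summary.
    """
    contigs = read_sequences(contigs_path, kind="contig")
    reads = read_sequences(reads_path, kind="read")
    result = link_contigs(contigs, reads, params)
    out_prefix = str(out_prefix)
    write_scaffolds(result.scaffolds, out_prefix + ".scaffolds.fasta")
    _graph.write_links_tsv(result.filtered_graph, out_prefix + ".links.tsv")
    return result.summary
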