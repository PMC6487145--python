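from kmerlink import (Candidate, ConnectionEdge, Parameters, build_graph,
                      build_index, build_scaffolds, choose_extension,
                      filter_and_map, filter_edges, generate_pairs)
from kmerlink.graph import ConnectionGraph


def _filtered_graph(contigs, reads, params):
    bloom, umap = build_index(contigs, params)
    obs = []
    for read in reads:
        obs.extend(
            filter_and_map(generate_pairs(read, params), bloom, umap, params)
        )
    return filter_edges(build_graph(obs, contigs, params), params)


def _cand(n_pairs, partner="x"):
    edge = ConnectionEdge(partner, "y", 1, 1,
                          per_read_counts={"r": n_pairs})
    return Candidate(edge, partner, 1, True)


def test_single_candidate_is_always_chosen():
    c = _cand(1)
    assert choose_extension([c], 0.3) is c


def test_equal_shares_block_extension():
    # two candidates with 4 pairs each: shares 0.5/0.5 >= 0.3
    assert choose_extension([_cand(4, "a"), _cand(4, "b")], 0.3) is None


def test_dominant_candidate_is_chosen_when_competition_is_weak():
    a, b = _cand(9, "a"), _cand(1, "b")
    assert choose_extension([a, b], 0.3) is a


def test_competing_share_at_threshold_blocks_extension():
    # shares 0.7/0.3: competing share equals the threshold -> ambiguous
    assert choose_extension([_cand(7, "a"), _cand(3, "b")], 0.3) is None
    assert choose_extension([_cand(7, "a"), _cand(3, "b")], 0.31) is not None


def test_tie_for_best_is_always_ambiguous():
    cands = [_cand(2, "a"), _cand(2, "b"), _cand(1, "c"), _cand(1, "d")]
    assert choose_extension(cands, 0.9) is None


def test_tiny_example_builds_four_layouts(tiny):
    contigs, reads, params = tiny
    layouts = build_scaffolds(_filtered_graph(contigs, reads, params), params)
    assert len(layouts) == 4
    multi = [l for l in layouts if len(l.slots) > 1]
    assert len(multi) == 1
    assert multi[0].slots == [("ctg1", 1), ("ctg3", 1)]
    assert len(multi[0].junctions) == 1


def test_contigs_are_conserved_across_layouts(tiny):
    contigs, reads, params = tiny
    layouts = build_scaffolds(_filtered_graph(contigs, reads, params), params)
    placed = [cid for l in layouts for cid in l.contig_ids]
    assert sorted(placed) == sorted(c.id for c in contigs)


def test_edgeless_graph_gives_singletons_by_descending_length(tiny):
    contigs, _, params = tiny
    graph = ConnectionGraph(
        contig_lengths={c.id: len(c.sequence) for c in contigs},
        contig_order={c.id: i for i, c in enumerate(contigs)},
    )
    layouts = build_scaffolds(graph, params)
    assert [l.slots for l in layouts] == [
        [("ctg3", 1)], [("ctg5", 1)], [("ctg4", 1)],
        [("ctg1", 1)], [("ctg2", 1)],  # length tie broken by input order
    ]


def test_unambiguous_chain_is_assembled_with_orientations():
    """A three-contig chain a-b-c where b occurs reverse-complemented in
    the genome order must come out as one layout with propagated strands."""
    from kmerlink import SeqRecord, reverse_complement
    import numpy as np

    rng = np.random.default_rng(42)
    bases = "ACGT"
    genome = "".join(bases[i] for i in rng.integers(0, 4, 700))
    a, b, c = genome[0:200], genome[210:420], genome[430:700]
    contigs = [
        SeqRecord("a", a, "contig"),
        SeqRecord("b", reverse_complement(b), "contig"),  # stored flipped
        SeqRecord("c", c, "contig"),
    ]
    reads = [
        SeqRecord("r1", genome[50:500], "read"),
        SeqRecord("r2", reverse_complement(genome[200:680]), "read"),
    ]
    params = Parameters(k=11, d=120, t=1)
    layouts = build_scaffolds(_filtered_graph(contigs, reads, params), params)
    assert len(layouts) == 1
    slots = layouts[0].slots
    # seed is the longest contig, oriented +; the chain may come out in
    # either genome direction depending on the seed's stored strand
    assert slots in (
        [("a", 1), ("b", -1), ("c", 1)],
        [("c", -1), ("b", 1), ("a", -1)],
    )


def test_seen_partners_are_excluded_before_ambiguity(tiny):
    """Once ctg1 is placed, right-extension of ctg3 sees only the two
    tied candidates; their 0.5 shares stop the extension."""
    contigs, reads, params = tiny
    graph = _filtered_graph(contigs, reads, params)
    from kmerlink.scaffold import _candidates_right

    cands = _candidates_right(graph, "ctg3", 1, seen={"ctg3", "ctg1"})
    assert sorted(c.partner for c in cands) == ["ctg4", "ctg5"]
    shares = [c.n_pairs / sum(x.n_pairs for x in cands) for c in cands]
    assert shares == [0.5, 0.5]
    assert choose_extension(cands, params.ratio_threshold) is None


def test_determinism_of_layouts(tiny):
    contigs, reads, params = tiny
    g1 = _filtered_graph(contigs, reads, params)
    g2 = _filtered_graph(contigs, reads, params)
    assert build_scaffolds(g1, params) == build_scaffolds(g2, params)
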