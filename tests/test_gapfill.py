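import dataclasses

import pytest

from kmerlink import SeqRecord, link_contigs
from kmerlink.gapfill import (GapRecord, estimate_gap, render_scaffold_sequence,
                              round_half_away, select_fill)
from kmerlink.graph import EdgeObservation
from kmerlink.pairs import KmerPair, LinkObservation
from kmerlink.scaffold import ScaffoldLayout


def _obs(gap, read_id="r", start1=0, left_end=5):
    pair = KmerPair(read_id, start1, "AAAAA", "CCCCC")
    from kmerlink.index import KmerOccurrence
    return LinkObservation(
        pair=pair,
        occ1=KmerOccurrence("L", 0, 1), occ2=KmerOccurrence("R", 0, 1),
        rel1=1, rel2=1, oriented_offset1=0, oriented_offset2=0,
        gap=gap, left_end_in_read=left_end,
    )


def _eobs(gap, read_id="r", left_end=5, flipped=False):
    return EdgeObservation(_obs(gap, read_id=read_id, left_end=left_end), flipped)


@pytest.mark.parametrize("x,expected", [
    (2.5, 3), (-2.5, -3), (2.4, 2), (-2.4, -2), (0.5, 1), (-0.5, -1), (0.0, 0),
])
def test_rounding_is_half_away_from_zero(x, expected):
    assert round_half_away(x) == expected


def test_tiny_junction_gap_is_three(tiny):
    contigs, reads, params = tiny
    result = link_contigs(contigs, reads, params)
    (gap,) = result.gap_records[0]
    assert gap.per_pair_gaps == (3, 3, 3, 3)
    assert gap.mean_gap == 3.0
    assert gap.rounded_gap == 3
    assert gap.rendered == "NNN"


def test_zero_or_negative_gap_renders_single_n():
    for g in (0, -4):
        rec = estimate_gap([_eobs(g)], "L", "R")
        assert rec.rounded_gap == g
        assert rec.rendered == "N"


def test_mean_gap_is_averaged_and_rounded():
    rec = estimate_gap([_eobs(2), _eobs(4)], "L", "R")
    assert rec.mean_gap == 3.0
    assert rec.rounded_gap == 3
    rec = estimate_gap([_eobs(2), _eobs(3)], "L", "R")
    assert rec.rounded_gap == 3  # 2.5 rounds away from zero


def test_empty_observation_set_is_a_contract_violation():
    with pytest.raises(ValueError):
        estimate_gap([], "L", "R")


def test_fill_taken_from_read_with_most_pairs(tiny):
    contigs, reads, params = tiny
    params = dataclasses.replace(params, gap_fill=True)
    result = link_contigs(contigs, reads, params)
    (gap,) = result.gap_records[0]
    assert gap.fill_read_id == "read1"  # 3 pairs beat read2's single pair
    assert gap.fill_interval == (7, 10)
    assert gap.rendered == "AAA"
    assert result.scaffolds[0].sequence == "ACCGAATAAAGACTTTACGATAACTG"


def test_fill_tie_breaks_by_read_input_order():
    reads = {
        "r1": SeqRecord("r1", "ACGTACGTAC", "read"),
        "r2": SeqRecord("r2", "TGCATGCATG", "read"),
    }
    order = {"r1": 0, "r2": 1}
    obs = [_eobs(3, "r2", left_end=2), _eobs(3, "r2", left_end=2),
           _eobs(3, "r1", left_end=4), _eobs(3, "r1", left_end=4)]
    gap = estimate_gap(obs, "L", "R")
    filled = select_fill(gap, obs, True, reads, order)
    assert filled.fill_read_id == "r1"
    assert filled.fill_interval == (4, 7)
    assert filled.rendered == reads["r1"].sequence[4:7] == "ACG"


def test_fill_interval_outside_read_falls_back_to_n_run():
    reads = {"r1": SeqRecord("r1", "ACGTAC", "read")}
    obs = [_eobs(5, "r1", left_end=4)]
    gap = estimate_gap(obs, "L", "R")
    filled = select_fill(gap, obs, True, reads, {"r1": 0})
    assert filled.fill_read_id is None
    assert filled.rendered == "N" * 5


def test_fill_is_reverse_complemented_against_layout():
    # the read saw the junction in the flipped direction
    reads = {"r1": SeqRecord("r1", "TTTTGCAGGG", "read")}
    obs = [_eobs(3, "r1", left_end=4, flipped=True)]
    gap = estimate_gap(obs, "L", "R")
    filled = select_fill(gap, obs, True, reads, {"r1": 0})
    assert filled.rendered == "TGC"  # reverse complement of GCA at [4,7)


def test_render_concatenates_oriented_contigs_and_gaps():
    contigs = {
        "a": SeqRecord("a", "ACGTA", "contig"),
        "b": SeqRecord("b", "GGCAT", "contig"),
    }
    layout = ScaffoldLayout(slots=[("a", 1), ("b", -1)])
    gap = GapRecord("a", "b", (2,), 2.0, 2, rendered="NN")
    seq = render_scaffold_sequence(layout, [gap], contigs)
    assert seq == "ACGTA" + "NN" + "ATGCC"


def test_render_singleton_layout_is_the_contig():
    contigs = {"a": SeqRecord("a", "ACGTA", "contig")}
    layout = ScaffoldLayout(slots=[("a", 1)])
    assert render_scaffold_sequence(layout, [], contigs) == "ACGTA"


def test_rendered_length_accounting(tiny):
    contigs, reads, params = tiny
    result = link_contigs(contigs, reads, params)
    by_id = {c.id: len(c.sequence) for c in contigs}
    for layout, gaps, scaffold in zip(
        result.layouts, result.gap_records, result.scaffolds
    ):
        expected = sum(by_id[cid] for cid in layout.contig_ids) + sum(
            max(1, g.rounded_gap) for g in gaps
        )
        assert len(scaffold.sequence) == expected
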