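import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kmerlink import (BloomFilter, Parameters, SeqRecord, build_index,
                      canonical_kmer, reverse_complement)

odd_kmer = st.text(alphabet="ACGT", min_size=5, max_size=5)


def test_canonical_kmer_examples():
    assert canonical_kmer("ACCGA") == ("ACCGA", 1)   # ACCGA < TCGGT
    assert canonical_kmer("TCGGT") == ("ACCGA", -1)


@given(odd_kmer)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_canonical_kmer_is_strand_symmetric(s):
    canon, strand = canonical_kmer(s)
    canon_rc, strand_rc = canonical_kmer(reverse_complement(s))
    assert canon == canon_rc
    assert strand == -strand_rc
    assert canon in (s, reverse_complement(s))


def test_canonical_kmer_rejects_empty_and_n():
    with pytest.raises(ValueError):
        canonical_kmer("")
    with pytest.raises(ValueError):
        canonical_kmer("ACNGT")


def _tiny_params(**kw):
    return Parameters(k=5, d=10, t=1, **kw)


def test_build_index_counts_tiny_contig_spectrum(tiny):
    contigs, _, params = tiny
    _, umap = build_index(contigs, params)
    # ACCGAAT contributes exactly its three 5-mers, all unique
    for km in ("ACCGA", "CCGAA", "CGAAT"):
        canon, _ = canonical_kmer(km)
        assert umap.counts[canon] == 1
        assert canon in umap.unique
        assert umap.unique[canon].contig_id == "ctg1"
    # TAACT sits at offset 10 of ctg3, forward, unique
    canon, strand = canonical_kmer("TAACT")
    occ = umap.unique[canon]
    assert (occ.contig_id, occ.offset, strand * occ.strand) == ("ctg3", 10, 1)


def test_duplicated_kmer_is_excluded_from_unique_map():
    contigs = [
        SeqRecord("a", "TTACCGGATCATT", "contig"),
        SeqRecord("b", "GGACCGGATCAGG", "contig"),
    ]
    params = Parameters(k=9, d=10)
    _, umap = build_index(contigs, params)
    canon, _ = canonical_kmer("ACCGGATCA")
    assert umap.counts[canon] == 2
    assert canon not in umap.unique


def test_kmers_containing_n_are_skipped():
    contigs = [SeqRecord("a", "ACGTGNACGTT", "contig")]
    _, umap = build_index(contigs, _tiny_params())
    assert all("N" not in km for km in umap.counts)
    # only the two N-free 5-mers at each end
    assert len(umap.counts) == 2


def test_unique_map_matches_brute_force_scan():
    """Oracle: unique map == exhaustive scan of all k-mers, both strands."""
    rng = np.random.default_rng(11)
    bases = "ACGT"
    for _ in range(20):
        contigs = [
            SeqRecord(
                f"c{i}",
                "".join(bases[j] for j in rng.integers(0, 4, int(rng.integers(20, 120)))),
                "contig",
            )
            for i in range(int(rng.integers(1, 4)))
        ]
        params = Parameters(k=7, d=10)
        _, umap = build_index(contigs, params)
        counts = {}
        positions = {}
        for c in contigs:
            for off in range(len(c.sequence) - 7 + 1):
                km = c.sequence[off : off + 7]
                canon, strand = canonical_kmer(km)
                counts[canon] = counts.get(canon, 0) + 1
                positions.setdefault(canon, (c.id, off, strand))
        assert umap.counts == counts
        expected_unique = {
            km: pos for km, pos in positions.items() if counts[km] == 1
        }
        got = {
            km: (o.contig_id, o.offset, o.strand)
            for km, o in umap.unique.items()
        }
        assert got == expected_unique


def test_bloom_has_no_false_negatives(tiny):
    contigs, _, params = tiny
    bloom, umap = build_index(contigs, params)
    for km in umap.counts:
        assert km in bloom


def test_bloom_empirical_fpr_within_twice_theoretical():
    rng = np.random.default_rng(5)
    bases = "ACGT"
    n = 20_000
    keys = {
        "".join(bases[j] for j in rng.integers(0, 4, 21)) for _ in range(n)
    }
    bloom = BloomFilter(len(keys), 0.01)
    for key in keys:
        bloom.add(key)
    assert all(key in bloom for key in keys)  # exhaustive: no false negatives
    absent_trials = 20_000
    fp = 0
    for _ in range(absent_trials):
        q = "".join(bases[j] for j in rng.integers(0, 4, 21))
        if q not in keys and q in bloom:
            fp += 1
    assert fp / absent_trials <= 2 * bloom.theoretical_fpr(len(keys))


def test_bloom_sizing_follows_target_fpr():
    bloom = BloomFilter(1000, 0.01)
    assert bloom.theoretical_fpr(1000) < 0.02
    assert bloom.hash_count >= 1
    with pytest.raises(ValueError):
        BloomFilter(10, 1.5)
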