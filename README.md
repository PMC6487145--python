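# kmerlink

Scaffold short-read assembly contigs with long, error-prone reads
(ONT/PacBio-style) using paired k-mer evidence, estimate the gap between
neighbouring contigs, and optionally fill each gap with a fragment of the
best-supporting long read.

It is aimed at hybrid-assembly workflows: a second-generation assembler
produces accurate but fragmented contigs; long reads, too noisy for exact
mapping, still contain enough intact k-mers to say *which contigs are
neighbours and how far apart they sit*. kmerlink exploits exactly that
signal, avoiding base-level alignment entirely.

## Method

1. **Contig k-spectrum index.** Every k-mer of every contig (canonical
   form, strand-collapsed) is counted in a hash table and inserted into a
   Bloom filter. K-mers occurring more than once are repeats and are
   treated as non-unique; the count-1 k-mers form a *unique-k-mer map*
   from k-mer to its single position (contig, offset, strand).
2. **Paired k-mers from reads.** From each long read, pairs of k-mers are
   taken at a fixed start-to-start distance *d*, sliding by *t* bases. A
   pair survives iff both k-mers pass the Bloom filter, both are unique in
   the contig set, and their positions lie on two *different* contigs —
   direct evidence the read bridges those contigs.
3. **Connection graph.** Surviving pairs are grouped into edges keyed by
   contig pair *and* junction geometry (orientation signature). Each edge
   carries three support statistics: number of k-mer pairs, number of
   distinct reads, and number of "strong" reads (reads contributing
   strictly more than `per_read_pair_min` pairs). Edges below any of the
   three user thresholds are removed.
4. **Scaffolding.** Contigs are seeded in descending length order and
   greedily extended at both ends. With several candidate neighbours, the
   best (most pairs) is accepted only if every competitor's share of the
   pair count stays below `ratio_threshold`; otherwise extension stops.
5. **Gap estimation / filling.** Per supporting pair the gap is
   `d − (L_left − o1′) − o2′` (pair distance minus the left contig's tail
   after the first k-mer minus the right contig's head before the second);
   the junction estimate is the rounded mean. Non-positive estimates mean
   overlap and render as a single `N`; positive gaps render as an N run
   or, with `--fill-gaps`, as a fragment of the read with the most
   supporting pairs, cut where the left contig ends on that read.

## Worked example

```bash
python examples/link_worked_example.py
```

prints (abridged):

```
contigs: 5, reads: 7
k-mer pairs generated from reads : 31
  after Bloom filter             : 16
  after uniqueness filter        : 15
  linking two distinct contigs   : 13
connection graph edges           : 4 -> 3 after threshold filters
scaffolds                        : 4

scaffold_1  members=ctg1(+),ctg3(+)
  ACCGAATNNNGACTTTACGATAACTG
...
```

Of 31 generated pairs, 13 map uniquely onto two distinct contigs. Exactly
one junction survives the three edge filters unambiguously, joining two
contigs with an estimated gap of 3 bases (the `NNN` run). The seed contig
is *not* extended to the right because its two candidate neighbours each
hold a 0.5 share of the supporting pairs — above the 0.3 ambiguity
threshold. With gap filling on (`examples/gap_fill_example.py`) the `NNN`
becomes `AAA`, copied from the read that supports the junction with 3
k-mer pairs.

The same interface is available from the shell:

```bash
kmerlink link --contigs contigs.fasta --reads reads.fastq \
    -k 15 -d 4000 -t 2 --fill-gaps --out run1
kmerlink simulate --genome-length 100000 --n-gaps 4 --seed 1 --out sim1
```

`link` writes `<prefix>.scaffolds.fasta` and a `<prefix>.links.tsv` edge
report; `simulate` writes a seeded synthetic genome, contigs, reads and a
ground-truth table.

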