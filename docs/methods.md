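# Methods

## Problem and model

Second-generation assemblies are accurate but fragmented; third-generation
reads are long but error-ridden (10–15% indel/substitution rates), which
makes exact alignment expensive and fragile. kmerlink links contigs using
only *paired k-mer co-occurrence*: if two k-mers taken from one read at a
fixed distance *d* each occur exactly once in the contig set and on two
different contigs, the read almost certainly spans the junction between
those contigs. Errors destroy many k-mers, but each surviving pair is
near-unambiguous, and a spanning read typically yields many pairs, so the
evidence is redundant.

The method assumes: (i) contigs are essentially error-free relative to
the reads, so their k-spectrum can be trusted; (ii) repeats are handled by
*discarding* repeated k-mers rather than resolving them — junctions whose
flanks are entirely repetitive cannot be linked; (iii) a junction's
physical geometry is consistent across supporting reads (contradictory
orientations are kept on separate edges and resolved by the support
filters, never pooled).

## Parameters

| name | default | meaning |
| --- | --- | --- |
| `k` | 15 | k-mer length (bases). Odd, so no k-mer is its own reverse complement. Smaller k tolerates higher read error but increases repeat collisions. |
| `d` | 4000 | start-to-start distance (bases) between the two k-mers of a pair. Must exceed the gaps to be bridged. |
| `t` | 2 | sliding step (bases) between pair start positions; 1 is exhaustive, larger values subsample for speed. |
| `min_pair_links` | 1 | edge filter: minimum k-mer pairs. |
| `min_read_links` | 1 | edge filter: minimum distinct reads. |
| `per_read_pair_min` | 1 | a read is *strong* for an edge iff its pair count is strictly greater than this. |
| `min_strong_reads` | 1 | edge filter: minimum strong reads. |
| `ratio_threshold` | 0.3 | extension is ambiguous if any competing candidate's pair-count share reaches this value. |
| `gap_fill` | off | replace N runs with a long-read fragment. |
| `bloom_fpr_target` | 0.01 | Bloom filter sizing target. |

The pair distance is defined start-to-start: with k = 5, d = 10 a 16-base
read admits exactly two pair positions (16 − 10 − 5 + 1), which is the
behaviour the rest of the arithmetic (gap estimation, fill intervals) is
built on.

The edge-filter defaults (1/1/1 with `per_read_pair_min` = 1) are the
weakest settings that still demand one read with at least two pairs per
junction, which suffices to discard single-pair coincidences on tiny
inputs; real datasets warrant raising them with coverage.

## Strand handling

K-mers are indexed in canonical form (lexicographic minimum of the k-mer
and its reverse complement), so reads from either genome strand hit the
same keys. Each unique occurrence stores the strand relation between
canonical form and contig; combined with the strand relation between the
read's k-mer and the canonical form, this recovers each contig's
orientation *relative to the read*. Offsets are re-expressed in that
orientation (`o′ = o` or `L − k − o`), which makes the gap formula
orientation-free. Edges store a canonical orientation signature — the
lexicographically smaller of the two equivalent readings of the junction
— and each observation remembers whether its read saw the junction
flipped, which later decides whether a gap-fill fragment must be
reverse-complemented.

## Scaffolding rule

Seeds are taken in descending contig length (ties by input order), each
seed oriented +, extended right then left. At an active end only edges
with compatible geometry whose partner is not yet placed are candidates;
excluded partners do not enter the ambiguity denominator. A single
candidate is always accepted. With several, the one with most pairs wins
only if every other candidate's share of the candidate total is strictly
below `ratio_threshold`; ties for the best are always ambiguous. This
reduces to "prefer the largest" when competition is weak and refuses to
guess when two neighbours are comparably supported (two 0.5 shares stop
extension at the default threshold).

## Numerical choices

- Gap means and fill-interval starts are rounded half away from zero —
  symmetric and locale-independent.
- A gap estimate ≤ 0 is treated as an overlap and rendered as a single
  `N`; there is no sequence to insert and the exact overlap extent is not
  trusted from noisy evidence.
- The fill fragment's length is forced to the junction's consensus gap
  size rather than the chosen read's private estimate, keeping scaffold
  length consistent with the reported gap. If the implied read interval
  falls outside the read, the N run is kept and a warning logged.
- The Bloom filter is sized as `m = ⌈−n·ln p / ln²2⌉` bits with
  `h = round(m/n·ln 2)` hashes; indices come from blake2b-derived double
  hashing, so the structure is bit-reproducible across runs and
  platforms. False positives only cost a hash-table lookup: the unique
  map performs an exact check immediately after, so the surviving pair
  set is exact. Only the contig spectrum is counted exactly; the read
  spectrum is never stored.
- Contigs shorter than k cannot host a k-mer; they are excluded from the
  index but passed through verbatim as single-contig scaffolds, so the
  contig set is conserved.

## Synthetic data

`kmerlink.simulate` generates a uniform random genome (optionally with
planted tandem repeats), cuts it into contigs by removing gap intervals
(one per equal-width genome segment, away from segment edges, so layouts
are always feasible and contigs stay long), and samples reads with
truncated-normal lengths (minimum 200 bp), uniform starts, uniform
strand, and independent per-base substitution/insertion/deletion errors.
Defaults describe a desk-scale scenario — 100 kb genome, 4 gaps of
100–500 bp, 10× coverage of ~6 kb reads — chosen so that typical reads
span whole gaps with k-mer-pair headroom on both sides.

What the simulator does *not* emulate: realistic ONT/PacBio error
profiles (homopolymer bias, quality-dependent error bursts), chimeric
reads, heavy-tailed read lengths, non-uniform genome composition, or
short-read assembly artefacts in the contigs. Passing the recovery tests
therefore demonstrates the correctness of the linking/gap arithmetic and
strand handling, not field performance on real libraries.

The truth set records contig intervals, true adjacencies with gap
sequences, and read origins; `spanning_reads` decides analytically which
reads *must* produce a linking pair for a junction (a position `y` with
both k-mers inside their contigs, inside the read, and on the read's
t-grid — the grid differs between strands). On error-free reads the
pipeline recovers every spanned adjacency with the exact gap length and,
in fill mode, the exact gap sequence; with errors the per-junction fill
identity degrades gracefully and is reported rather than asserted.

## Known limitations

- One read fills each gap; no multi-read consensus, so raw-read error
  rates appear verbatim in filled gaps.
- Greedy extension with a local ambiguity rule; no global path or
  matching optimisation.
- Repeated k-mers are discarded, not resolved: junctions with fully
  repetitive flanks longer than a read cannot be linked.
- Error-tolerant (profile-based) k-mer matching is out of scope; every
  error in a read invalidates k affected k-mers.
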