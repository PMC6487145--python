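"""Algorithm parameters.

All tunables of the scaffolding pipeline live in a single frozen
:class:`Parameters` object so that every stage sees one consistent
configuration and a run is fully described by (inputs, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True)
class Parameters:
    """Tunable parameters of the linking pipeline.

    Attributes
    ----------
    k:
        k-mer length in bases. Must be odd and >= 3; odd k guarantees no
        k-mer equals its own reverse complement, so canonical keys are
        unambiguous. Higher long-read error rates call for smaller k.
    d:
        Pair distance in bases, measured start-of-first-k-mer to
        start-of-second-k-mer on the read.
    t:
        Sliding step in bases between successive pair start positions on a
        read (1 generates the full set of pairs; larger t subsamples).
    min_pair_links:
        Edge filter 1 — minimum number of k-mer pairs on an edge.
    min_read_links:
        Edge filter 2 — minimum number of distinct reads supporting an edge.
    per_read_pair_min:
        A read counts as "strong" for an edge iff its pair count on that
        edge is strictly greater than this value.
    min_strong_reads:
        Edge filter 3 — minimum number of strong reads on an edge.
    ratio_threshold:
        Ambiguity threshold for scaffold extension: with several candidate
        neighbours, the best one is accepted only if every competing
        candidate's share of the pair count is below this value.
    gap_fill:
        When true, positive gaps are filled with a fragment of the
        best-supported long read instead of a run of ``N``.
    bloom_fpr_target:
        Target false-positive rate used to size the Bloom filter.
    seed:
        Seed for randomized components (simulation only; the linking
        pipeline itself is deterministic).
    """

    k: int = 15
    d: int = 4000
    t: int = 2
    min_pair_links: int = 1
    min_read_links: int = 1
    per_read_pair_min: int = 1
    min_strong_reads: int = 1
    ratio_threshold: float = 0.3
    gap_fill: bool = False
    bloom_fpr_target: float = 0.01
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.k < 3 or self.k % 2 == 0:
            raise ValueError(f"k must be an odd integer >= 3, got {self.k}")
        if self.d <= self.k:
            raise ValueError(f"d must exceed k ({self.k}), got {self.d}")
        if self.t < 1:
            raise ValueError(f"t must be >= 1, got {self.t}")
        if not (0.0 < self.ratio_threshold < 1.0):
            raise ValueError(
                f"ratio_threshold must lie in (0, 1), got {self.ratio_threshold}"
            )
        for name in ("min_pair_links", "min_read_links",
                     "per_read_pair_min", "min_strong_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not (0.0 < self.bloom_fpr_target < 1.0):
            raise ValueError(
                f"bloom_fpr_target must lie in (0, 1), got {self.bloom_fpr_target}"
            )
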