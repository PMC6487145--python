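"""Show gap filling: the N run is replaced by a long-read fragment.

With gap filling on, the junction's N run is replaced by the fragment of
the read that supports the junction with the most k-mer pairs, cut at the
read coordinates where the left contig ends.
"""

import dataclasses

from kmerlink import link_contigs, tiny_example

contigs, reads, params = tiny_example()

plain = link_contigs(contigs, reads, params)
filled = link_contigs(contigs, reads, dataclasses.replace(params, gap_fill=True))

gap = filled.gap_records[0][0]
print("without gap fill:", plain.scaffolds[0].sequence)
print("with gap fill   :", filled.scaffolds[0].sequence)
print(f"fill read: {gap.fill_read_id}, read interval "
      f"[{gap.fill_interval[0]}, {gap.fill_interval[1]}), "
      f"inserted fragment: {gap.rendered!r}")
print()
print("The chosen read supports the junction with 3 k-mer pairs (the")
print("runner-up has 1), so its bases replace the 3 estimated N's.")
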