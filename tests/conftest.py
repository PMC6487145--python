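import pytest

from kmerlink import tiny_example


@pytest.fixture
def tiny():
    """Five contigs, seven reads, k=5/d=10/t=1 parameters."""
    contigs, reads, params = tiny_example()
    return contigs, reads, params


@pytest.fixture
def tiny_files(tmp_path, tiny):
    """The tiny dataset written to FASTA/FASTQ files."""
    contigs, reads, _params = tiny
    contig_path = tmp_path / "contigs.fasta"
    reads_path = tmp_path / "reads.fastq"
    with open(contig_path, "wt") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n{c.sequence}\n")
    with open(reads_path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
    return contig_path, reads_path
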