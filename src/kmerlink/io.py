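"""Sequence input/output and strand utilities.

FASTA (contigs, scaffolds) and FASTQ (long reads) are parsed with
Bio.SeqIO; gzip compression is detected from magic bytes. Sequences are
case-folded to uppercase DNA over {A, C, G, T, N} at parse time. Internal
coordinates throughout the package are 0-based, half-open.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Union

from Bio import SeqIO

__all__ = [
    "SeqRecord",
    "InputFormatError",
    "read_sequences",
    "reverse_complement",
    "write_scaffolds",
]

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_FASTA_WIDTH = 80


class InputFormatError(ValueError):
    """Raised when an input sequence file cannot be parsed or validated."""


@dataclass(frozen=True)
class SeqRecord:
    """A named DNA sequence (contig, read, or scaffold)."""

    id: str
    sequence: str
    source: str = "contig"  # "contig" | "read" | "scaffold"
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


def reverse_complement(s: str) -> str:
    """Watson–Crick reverse complement; ``N`` maps to ``N``."""
    if not set(s) <= _VALID_BASES:
        bad = sorted(set(s) - _VALID_BASES)
        raise ValueError(f"invalid DNA characters: {bad}")
    return s.translate(_COMPLEMENT)[::-1]


def _rc(s: str) -> str:
    # hot-path variant without validation (inputs validated at parse time)
    return s.translate(_COMPLEMENT)[::-1]


def _open_text(path: Union[str, Path]) -> _io.TextIOBase:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(handle: _io.TextIOBase) -> str:
    pos = handle.tell()
    first = ""
    for line in handle:
        if line.strip():
            first = line.lstrip()[0]
            break
    handle.seek(pos)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    return ""


def read_sequences(path: Union[str, Path], kind: str = "contig") -> List[SeqRecord]:
    """Read a FASTA (or, for reads, FASTQ) file into :class:`SeqRecord` s.

    Records are returned in file order; that order is the canonical input
    order used for all deterministic tie-breaking downstream. Sequences are
    uppercased and validated against the DNA alphabet {A, C, G, T, N}.
    Quality strings of FASTQ input are ignored (the linking algorithm does
    not use them).

    Parameters
    ----------
    path:
        FASTA or FASTQ file, optionally gzip-compressed.
    kind:
        ``"contig"`` (FASTA only) or ``"read"`` (FASTA or FASTQ).
    """
    if kind not in ("contig", "read"):
        raise ValueError(f"kind must be 'contig' or 'read', got {kind!r}")
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"{path}: file does not exist")
    handle = _open_text(path)
    with handle:
        fmt = _sniff_format(handle)
        if fmt == "":
            # empty (or whitespace-only) file is an empty collection
            if handle.read().strip() == "":
                return []
            raise InputFormatError(
                f"{path}: not recognized as FASTA or FASTQ (first record "
                f"must start with '>' or '@')"
            )
        if fmt == "fastq" and kind == "contig":
            raise InputFormatError(f"{path}: contigs must be FASTA, got FASTQ")
        records: List[SeqRecord] = []
        seen_ids = set()
        try:
            for rec in SeqIO.parse(handle, fmt):
                seq = str(rec.seq).upper()
                if not seq:
                    raise InputFormatError(
                        f"{path}: record {rec.id!r} has an empty sequence"
                    )
                if not set(seq) <= _VALID_BASES:
                    bad = sorted(set(seq) - _VALID_BASES)
                    raise InputFormatError(
                        f"{path}: record {rec.id!r} contains invalid "
                        f"characters {bad}"
                    )
                if rec.id in seen_ids:
                    raise InputFormatError(
                        f"{path}: duplicate record id {rec.id!r}"
                    )
                seen_ids.add(rec.id)
                records.append(SeqRecord(id=rec.id, sequence=seq, source=kind))
        except ValueError as exc:
            if isinstance(exc, InputFormatError):
                raise
            raise InputFormatError(f"{path}: malformed {fmt} record: {exc}") from exc
    return records


def write_fasta(records: Iterable[SeqRecord], path: Union[str, Path]) -> None:
    """Write records as 80-column-wrapped FASTA."""
    with open(path, "wt") as out:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            out.write(header + "\n")
            seq = rec.sequence
            for i in range(0, len(seq), _FASTA_WIDTH):
                out.write(seq[i : i + _FASTA_WIDTH] + "\n")


def write_scaffolds(scaffolds: Iterable[SeqRecord], path: Union[str, Path]) -> None:
    """Write rendered scaffold sequences to FASTA.

    Scaffold ids are assigned ``scaffold_1..scaffold_n`` in construction
    order; each description lists the member contigs with orientations.
    """
    write_fasta(scaffolds, path)


def write_fastq(records: Iterable[SeqRecord], path: Union[str, Path]) -> None:
    """Write records as FASTQ with uniform placeholder qualities."""
    with open(path, "wt") as out:
        for rec in records:
            out.write(f"@{rec.id}\n{rec.sequence}\n+\n{'I' * len(rec.sequence)}\n")
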