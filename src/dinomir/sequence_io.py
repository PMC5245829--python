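"""Sequence I/O and the collapsed-read representation.

All nucleotide sequences are handled in DNA space: ``U`` is normalized to
``T`` on input and everything is upper-cased, so a single canonical alphabet
``{A, C, G, T, N}`` flows through the whole pipeline. Coordinates are
0-based, half-open.

Collapsed reads (unique sequence + copy number) use the fastx-collapser
style FASTA header dialect ``seq{rank}_x{count}``, with rank 1..N assigned
by descending count and ties broken by sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NORMALIZE = str.maketrans("acgtnuU", "ACGTNTT")


class FormatError(ValueError):
    """A sequence file violates its format contract."""


def normalize_seq(seq: str) -> str:
    """Upper-case and map RNA ``U`` to DNA ``T``."""
    return seq.translate(_NORMALIZE)


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N.

    Raises ``ValueError`` on characters outside the alphabet.
    """
    if not set(seq) <= ALPHABET:
        bad = sorted(set(seq) - ALPHABET)
        raise ValueError(f"non-alphabet characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Read:
    """One sequencing read."""

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )


@dataclass(frozen=True)
class CollapsedRead:
    """A unique sequence with its copy count in the library."""

    seq: str
    count: int
    id: str = ""

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("collapsed read count must be >= 1")


@dataclass
class ReferenceSet:
    """A named set of reference sequences (rRNA, tRNA, organelle, ...)."""

    name: str
    records: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [rid for rid, _ in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"reference set {self.name!r}: duplicate ids")
        for rid, seq in self.records:
            if not seq:
                raise ValueError(f"reference set {self.name!r}: {rid!r} is empty")

    @classmethod
    def from_fasta(cls, name: str, path: str | Path) -> "ReferenceSet":
        return cls(name=name, records=list(read_fasta(path)))


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream reads from a 4-line-record FASTQ file (Phred+33).

    Sequences are normalized (U->T, upper case). Malformed records raise
    :class:`FormatError` naming the (0-based) record index.
    """
    index = 0
    parser = SeqIO.parse(str(path), "fastq")
    while True:
        try:
            rec = next(parser)
        except StopIteration:
            return
        except ValueError as exc:
            raise FormatError(f"malformed FASTQ record at index {index}: {exc}") from exc
        quals = rec.letter_annotations.get("phred_quality", [])
        qual = "".join(chr(q + 33) for q in quals)
        try:
            yield Read(id=rec.id, seq=normalize_seq(str(rec.seq)), qual=qual)
        except ValueError as exc:
            raise FormatError(f"malformed FASTQ record at index {index}: {exc}") from exc
        index += 1


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = read.qual if read.qual is not None else "I" * len(read.seq)
            fh.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Stream ``(id, seq)`` records from FASTA; multi-line and CRLF tolerated.

    A sequence line before any header raises :class:`FormatError`. An empty
    record (two adjacent headers) is yielded with an empty sequence and a
    warning, matching lenient FASTA readers.
    """
    header: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    yield _emit_fasta_record(header, chunks)
                header = line[1:].split()[0] if len(line) > 1 else ""
                chunks = []
            else:
                if header is None:
                    raise FormatError(
                        f"{path}: sequence data at line {lineno} before any '>' header"
                    )
                chunks.append(line)
    if header is not None:
        yield _emit_fasta_record(header, chunks)


def _emit_fasta_record(header: str, chunks: list[str]) -> tuple[str, str]:
    seq = normalize_seq("".join(chunks))
    if not seq:
        warnings.warn(f"FASTA record {header!r} has an empty sequence", stacklevel=3)
    return header, seq


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def rank_collapsed(collapsed: Iterable[CollapsedRead]) -> list[CollapsedRead]:
    """Assign ``seq{rank}_x{count}`` ids, ordered by count desc then sequence."""
    ordered = sorted(collapsed, key=lambda cr: (-cr.count, cr.seq))
    return [
        CollapsedRead(seq=cr.seq, count=cr.count, id=f"seq{rank}_x{cr.count}")
        for rank, cr in enumerate(ordered, 1)
    ]


def write_collapsed_fasta(collapsed: Iterable[CollapsedRead], path: str | Path) -> None:
    """Write collapsed reads as FASTA with ``seq{rank}_x{count}`` headers."""
    ranked = rank_collapsed(collapsed)
    write_fasta(((cr.id, cr.seq) for cr in ranked), path)


def read_collapsed_fasta(path: str | Path) -> list[CollapsedRead]:
    """Read a collapsed FASTA; the ``_x{count}`` suffix carries the count."""
    out: list[CollapsedRead] = []
    for rid, seq in read_fasta(path):
        try:
            count = int(rid.rsplit("_x", 1)[1])
        except (IndexError, ValueError) as exc:
            raise FormatError(
                f"collapsed FASTA header {rid!r} lacks a parseable _x<count> suffix"
            ) from exc
        out.append(CollapsedRead(seq=seq, count=count, id=rid))
    return out
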