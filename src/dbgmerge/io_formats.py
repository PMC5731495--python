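"""FASTA/FASTQ input and output, plus Phred quality trimming of reads.

Parsing and serialisation are delegated to :mod:`Bio.SeqIO`; this module adds
the normalisation contract used throughout the package (uppercase, RNA ``U``
mapped to ``T``), transparent gzip support keyed on the ``.gz`` extension,
and the read-trimming rule: a read is cut immediately before the first base
whose quality score falls below the threshold (default 15).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = [
    "SeqRecord",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "trim_read",
    "trim_fastq",
]

_NORMALIZE = str.maketrans("acgtunU", "ACGTTNT")


class FastaFormatError(ValueError):
    """Raised when a sequence file violates basic format expectations."""


@dataclass
class SeqRecord:
    """A named DNA sequence with optional per-base Phred qualities."""

    id: str
    seq: str
    qual: list[int] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _normalize(seq: str) -> str:
    return seq.translate(_NORMALIZE)


def _open_text(path: str | Path, mode: str) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fasta(path: str | Path) -> Iterator[SeqRecord]:
    """Yield normalised records from a (possibly gzipped) FASTA file.

    Sequences are uppercased and ``U`` is mapped to ``T`` so that downstream
    k-mer logic only ever sees the alphabet ``{A, C, G, T, N}``.

    Raises
    ------
    FastaFormatError
        If a record has an empty header or an empty sequence.
    """
    with _open_text(path, "r") as handle:
        for i, rec in enumerate(SeqIO.parse(handle, "fasta")):
            if not rec.id:
                raise FastaFormatError(f"{path}: record #{i + 1} has an empty header")
            seq = _normalize(str(rec.seq))
            if not seq:
                raise FastaFormatError(f"{path}: record {rec.id!r} has an empty sequence")
            yield SeqRecord(id=rec.id, seq=seq)


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with sequence lines wrapped at ``width``."""
    if width < 1:
        raise ValueError("width must be positive")
    with _open_text(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(_BioRecord(Seq(r.seq), id=r.id, description="") for r in records)


def _fastq_format(offset: int) -> str:
    if offset == 33:
        return "fastq"
    if offset == 64:
        return "fastq-illumina"
    raise ValueError(f"unsupported Phred offset {offset}; use 33 or 64")


def read_fastq(path: str | Path, phred_offset: int = 33) -> Iterator[SeqRecord]:
    """Yield normalised reads (with integer qualities) from a FASTQ file."""
    fmt = _fastq_format(phred_offset)
    with _open_text(path, "r") as handle:
        for rec in SeqIO.parse(handle, fmt):
            yield SeqRecord(
                id=rec.id,
                seq=_normalize(str(rec.seq)),
                qual=list(rec.letter_annotations["phred_quality"]),
            )


def write_fastq(records: Iterable[SeqRecord], path: str | Path, phred_offset: int = 33) -> None:
    fmt = _fastq_format(phred_offset)
    with _open_text(path, "w") as handle:
        for r in records:
            if r.qual is None:
                raise ValueError(f"record {r.id!r} has no quality scores")
            bio = _BioRecord(Seq(r.seq), id=r.id, description="")
            bio.letter_annotations["phred_quality"] = r.qual
            SeqIO.write(bio, handle, fmt)


def trim_read(rec: SeqRecord, threshold: int = 15) -> SeqRecord:
    """Trim a read at the first base whose quality drops below ``threshold``.

    The returned record is the prefix of ``rec`` strictly before the first
    position with quality < ``threshold`` (the whole read when no such
    position exists).  The result may be empty.
    """
    if rec.qual is None:
        raise ValueError(f"record {rec.id!r} has no quality scores")
    cut = len(rec.seq)
    for i, q in enumerate(rec.qual):
        if q < threshold:
            cut = i
            break
    return SeqRecord(id=rec.id, seq=rec.seq[:cut], qual=rec.qual[:cut])


def trim_fastq(
    records: Iterable[SeqRecord],
    threshold: int = 15,
    min_len: int = 0,
    keep_empty: bool = False,
) -> Iterator[SeqRecord]:
    """Apply :func:`trim_read` to a stream of reads.

    Reads trimmed below ``min_len`` are dropped; zero-length reads are
    dropped unless ``keep_empty`` is set (empty records break many
    downstream tools).
    """
    for rec in records:
        trimmed = trim_read(rec, threshold)
        if len(trimmed) < max(min_len, 0 if keep_empty else 1):
            continue
        yield trimmed
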