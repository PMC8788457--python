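"""Readers and writers for the formats the pipeline touches.

All file handling lives here: FASTQ / FASTA (plain or gzipped, detected by
magic bytes) come in through :func:`read_fastq` / :func:`read_fasta`, and every
report leaves through :func:`write_csv_table`.  Downstream modules only ever
see :class:`Read` and :class:`SequenceSet` objects.
"""

from __future__ import annotations

import csv
import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

READ_ALPHABET = set("ACGTUN")
REFERENCE_ALPHABET = set("ACGU")

#: Sanger / modern-Illumina quality encoding. Fixed on purpose: no +64
#: auto-detection; anything else is a documented input error.
PHRED_OFFSET = 33
MAX_PHRED = 93


class FormatError(ValueError):
    """Raised for malformed or invalid input files."""


@dataclass
class Read:
    """One sequencing read with per-base qualities.

    ``count`` stays 1 until :func:`clashkit.preprocess.collapse_reads` merges
    identical molecules; ``members`` then lists the ids of the merged reads.
    """

    read_id: str
    sequence: str
    qualities: list[int]
    umi: str = ""
    count: int = 1
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise FormatError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        if any(q < 0 or q > MAX_PHRED for q in self.qualities):
            raise FormatError(f"read {self.read_id!r}: Phred score outside [0, {MAX_PHRED}]")
        bad = set(self.sequence) - READ_ALPHABET
        if bad:
            raise FormatError(f"read {self.read_id!r}: invalid characters {sorted(bad)}")
        if self.count < 1:
            raise FormatError(f"read {self.read_id!r}: count must be >= 1")

    @property
    def mean_quality(self) -> float:
        return sum(self.qualities) / len(self.qualities) if self.qualities else 0.0


@dataclass
class SequenceSet:
    """An ordered, name-unique reference set (regulatory or target RNAs).

    Sequences are RNA (T normalized to U on load); N is not allowed in
    references.
    """

    role: str
    names: list[str]
    sequences: dict[str, str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ("regulatory", "target"):
            raise ValueError(f"role must be 'regulatory' or 'target', got {self.role!r}")
        for name in self.names:
            seq = self.sequences[name]
            if not seq:
                raise FormatError(f"reference {name!r} ({self.role}): empty sequence")
            bad = set(seq) - REFERENCE_ALPHABET
            if bad:
                raise FormatError(
                    f"reference {name!r} ({self.role}): invalid characters {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def items(self) -> Iterator[tuple[str, str]]:
        for name in self.names:
            yield name, self.sequences[name]


def _open_maybe_gzip(path: str | Path, mode: str = "rt"):
    """Open plain or gzipped text, sniffing the gzip magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream reads from a FASTQ or FASTQ.gz file (Sanger +33 qualities).

    Yields records in file order; raises :class:`FormatError` naming the
    1-based record index for malformed records.
    """
    with _open_maybe_gzip(path) as handle:
        index = 0
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                index += 1
                if len(seq) != len(qual):
                    raise FormatError(
                        f"{path}: record {index}: sequence and quality lengths differ"
                    )
                read_id = title.split(None, 1)[0]
                quals = [ord(c) - PHRED_OFFSET for c in qual]
                try:
                    yield Read(read_id, seq.upper(), quals)
                except FormatError as exc:
                    raise FormatError(f"{path}: record {index}: {exc}") from exc
        except ValueError as exc:
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"{path}: record {index + 1}: {exc}") from exc


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    """Write reads as 4-line FASTQ (gzipped when the path ends in .gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as out:
        for read in reads:
            qual = "".join(chr(q + PHRED_OFFSET) for q in read.qualities)
            out.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")


def read_fasta(path: str | Path, role: str) -> SequenceSet:
    """Load a reference FASTA (plain or gzipped) as a :class:`SequenceSet`.

    Names are the header up to the first whitespace (full header kept as the
    description); T is normalized to U. Duplicate names and empty sequences
    are errors.
    """
    names: list[str] = []
    sequences: dict[str, str] = {}
    descriptions: dict[str, str] = {}
    with _open_maybe_gzip(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            name = header.split(None, 1)[0] if header.strip() else ""
            if not name:
                raise FormatError(f"{path}: FASTA record with empty header")
            if name in sequences:
                raise FormatError(f"{path}: duplicate sequence name {name!r}")
            names.append(name)
            sequences[name] = seq.upper().replace("T", "U")
            descriptions[name] = header
    return SequenceSet(role=role, names=names, sequences=sequences, descriptions=descriptions)


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as out:
        for name, seq in entries:
            out.write(f">{name}\n{seq}\n")


def write_csv_table(
    rows: Iterable[Sequence], header: Sequence[str], path: str | Path
) -> None:
    """Write an RFC-4180 CSV with a header row.

    Rows are written in the order given; callers are responsible for the
    documented sort key of each table.
    """
    path = Path(path)
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, lineterminator="\r\n")
        writer.writerow(list(header))
        for row in rows:
            if len(row) != len(header):
                raise ValueError(
                    f"{path}: row has {len(row)} fields, header has {len(header)}"
                )
            writer.writerow(list(row))


def format_csv(rows: Iterable[Sequence], header: Sequence[str]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\r\n")
    writer.writerow(list(header))
    for row in rows:
        writer.writerow(list(row))
    return buf.getvalue()
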