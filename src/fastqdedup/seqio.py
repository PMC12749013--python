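"""Streaming FASTQ/FASTA readers and writers, plain or gzip-compressed.

The FASTQ dialect is strict 4-line records (modern sequencer output);
multi-line FASTQ is rejected.  FASTA sequences may span multiple lines and
are concatenated.  Trailing CR is stripped on input (CRLF tolerance); output
uses LF.  Record identifiers, comments, sequences and qualities pass through
byte-identically: parsing a written file reproduces every field.

Gzip output is written with a zeroed mtime and no embedded filename so that
identical record streams produce byte-identical files.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Literal

from .errors import ContractViolationError, MalformedInputError, PairSyncError
from .records import DedupUnit, SeqRecord

GZIP_MAGIC = b"\x1f\x8b"

FormatName = Literal["fastq", "fasta"]
CompressionName = Literal["none", "gzip", "auto"]


@dataclass(frozen=True)
class FormatSpec:
    """File format (fastq/fasta) and compression (none/gzip/auto).

    ``auto`` resolves to gzip iff the file starts with the gzip magic bytes
    0x1F 0x8B.
    """

    format: FormatName = "fastq"
    compression: CompressionName = "auto"


def infer_format(path: str | os.PathLike[str]) -> FormatName:
    """Guess fastq/fasta from the file extension (``.gz`` suffix ignored)."""
    name = os.fspath(path).lower()
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fasta", ".fa", ".fna", ".ffn", ".frn")):
        return "fasta"
    return "fastq"


def detect_compression(path: str | os.PathLike[str]) -> Literal["none", "gzip"]:
    """Return ``gzip`` iff the file begins with the gzip magic bytes."""
    with open(path, "rb") as fh:
        return "gzip" if fh.read(2) == GZIP_MAGIC else "none"


def _resolve(path: str | os.PathLike[str], spec: FormatSpec) -> Literal["none", "gzip"]:
    if spec.compression == "auto":
        return detect_compression(path)
    return spec.compression


def open_text_read(path: str | os.PathLike[str], spec: FormatSpec) -> IO[str]:
    if _resolve(path, spec) == "gzip":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="latin-1", newline="")
    return open(path, "r", encoding="latin-1", newline="")


def open_text_write(path: str | os.PathLike[str], spec: FormatSpec) -> IO[str]:
    if spec.compression == "gzip":
        raw = open(path, "wb")
        gz = gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)
        return io.TextIOWrapper(_Chained(gz, raw), encoding="latin-1", newline="")
    return open(path, "w", encoding="latin-1", newline="")


class _Chained(io.RawIOBase):
    """Write-through to a GzipFile that also closes the underlying raw file."""

    def __init__(self, gz: gzip.GzipFile, raw: IO[bytes]) -> None:
        self._gz = gz
        self._raw = raw

    def writable(self) -> bool:
        return True

    def write(self, b) -> int:  # type: ignore[override]
        return self._gz.write(b)

    def close(self) -> None:
        if not self.closed:
            self._gz.close()
            self._raw.close()
        super().close()


def _clean(line: str) -> str:
    if line.endswith("\n"):
        line = line[:-1]
    if line.endswith("\r"):
        line = line[:-1]
    return line


def _split_header(line: str) -> tuple[str, str | None]:
    body = line[1:]
    for i, ch in enumerate(body):
        if ch in (" ", "\t"):
            return body[:i], body[i + 1 :]
    return body, None


def _as_text(stream) -> IO[str]:
    if isinstance(stream, io.TextIOBase):
        return stream
    return io.TextIOWrapper(stream, encoding="latin-1", newline="")


def parse_records(stream, spec: FormatSpec) -> Iterator[SeqRecord]:
    """Yield :class:`SeqRecord` objects from a FASTQ or FASTA text/byte stream.

    FASTQ is parsed as strict 4-line blocks; a truncated trailing block or a
    sequence/quality length mismatch raises :class:`MalformedInputError`
    naming the record ordinal.
    """
    text = _as_text(stream)
    if spec.format == "fastq":
        yield from _parse_fastq(text)
    elif spec.format == "fasta":
        yield from _parse_fasta(text)
    else:  # pragma: no cover - guarded by FormatSpec typing
        raise ValueError(f"unknown format {spec.format!r}")


def _parse_fastq(text: IO[str]) -> Iterator[SeqRecord]:
    ordinal = 0
    while True:
        raw = text.readline()
        if raw == "":
            return
        header = _clean(raw)
        if header == "":
            # tolerate blank line(s) at end of file only
            rest = text.read()
            if rest.strip() == "":
                return
            raise MalformedInputError(
                f"blank line before record #{ordinal + 1} in FASTQ input"
            )
        ordinal += 1
        if not header.startswith("@"):
            raise MalformedInputError(
                f"record #{ordinal}: FASTQ header does not start with '@': {header[:40]!r}"
            )
        seq_l = text.readline()
        plus_l = text.readline()
        qual_l = text.readline()
        if seq_l == "" or plus_l == "" or qual_l == "":
            raise MalformedInputError(
                f"record #{ordinal}: truncated FASTQ block (expected 4 lines)"
            )
        sequence = _clean(seq_l)
        if not _clean(plus_l).startswith("+"):
            raise MalformedInputError(
                f"record #{ordinal}: FASTQ separator line does not start with '+'"
            )
        quality = _clean(qual_l)
        if len(quality) != len(sequence):
            raise MalformedInputError(
                f"record #{ordinal}: sequence length {len(sequence)} != "
                f"quality length {len(quality)}"
            )
        rid, comment = _split_header(header)
        yield SeqRecord(id=rid, sequence=sequence, quality=quality, comment=comment)


def _parse_fasta(text: IO[str]) -> Iterator[SeqRecord]:
    rid: str | None = None
    comment: str | None = None
    chunks: list[str] = []
    ordinal = 0
    for raw in text:
        line = _clean(raw)
        if line.startswith(">"):
            if rid is not None:
                yield SeqRecord(id=rid, sequence="".join(chunks), comment=comment)
            ordinal += 1
            rid, comment = _split_header(line)
            chunks = []
        elif line == "":
            continue
        else:
            if rid is None:
                raise MalformedInputError(
                    "FASTA input: sequence data before the first '>' header"
                )
            chunks.append(line)
    if rid is not None:
        yield SeqRecord(id=rid, sequence="".join(chunks), comment=comment)


def format_record(record: SeqRecord, fmt: FormatName) -> str:
    header_tail = f" {record.comment}" if record.comment is not None else ""
    if fmt == "fastq":
        if record.quality is None:
            raise ContractViolationError(
                f"record {record.id!r} has no quality string; cannot write FASTQ"
            )
        return f"@{record.id}{header_tail}\n{record.sequence}\n+\n{record.quality}\n"
    return f">{record.id}{header_tail}\n{record.sequence}\n"


def write_records(records: Iterable[SeqRecord], sink, spec: FormatSpec) -> int:
    """Write records to a text/byte sink; returns the number written."""
    text = _as_text(sink)
    n = 0
    for record in records:
        text.write(format_record(record, spec.format))
        n += 1
    text.flush()
    return n


def read_records(path: str | os.PathLike[str], spec: FormatSpec) -> Iterator[SeqRecord]:
    with open_text_read(path, spec) as fh:
        yield from parse_records(fh, spec)


def write_records_path(
    records: Iterable[SeqRecord], path: str | os.PathLike[str], spec: FormatSpec
) -> int:
    with open_text_write(path, spec) as fh:
        return write_records(records, fh, spec)


def single_reader(path: str | os.PathLike[str], spec: FormatSpec) -> Iterator[DedupUnit]:
    """Yield single-end :class:`DedupUnit` objects in file order."""
    for index, record in enumerate(read_records(path, spec)):
        yield DedupUnit(left=record, index=index)


def paired_reader(
    path_left: str | os.PathLike[str],
    path_right: str | os.PathLike[str],
    spec: FormatSpec,
) -> Iterator[DedupUnit]:
    """Pair the i-th records of two synchronized files, strictly by position.

    Files of unequal record count raise :class:`PairSyncError` reporting both
    counts; the pairing never truncates silently.
    """
    left_it = read_records(path_left, spec)
    right_it = read_records(path_right, spec)
    index = 0
    while True:
        left = next(left_it, None)
        right = next(right_it, None)
        if left is None and right is None:
            return
        if left is None or right is None:
            n_left = index + (0 if left is None else 1) + sum(1 for _ in left_it)
            n_right = index + (0 if right is None else 1) + sum(1 for _ in right_it)
            raise PairSyncError(
                f"paired inputs out of sync: {n_left} records in "
                f"{os.fspath(path_left)!r} vs {n_right} in {os.fspath(path_right)!r}"
            )
        yield DedupUnit(left=left, right=right, index=index)
        index += 1


def single_writer(
    units: Iterable[DedupUnit], path: str | os.PathLike[str], spec: FormatSpec
) -> int:
    return write_records_path((u.left for u in units), path, spec)


def paired_writer(
    units: Iterable[DedupUnit],
    path_left: str | os.PathLike[str],
    path_right: str | os.PathLike[str],
    spec: FormatSpec,
) -> tuple[int, int]:
    """Write left mates to ``path_left`` and right mates to ``path_right``.

    Every unit must carry a right mate; the two outputs stay synchronized.
    """
    n = 0
    with open_text_write(path_left, spec) as out_l, open_text_write(path_right, spec) as out_r:
        for unit in units:
            if unit.right is None:
                raise ContractViolationError(
                    f"unit #{unit.index} ({unit.left.id!r}) has no right mate"
                )
            out_l.write(format_record(unit.left, spec.format))
            out_r.write(format_record(unit.right, spec.format))
            n += 1
    return n, n
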