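"""Memory-budgeted external merge sort of read units.

Units are buffered until their estimated footprint would exceed the budget,
sorted by ``(key, original index)`` and spilled to a sorted run file; the
runs are then k-way merged into one globally sorted stream.  The ``(key,
index)`` total order makes the output independent of the budget and makes
the first occurrence in the input the lowest-sorting member of every tie
group.  Runs use a private length-prefixed binary framing and live in a
dedicated subdirectory that is removed on completion or error; cumulative
live temporary bytes stay within about twice the serialized input size.

If everything fits in one buffer the sort happens in memory and no
temporary file is created.
"""

from __future__ import annotations

import heapq
import os
import shutil
import struct
import tempfile
from dataclasses import dataclass, field
from typing import IO, Callable, Iterable, Iterator

from .errors import InternalFormatError
from .records import DedupUnit, SeqRecord

#: Fixed per-mate overhead (bytes) added to the text payload when estimating
#: how much buffered memory one unit costs.  Approximates container overhead;
#: the contract is bounded, parameterizable buffering, not byte-exact RSS.
OVERHEAD_PER_MATE = 96

MIN_BUDGET_BYTES = 16 * 1024 * 1024
DEFAULT_BUDGET_MIB = 2048

_NONE_LEN = 0xFFFFFFFF
_HEADER = struct.Struct("<QB")
_LEN = struct.Struct("<I")

KeyFn = Callable[[DedupUnit], bytes]


@dataclass(frozen=True)
class MemoryBudget:
    """User-facing RAM ceiling for the sort buffer (floor 16 MiB)."""

    bytes: int = DEFAULT_BUDGET_MIB * 1024 * 1024

    def __post_init__(self) -> None:
        if self.bytes < MIN_BUDGET_BYTES:
            raise ValueError(
                f"memory budget {self.bytes} B is below the 16 MiB floor"
            )

    @classmethod
    def from_mebibytes(cls, mib: int) -> "MemoryBudget":
        return cls(bytes=int(mib) * 1024 * 1024)


@dataclass
class RunFile:
    """One sorted temporary run on disk."""

    path: str
    n_records: int
    byte_size: int


@dataclass
class TempAccounting:
    """Byte accountant for temporary run/merge files.

    ``bytes_written`` is cumulative over the whole sort; ``peak_live_bytes``
    tracks the high-water mark of run files existing simultaneously.
    """

    bytes_written: int = 0
    live_bytes: int = 0
    peak_live_bytes: int = 0

    def wrote(self, n: int) -> None:
        self.bytes_written += n
        self.live_bytes += n
        self.peak_live_bytes = max(self.peak_live_bytes, self.live_bytes)

    def freed(self, n: int) -> None:
        self.live_bytes -= n


def unit_footprint(unit: DedupUnit) -> int:
    """Estimated buffered-memory cost of one unit, in bytes."""
    total = _mate_footprint(unit.left)
    if unit.right is not None:
        total += _mate_footprint(unit.right)
    return total


def _mate_footprint(record: SeqRecord) -> int:
    n = len(record.id) + len(record.sequence) + OVERHEAD_PER_MATE
    if record.quality is not None:
        n += len(record.quality)
    if record.comment is not None:
        n += len(record.comment)
    return n


def _dump_field(parts: list[bytes], value: str | None) -> None:
    if value is None:
        parts.append(_LEN.pack(_NONE_LEN))
    else:
        data = value.encode("latin-1")
        parts.append(_LEN.pack(len(data)))
        parts.append(data)


def _dump_unit(unit: DedupUnit, out: IO[bytes]) -> int:
    parts: list[bytes] = [_HEADER.pack(unit.index, 1 if unit.right is not None else 0)]
    for mate in (unit.left, unit.right):
        if mate is None:
            continue
        _dump_field(parts, mate.id)
        _dump_field(parts, mate.comment)
        _dump_field(parts, mate.sequence)
        _dump_field(parts, mate.quality)
    frame = b"".join(parts)
    out.write(frame)
    return len(frame)


def _read_exact(stream: IO[bytes], n: int) -> bytes:
    data = stream.read(n)
    if len(data) != n:
        raise InternalFormatError("truncated record in temporary run file")
    return data


def _load_field(stream: IO[bytes]) -> str | None:
    (length,) = _LEN.unpack(_read_exact(stream, 4))
    if length == _NONE_LEN:
        return None
    return _read_exact(stream, length).decode("latin-1")


def _load_mate(stream: IO[bytes]) -> SeqRecord:
    rid = _load_field(stream)
    comment = _load_field(stream)
    sequence = _load_field(stream)
    quality = _load_field(stream)
    if rid is None or sequence is None:
        raise InternalFormatError("corrupt mate frame in temporary run file")
    return SeqRecord(id=rid, sequence=sequence, quality=quality, comment=comment)


def _iter_run(run: RunFile) -> Iterator[DedupUnit]:
    with open(run.path, "rb") as fh:
        while True:
            head = fh.read(_HEADER.size)
            if head == b"":
                return
            if len(head) != _HEADER.size:
                raise InternalFormatError("truncated header in temporary run file")
            index, flags = _HEADER.unpack(head)
            left = _load_mate(fh)
            right = _load_mate(fh) if flags & 1 else None
            yield DedupUnit(left=left, right=right, index=index)


def _write_run(
    units: Iterable[DedupUnit], tmpdir: str, accounting: TempAccounting | None
) -> RunFile:
    fd, path = tempfile.mkstemp(prefix="run-", suffix=".bin", dir=tmpdir)
    n = 0
    size = 0
    with os.fdopen(fd, "wb", buffering=1 << 20) as out:
        for unit in units:
            size += _dump_unit(unit, out)
            n += 1
    if accounting is not None:
        accounting.wrote(size)
    return RunFile(path=path, n_records=n, byte_size=size)


def _delete_run(run: RunFile, accounting: TempAccounting | None) -> None:
    try:
        os.unlink(run.path)
    except FileNotFoundError:
        pass
    if accounting is not None:
        accounting.freed(run.byte_size)


def _budget_bytes(budget: MemoryBudget | int) -> int:
    if isinstance(budget, MemoryBudget):
        return budget.bytes
    return int(budget)


def build_runs(
    units: Iterable[DedupUnit],
    key_fn: KeyFn,
    budget: MemoryBudget | int,
    tmpdir: str,
    accounting: TempAccounting | None = None,
) -> list[RunFile]:
    """Split the unit stream into sorted run files under the memory budget.

    A unit is buffered unless adding it would push the summed
    :func:`unit_footprint` past the budget, in which case the buffer is
    sorted by ``(key_fn, index)`` and written out first.
    """
    limit = _budget_bytes(budget)
    runs: list[RunFile] = []
    buffer: list[DedupUnit] = []
    size = 0
    try:
        for unit in units:
            fp = unit_footprint(unit)
            if buffer and size + fp > limit:
                buffer.sort(key=lambda u: (key_fn(u), u.index))
                runs.append(_write_run(buffer, tmpdir, accounting))
                buffer = []
                size = 0
            buffer.append(unit)
            size += fp
        if buffer:
            buffer.sort(key=lambda u: (key_fn(u), u.index))
            runs.append(_write_run(buffer, tmpdir, accounting))
    except BaseException:
        for run in runs:
            _delete_run(run, accounting)
        raise
    return runs


def _consuming_iter(run: RunFile, accounting: TempAccounting | None) -> Iterator[DedupUnit]:
    try:
        yield from _iter_run(run)
    finally:
        _delete_run(run, accounting)


def kway_merge(
    runs: list[RunFile],
    key_fn: KeyFn,
    accounting: TempAccounting | None = None,
    max_open_files: int = 128,
) -> Iterator[DedupUnit]:
    """Merge sorted runs into one globally sorted stream.

    Holds one head record per run; ties on the key come out in ascending
    original index.  When the run count exceeds ``max_open_files``, groups of
    runs are first cascade-merged into larger runs (consumed runs are deleted
    as they drain, bounding live temporary bytes).
    """
    runs = list(runs)
    while len(runs) > max_open_files:
        group, runs = runs[:max_open_files], runs[max_open_files:]
        tmpdir = os.path.dirname(group[0].path)
        merged = heapq.merge(
            *(_consuming_iter(r, accounting) for r in group),
            key=lambda u: (key_fn(u), u.index),
        )
        runs.append(_write_run(merged, tmpdir, accounting))
    yield from heapq.merge(
        *(_consuming_iter(r, accounting) for r in runs),
        key=lambda u: (key_fn(u), u.index),
    )


def external_sort(
    units: Iterable[DedupUnit],
    key_fn: KeyFn,
    budget: MemoryBudget | int,
    tmpdir: str | None = None,
    accounting: TempAccounting | None = None,
    max_open_files: int = 128,
) -> Iterator[DedupUnit]:
    """Yield units sorted by ``(key_fn, index)`` within the memory budget.

    Output is identical for every budget at or above the floor.  If the whole
    input fits in one buffer, no temporary file is written.
    """
    limit = _budget_bytes(budget)
    buffer: list[DedupUnit] = []
    size = 0
    spill: Iterator[DedupUnit] | None = None
    workdir: str | None = None
    runs: list[RunFile] = []

    def flush() -> None:
        nonlocal buffer, size, workdir
        if workdir is None:
            workdir = tempfile.mkdtemp(prefix="extsort-", dir=tmpdir)
        buffer.sort(key=lambda u: (key_fn(u), u.index))
        runs.append(_write_run(buffer, workdir, accounting))
        buffer = []
        size = 0

    try:
        for unit in units:
            fp = unit_footprint(unit)
            if buffer and size + fp > limit:
                flush()
            buffer.append(unit)
            size += fp
        if not runs:
            buffer.sort(key=lambda u: (key_fn(u), u.index))
            yield from buffer
            return
        if buffer:
            flush()
        yield from kway_merge(runs, key_fn, accounting, max_open_files)
    finally:
        if workdir is not None:
            shutil.rmtree(workdir, ignore_errors=True)
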