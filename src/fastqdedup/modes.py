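"""The sequence-based deduplication engine.

Reads (or read pairs) are sorted by sequence with a memory-budgeted external
sort, then duplicates are removed in a single pass over the sorted stream.
Three duplicate definitions are supported:

``tight``
    Only complete sequence duplicates are removed; sequences of different
    lengths are never duplicates.  This is the default.
``loose``
    FastUniq-style prefix matching: the shorter sequence is a duplicate of
    the longer when it exactly matches the longer's prefix.  Like FastUniq,
    the result on paired-end data depends on the input file order, a
    consequence of the inherent ambiguity of prefix-based duplicate identity.
``tail_hamming``
    Two reads are duplicates when they are adjacent in the sorted stream and
    their Hamming distance is at most a user threshold ``k``.  Motivated by
    sequencing errors accumulating toward read 3' ends.  Because "is within
    Hamming distance k" is not transitive, the removed set is
    algorithm-defined: in a sorted chain A-B-C with d(A,B)<=k and d(B,C)<=k
    but d(A,C)>k, this scan removes both B and C (each compared to its
    immediate predecessor), while other valid algorithms would keep C.

For paired-end data a pair is removed only when BOTH its left and right
mates are duplicates of the corresponding mates of the reference pair.

The retained copy of every duplicate group is the one with the lowest
original input index (the sort tie-break), so output is deterministic and
``tight`` agrees with fast mode on kept IDs.  Kept units are written in
sorted order.  N and IUPAC letters are ordinary symbols in every comparison.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Literal

from . import seqio
from .errors import ContractViolationError
from .extsort import MemoryBudget, TempAccounting, external_sort
from .records import DedupUnit
from .seqio import FormatSpec

ModeName = Literal["tight", "loose", "tail_hamming"]

#: Sentinel separating left and right mate sequences in the paired-end sort
#: key; it sorts before every base letter so a prefix sorts before all of its
#: extensions.
PAIR_SENTINEL = b"\x00"


@dataclass(frozen=True)
class ComparatorSpec:
    """Duplicate definition: mode plus the Hamming threshold for tail_hamming."""

    mode: ModeName = "tight"
    hamming_max: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("tight", "loose", "tail_hamming"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.hamming_max < 0:
            raise ValueError("hamming_max must be >= 0")


@dataclass
class DedupStats:
    """Counters for one deduplication run."""

    total: int = 0
    kept: int = 0
    removed: int = 0
    temp_bytes_written: int = 0
    peak_temp_bytes: int = 0
    input_bytes: int = 0

    @property
    def percent_removed(self) -> float:
        if self.total == 0:
            return 0.0
        return 100.0 * self.removed / self.total


def sort_key(unit: DedupUnit) -> bytes:
    """Byte sort key: uppercased sequence; PE mates joined by the sentinel."""
    key = unit.left.sequence_upper.encode("latin-1")
    if unit.right is not None:
        key += PAIR_SENTINEL + unit.right.sequence_upper.encode("latin-1")
    return key


def compare_tight(a: str, b: str) -> bool:
    """Exact full-length equality; different lengths are never duplicates."""
    return a.upper() == b.upper()


def compare_loose(a: str, b: str) -> bool:
    """True when the shorter sequence equals the longer one's prefix."""
    a = a.upper()
    b = b.upper()
    if len(a) > len(b):
        a, b = b, a
    return b[: len(a)] == a


def compare_tail_hamming(a: str, b: str, k: int) -> bool:
    """True when lengths match and positional mismatches number at most ``k``.

    Hamming distance is undefined for unequal lengths, so those compare as
    non-duplicates (mirroring tight's length rule).  Exits early once the
    mismatch count exceeds ``k``.
    """
    if len(a) != len(b):
        return False
    a = a.upper()
    b = b.upper()
    if a == b:
        return True
    mismatches = 0
    for x, y in zip(a, b):
        if x != y:
            mismatches += 1
            if mismatches > k:
                return False
    return True


def unit_is_duplicate(
    candidate: DedupUnit, reference: DedupUnit, spec: ComparatorSpec
) -> bool:
    """Mode comparator on SE sequences; for PE it must hold for both mates."""
    if candidate.is_paired != reference.is_paired:
        raise ContractViolationError(
            "cannot compare single-end and paired-end units"
        )
    if spec.mode == "tight":
        cmp = compare_tight
    elif spec.mode == "loose":
        cmp = compare_loose
    else:
        cmp = lambda a, b: compare_tail_hamming(a, b, spec.hamming_max)  # noqa: E731
    if not cmp(candidate.left.sequence, reference.left.sequence):
        return False
    if candidate.right is not None:
        return cmp(candidate.right.sequence, reference.right.sequence)
    return True


def scan_dedup(
    sorted_units: Iterable[DedupUnit],
    spec: ComparatorSpec,
    stats: DedupStats | None = None,
) -> Iterator[DedupUnit]:
    """Single pass over a ``(sort_key, index)``-sorted stream, yielding kept units.

    tight/loose compare each unit to the current group representative (the
    first kept unit of the group); a non-duplicate is kept and becomes the
    new representative.  tail_hamming compares each unit to its immediate
    predecessor in the sorted stream, kept or not ("adjacent in the sorted
    file").  The first unit is always kept.  A decreasing key raises
    :class:`ContractViolationError`.
    """
    if stats is None:
        stats = DedupStats()
    adjacent = spec.mode == "tail_hamming"
    reference: DedupUnit | None = None
    prev_key: bytes | None = None
    for unit in sorted_units:
        key = sort_key(unit)
        if prev_key is not None and key < prev_key:
            raise ContractViolationError(
                f"input to scan_dedup is not sorted at unit #{unit.index}"
            )
        prev_key = key
        stats.total += 1
        if reference is not None and unit_is_duplicate(unit, reference, spec):
            stats.removed += 1
            if adjacent:
                reference = unit
            continue
        stats.kept += 1
        reference = unit
        yield unit


def run_seqbased(
    input_paths: tuple[str, ...] | list[str],
    output_paths: tuple[str, ...] | list[str],
    spec: ComparatorSpec = ComparatorSpec(),
    budget: MemoryBudget | int = MemoryBudget(),
    tmpdir: str | None = None,
    input_spec: FormatSpec | None = None,
    output_spec: FormatSpec | None = None,
) -> DedupStats:
    """Full sequence-based pipeline: read -> external sort -> scan -> write.

    ``input_paths``/``output_paths`` hold one path (single-end) or two
    (paired-end, synchronized).  Kept units are written in sorted order with
    IDs, sequences and qualities unchanged; paired outputs stay aligned.
    Returns the run statistics, including temporary-file byte accounting.
    """
    if len(input_paths) not in (1, 2) or len(input_paths) != len(output_paths):
        raise ContractViolationError(
            "expected one input/output path (SE) or two of each (PE), got "
            f"{len(input_paths)} inputs and {len(output_paths)} outputs"
        )
    paired = len(input_paths) == 2
    if input_spec is None:
        input_spec = FormatSpec(format=seqio.infer_format(input_paths[0]))
    if output_spec is None:
        compression = "gzip" if os.fspath(output_paths[0]).endswith(".gz") else "none"
        output_spec = FormatSpec(format=input_spec.format, compression=compression)

    accounting = TempAccounting()
    stats = DedupStats()
    if paired:
        units: Iterable[DedupUnit] = seqio.paired_reader(
            input_paths[0], input_paths[1], input_spec
        )
    else:
        units = seqio.single_reader(input_paths[0], input_spec)

    sorted_units = external_sort(units, sort_key, budget, tmpdir, accounting)
    kept = scan_dedup(sorted_units, spec, stats)
    try:
        if paired:
            seqio.paired_writer(kept, output_paths[0], output_paths[1], output_spec)
        else:
            seqio.single_writer(kept, output_paths[0], output_spec)
    except BaseException:
        for path in output_paths:
            try:
                os.unlink(path)
            except OSError:
                pass
        raise
    stats.temp_bytes_written = accounting.bytes_written
    stats.peak_temp_bytes = accounting.peak_live_bytes
    stats.input_bytes = sum(os.path.getsize(p) for p in input_paths)
    return stats
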