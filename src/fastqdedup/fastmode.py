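"""In-memory exact deduplication with 64-bit packed sequence keys.

Sequences are packed 16 bases per 64-bit word using a 4-bit code per
symbol, so N and the IUPAC ambiguity letters stay distinct (no collisions).
The explicit base length disambiguates sequences whose packed words are
equal.  A set of full packed keys retains the first occurrence of each
distinct sequence (or sequence pair), preserving input order; kept IDs are
identical to tight mode's.  Memory usage cannot be limited in this mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .errors import ContractViolationError, UnsupportedSymbolError
from .modes import DedupStats
from .records import DedupUnit

#: 4-bit code per nucleotide symbol (IUPAC alphabet).
SYMBOL_CODES = {
    "A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "R": 5, "Y": 6, "S": 7,
    "W": 8, "K": 9, "M": 10, "B": 11, "D": 12, "H": 13, "V": 14, "U": 15,
}

_BASES_PER_WORD = 16
_WORD_MASK = (1 << 64) - 1


@dataclass(frozen=True)
class PackedSeq:
    """Sequence packed into 64-bit words plus its explicit base length.

    Base ``i`` occupies the ``i % 16``-th nibble from the most-significant
    end of word ``i // 16``; unused trailing nibbles are zero.  The encoding
    is injective: two PackedSeq values are equal iff the source sequences
    are equal (case-insensitively).
    """

    words: tuple[int, ...]
    length: int


def pack_sequence(seq: str) -> PackedSeq:
    """Pack a nucleotide sequence; unknown symbols raise naming the position."""
    codes = SYMBOL_CODES
    words: list[int] = []
    word = 0
    filled = 0
    for pos, ch in enumerate(seq.upper()):
        code = codes.get(ch)
        if code is None:
            raise UnsupportedSymbolError(
                f"unsupported symbol {seq[pos]!r} at position {pos}"
            )
        word = ((word << 4) | code) & _WORD_MASK
        filled += 1
        if filled == _BASES_PER_WORD:
            words.append(word)
            word = 0
            filled = 0
    if filled:
        words.append(word << (4 * (_BASES_PER_WORD - filled)))
    return PackedSeq(words=tuple(words), length=len(seq))


def fast_dedup(
    units: Iterable[DedupUnit], stats: DedupStats | None = None
) -> Iterator[DedupUnit]:
    """Yield the first occurrence of each distinct sequence (pair), input order."""
    if stats is None:
        stats = DedupStats()
    seen: set = set()
    paired: bool | None = None
    for unit in units:
        if paired is None:
            paired = unit.is_paired
        elif unit.is_paired != paired:
            raise ContractViolationError(
                f"unit #{unit.index} mixes single-end and paired-end input"
            )
        key = pack_sequence(unit.left.sequence)
        if unit.right is not None:
            key = (key, pack_sequence(unit.right.sequence))
        stats.total += 1
        if key in seen:
            stats.removed += 1
            continue
        seen.add(key)
        stats.kept += 1
        yield unit


def run_fast(
    input_paths,
    output_paths,
    input_spec=None,
    output_spec=None,
) -> DedupStats:
    """Fast-mode pipeline over files: read -> fast_dedup -> write, input order."""
    import os

    from . import seqio
    from .seqio import FormatSpec

    if len(input_paths) not in (1, 2) or len(input_paths) != len(output_paths):
        raise ContractViolationError(
            "expected one input/output path (SE) or two of each (PE)"
        )
    paired = len(input_paths) == 2
    if input_spec is None:
        input_spec = FormatSpec(format=seqio.infer_format(input_paths[0]))
    if output_spec is None:
        compression = "gzip" if os.fspath(output_paths[0]).endswith(".gz") else "none"
        output_spec = FormatSpec(format=input_spec.format, compression=compression)

    stats = DedupStats()
    if paired:
        units = seqio.paired_reader(input_paths[0], input_paths[1], input_spec)
    else:
        units = seqio.single_reader(input_paths[0], input_spec)
    kept = fast_dedup(units, stats)
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
    stats.input_bytes = sum(os.path.getsize(p) for p in input_paths)
    return stats
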