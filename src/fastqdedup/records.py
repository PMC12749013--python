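"""Domain types shared by every deduplication mode.

A :class:`SeqRecord` is one sequencing read; a :class:`DedupUnit` is the unit
of deduplication — a single read for single-end data or an ordered (left,
right) pair for paired-end data, together with its 0-based position in the
input stream.  Read identifiers are never modified by any operation in this
package; the original sequence case is preserved for output while all
comparisons work on the uppercased sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, slots=True)
class SeqRecord:
    """One read: identifier, sequence, optional per-base quality string.

    ``quality`` is present iff the record came from FASTQ and always has the
    same length as ``sequence``.  ``comment`` is the remainder of the header
    line after the first whitespace, preserved verbatim.
    """

    id: str
    sequence: str
    quality: str | None = None
    comment: str | None = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    @property
    def sequence_upper(self) -> str:
        """Uppercased sequence, the form used by every comparison."""
        return self.sequence.upper()


@dataclass(frozen=True, slots=True)
class DedupUnit:
    """Unit of deduplication: a single record (SE) or a read pair (PE).

    ``index`` is the 0-based position of the unit in the original input
    stream; it is the universal tie-breaker that makes every mode's output
    deterministic and makes the first occurrence the retained copy.
    """

    left: SeqRecord
    right: SeqRecord | None = None
    index: int = 0

    @property
    def is_paired(self) -> bool:
        return self.right is not None
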