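"""Synthetic sequencing libraries with known template/duplicate structure.

The generator emulates a PCR-amplified library: unique template molecules
(i.i.d. uniform nucleotides) are each read once ("original") and then
re-observed as copies that are exact PCR duplicates, copies carrying
substitution errors biased toward the 3' end, or 3'-truncated copies
(prefix duplicates).  A :class:`TruthManifest` records every read's
template and class, so the expected behaviour of each deduplication mode is
known exactly.  The error model is substitution-only — the kind of
divergence Hamming-distance comparison can express; there are no indels,
no quality-dependent errors and no optical-duplicate geometry.

All randomness flows from explicit integer seeds; the same seed reproduces
byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from . import seqio
from .records import DedupUnit, SeqRecord
from .seqio import FormatSpec

READ_CLASSES = ("original", "exact_pcr_copy", "tail_error_copy", "truncated_copy")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF[_b] = _i

#: Constant quality symbol used for synthesized FASTQ (Phred 40).
QUALITY_CHAR = "I"


@dataclass(frozen=True)
class Template:
    """One unique molecule: an id plus one (SE) or two (PE) mate sequences."""

    id: str
    sequences: tuple[str, ...]


@dataclass(frozen=True)
class ManifestEntry:
    read_id: str
    template_id: str
    read_class: str


@dataclass
class TruthManifest:
    """Ground truth: which template each emitted read came from, and how."""

    entries: list[ManifestEntry] = field(default_factory=list)

    @property
    def n_templates(self) -> int:
        return len({e.template_id for e in self.entries})

    def class_of(self, read_id: str) -> str:
        return self._index()[read_id].read_class

    def template_of(self, read_id: str) -> str:
        return self._index()[read_id].template_id

    def _index(self) -> dict[str, ManifestEntry]:
        idx = getattr(self, "_idx", None)
        if idx is None or len(idx) != len(self.entries):
            idx = {e.read_id: e for e in self.entries}
            object.__setattr__(self, "_idx", idx)
        return idx

    def counts_by_class(self) -> dict[str, int]:
        counts = {c: 0 for c in READ_CLASSES}
        for e in self.entries:
            counts[e.read_class] += 1
        return counts

    def write_tsv(self, path: str | os.PathLike[str]) -> None:
        with open(path, "w", encoding="ascii") as fh:
            fh.write("read_id\ttemplate_id\tclass\n")
            for e in self.entries:
                fh.write(f"{e.read_id}\t{e.template_id}\t{e.read_class}\n")

    @classmethod
    def read_tsv(cls, path: str | os.PathLike[str]) -> "TruthManifest":
        manifest = cls()
        with open(path, encoding="ascii") as fh:
            header = fh.readline()
            if header.strip() != "read_id\ttemplate_id\tclass":
                raise ValueError(f"unrecognized manifest header: {header!r}")
            for line in fh:
                read_id, template_id, read_class = line.rstrip("\n").split("\t")
                manifest.entries.append(ManifestEntry(read_id, template_id, read_class))
        return manifest


@dataclass(frozen=True)
class ErrorModel:
    """Per-base substitution profile rising toward the 3' end.

    The rate is zero over the first ``tail_start`` fraction of positions and
    climbs linearly to ``max_rate`` at the final base — sequencing errors
    are enriched at read ends.  With ``max_rate=0`` every copy is exact.
    """

    max_rate: float = 0.0
    tail_start: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_rate <= 1.0:
            raise ValueError("max_rate must be in [0, 1]")
        if not 0.0 <= self.tail_start <= 1.0:
            raise ValueError("tail_start must be in [0, 1]")

    def rates(self, length: int) -> np.ndarray:
        """Substitution probability per position for a read of ``length``."""
        rates = np.zeros(length)
        if length == 0 or self.max_rate == 0.0:
            return rates
        start = int(np.floor(self.tail_start * length))
        n_tail = length - start
        if n_tail <= 0:
            return rates
        rates[start:] = np.linspace(self.max_rate / n_tail, self.max_rate, n_tail)
        return rates


def _random_seq_block(rng: np.random.Generator, total: int) -> str:
    return _BASES[rng.integers(0, 4, size=total, dtype=np.uint8)].tobytes().decode("ascii")


def generate_templates(
    n: int,
    length_range: tuple[int, int] = (100, 100),
    paired: bool = False,
    seed: int = 0,
) -> list[Template]:
    """Draw ``n`` templates with i.i.d. uniform A/C/G/T sequences.

    ``length_range`` is inclusive.  Deterministic given ``seed``.
    """
    lo, hi = length_range
    if n < 0:
        raise ValueError("template count must be >= 0")
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length range {length_range}")
    rng = np.random.default_rng(seed)
    n_mates = 2 if paired else 1
    lengths = rng.integers(lo, hi + 1, size=n * n_mates)
    block = _random_seq_block(rng, int(lengths.sum()))
    templates: list[Template] = []
    offset = 0
    for i in range(n):
        mates = []
        for j in range(n_mates):
            length = int(lengths[i * n_mates + j])
            mates.append(block[offset : offset + length])
            offset += length
        templates.append(Template(id=f"t{i:06d}", sequences=tuple(mates)))
    return templates


def _mutate(seq: str, rates: np.ndarray, rng: np.random.Generator) -> tuple[str, int]:
    """Apply positional substitutions; returns (sequence, n_substitutions)."""
    hit = rng.random(len(seq)) < rates
    n_hits = int(hit.sum())
    if n_hits == 0:
        return seq, 0
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    codes = _CODE_OF[arr[hit]]
    # shift by 1..3 mod 4 guarantees a different base at every hit position
    new_codes = (codes + rng.integers(1, 4, size=n_hits, dtype=np.uint8)) % 4
    arr[hit] = _BASES[new_codes]
    return arr.tobytes().decode("ascii"), n_hits


CopiesSpec = int | Callable[[np.random.Generator], int]


def amplify(
    templates: Sequence[Template],
    copies: CopiesSpec = 4,
    error_model: ErrorModel = ErrorModel(),
    truncation_fraction: float = 0.0,
    truncation_range: tuple[int, int] = (1, 10),
    seed: int = 0,
) -> tuple[list[tuple[SeqRecord, ...]], TruthManifest]:
    """Emit one original plus ``copies`` duplicates per template.

    Each copy is a 3'-truncated prefix with probability
    ``truncation_fraction`` (truncation length uniform over the inclusive
    ``truncation_range``); otherwise substitutions are placed by
    ``error_model`` — a copy with at least one substitution (in either mate)
    is a ``tail_error_copy``, an untouched one an ``exact_pcr_copy``.
    Returns the reads (tuples of one or two mates) and the truth manifest.
    """
    if not 0.0 <= truncation_fraction <= 1.0:
        raise ValueError("truncation_fraction must be in [0, 1]")
    t_lo, t_hi = truncation_range
    if t_lo < 1 or t_hi < t_lo:
        raise ValueError(f"invalid truncation range {truncation_range}")
    rng = np.random.default_rng(seed)
    rate_cache: dict[int, np.ndarray] = {}
    reads: list[tuple[SeqRecord, ...]] = []
    manifest = TruthManifest()

    def rates_for(length: int) -> np.ndarray:
        if length not in rate_cache:
            rate_cache[length] = error_model.rates(length)
        return rate_cache[length]

    for template in templates:
        min_len = min(len(s) for s in template.sequences)
        if t_hi >= min_len and truncation_fraction > 0.0:
            raise ValueError(
                f"truncation up to {t_hi} bases >= shortest mate ({min_len} bp) "
                f"of template {template.id}"
            )
        n_copies = copies(rng) if callable(copies) else int(copies)
        if n_copies < 0:
            raise ValueError("copies must be >= 0")
        for serial in range(n_copies + 1):
            read_id = f"{template.id}/{serial}"
            if serial == 0:
                mates = template.sequences
                read_class = "original"
            elif truncation_fraction > 0.0 and rng.random() < truncation_fraction:
                mates = tuple(
                    s[: len(s) - int(rng.integers(t_lo, t_hi + 1))]
                    for s in template.sequences
                )
                read_class = "truncated_copy"
            else:
                mutated = [_mutate(s, rates_for(len(s)), rng) for s in template.sequences]
                mates = tuple(m[0] for m in mutated)
                n_subs = sum(m[1] for m in mutated)
                read_class = "tail_error_copy" if n_subs else "exact_pcr_copy"
            reads.append(tuple(SeqRecord(id=read_id, sequence=s) for s in mates))
            manifest.entries.append(ManifestEntry(read_id, template.id, read_class))
    return reads, manifest


def emit_dataset(
    reads: Sequence[tuple[SeqRecord, ...]],
    manifest: TruthManifest,
    out_paths: Sequence[str | os.PathLike[str]],
    format_spec: FormatSpec = FormatSpec(format="fastq", compression="none"),
    manifest_path: str | os.PathLike[str] | None = None,
    seed: int = 0,
) -> list[str]:
    """Shuffle reads deterministically and write them (plus the manifest).

    ``out_paths`` holds one path (SE) or two (PE).  FASTQ qualities are a
    constant high value.  Same seed, same bytes.
    """
    n_mates = len(reads[0]) if reads else len(out_paths)
    if len(out_paths) != n_mates:
        raise ValueError(
            f"reads have {n_mates} mate(s) but {len(out_paths)} output paths given"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))

    def finalize(record: SeqRecord) -> SeqRecord:
        if format_spec.format == "fastq":
            return SeqRecord(
                id=record.id,
                sequence=record.sequence,
                quality=QUALITY_CHAR * len(record.sequence),
                comment=record.comment,
            )
        return record

    written: list[str] = []
    for mate_idx, path in enumerate(out_paths):
        records = (finalize(reads[i][mate_idx]) for i in order)
        seqio.write_records_path(records, path, format_spec)
        written.append(os.fspath(path))
    if manifest_path is not None:
        manifest.write_tsv(manifest_path)
        written.append(os.fspath(manifest_path))
    return written


def reads_as_units(reads: Sequence[tuple[SeqRecord, ...]]) -> list[DedupUnit]:
    """Convenience: wrap generated reads as DedupUnits in list order."""
    units = []
    for index, mates in enumerate(reads):
        right = mates[1] if len(mates) > 1 else None
        units.append(DedupUnit(left=mates[0], right=right, index=index))
    return units
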