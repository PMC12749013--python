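"""Shared fixtures: synthetic library builders and file helpers."""

from __future__ import annotations

import random
from pathlib import Path

import pytest

from fastqdedup.records import DedupUnit, SeqRecord
from fastqdedup.seqio import FormatSpec, read_records
from fastqdedup.synthetic import ErrorModel, amplify, emit_dataset, generate_templates


def random_record(rng: random.Random, i: int, length: int = 60) -> SeqRecord:
    seq = "".join(rng.choice("ACGTN") for _ in range(length))
    qual = "".join(chr(rng.randint(33, 74)) for _ in range(length))
    comment = f"c{i}" if rng.random() < 0.5 else None
    return SeqRecord(id=f"r{i}", sequence=seq, quality=qual, comment=comment)


def random_units(
    n: int,
    seed: int = 0,
    paired: bool = False,
    length: int = 30,
    dup_rate: float = 0.5,
) -> list[DedupUnit]:
    """Random units with a controlled share of exact repeats of earlier units."""
    rng = random.Random(seed)
    units: list[DedupUnit] = []
    for i in range(n):
        if units and rng.random() < dup_rate:
            src = rng.choice(units)
            left = SeqRecord(id=f"r{i}", sequence=src.left.sequence,
                             quality="I" * len(src.left.sequence))
            right = None
            if paired:
                right = SeqRecord(id=f"r{i}", sequence=src.right.sequence,
                                  quality="I" * len(src.right.sequence))
        else:
            seq = "".join(rng.choice("ACGT") for _ in range(length))
            left = SeqRecord(id=f"r{i}", sequence=seq, quality="I" * length)
            right = None
            if paired:
                seq2 = "".join(rng.choice("ACGT") for _ in range(length))
                right = SeqRecord(id=f"r{i}", sequence=seq2, quality="I" * length)
        units.append(DedupUnit(left=left, right=right, index=i))
    return units


def build_library(
    out_dir: Path,
    seed: int,
    n_templates: int,
    copies: int = 3,
    paired: bool = False,
    error_rate: float = 0.0,
    truncation_fraction: float = 0.0,
    length: int = 100,
    compression: str = "none",
):
    """Generate an amplified library on disk; returns (paths, units, manifest)."""
    templates = generate_templates(n_templates, (length, length), paired=paired, seed=seed)
    reads, manifest = amplify(
        templates,
        copies=copies,
        error_model=ErrorModel(max_rate=error_rate),
        truncation_fraction=truncation_fraction,
        truncation_range=(1, 10),
        seed=seed + 1,
    )
    suffix = ".fastq.gz" if compression == "gzip" else ".fastq"
    paths = [out_dir / f"lib_{seed}_1{suffix}"]
    if paired:
        paths.append(out_dir / f"lib_{seed}_2{suffix}")
    spec = FormatSpec(format="fastq", compression=compression)
    emit_dataset(reads, manifest, paths, spec, seed=seed + 2)
    units = read_units(paths)
    return [str(p) for p in paths], units, manifest


def read_units(paths) -> list[DedupUnit]:
    spec = FormatSpec(format="fastq", compression="auto")
    streams = [list(read_records(p, spec)) for p in paths]
    if len(streams) == 1:
        return [DedupUnit(left=r, index=i) for i, r in enumerate(streams[0])]
    return [
        DedupUnit(left=l, right=r, index=i)
        for i, (l, r) in enumerate(zip(streams[0], streams[1]))
    ]


def read_ids(path) -> list[str]:
    spec = FormatSpec(format="fastq", compression="auto")
    return [r.id for r in read_records(path, spec)]


@pytest.fixture
def se_units():
    return random_units(200, seed=11)


@pytest.fixture
def pe_units():
    return random_units(200, seed=12, paired=True)
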