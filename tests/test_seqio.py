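"""Parsing, writing, pairing and compression handling."""

import gzip
import io
import random

import pytest
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from fastqdedup.errors import ContractViolationError, MalformedInputError, PairSyncError
from fastqdedup.records import DedupUnit, SeqRecord
from fastqdedup.seqio import (
    FormatSpec,
    detect_compression,
    infer_format,
    open_text_write,
    paired_reader,
    paired_writer,
    parse_records,
    read_records,
    write_records,
    write_records_path,
)

from conftest import random_record

FASTQ = FormatSpec(format="fastq", compression="none")
FASTA = FormatSpec(format="fasta", compression="none")


def parse_str(text: str, spec: FormatSpec = FASTQ) -> list[SeqRecord]:
    return list(parse_records(io.StringIO(text), spec))


class TestParse:
    def test_minimal_fastq_record(self):
        recs = parse_str("@r1\nACGT\n+\nIIII\n")
        assert recs == [SeqRecord(id="r1", sequence="ACGT", quality="IIII")]

    def test_multiline_fasta_is_concatenated(self):
        recs = parse_str(">r1\nAC\nGT\n", FASTA)
        assert recs == [SeqRecord(id="r1", sequence="ACGT", quality=None)]

    @pytest.mark.parametrize(
        "text",
        ["@r1\nACGT\n+\n", "@r1\nACGT\n", "@r1\n"],
        ids=["no-quality", "no-plus", "header-only"],
    )
    def test_truncated_fastq_block_names_ordinal(self, text):
        with pytest.raises(MalformedInputError, match="#1"):
            parse_str(text)
        with pytest.raises(MalformedInputError, match="#2"):
            parse_str("@r0\nAC\n+\nII\n" + text)

    def test_quality_length_mismatch_rejected(self):
        with pytest.raises(MalformedInputError, match="#1"):
            parse_str("@r1\nACGT\n+\nIII\n")

    def test_header_comment_split_on_first_whitespace(self):
        (rec,) = parse_str("@r1 some comment here\nAC\n+\nII\n")
        assert rec.id == "r1"
        assert rec.comment == "some comment here"

    def test_crlf_line_endings_accepted(self):
        recs = parse_str("@r1\r\nACGT\r\n+\r\nIIII\r\n")
        assert recs[0].sequence == "ACGT"
        assert recs[0].quality == "IIII"

    def test_empty_sequence_record_is_legal(self):
        (rec,) = parse_str("@r1\n\n+\n\n")
        assert rec.sequence == ""
        assert rec.quality == ""

    def test_bad_header_marker_rejected(self):
        with pytest.raises(MalformedInputError):
            parse_str("r1\nACGT\n+\nIIII\n")

    def test_fasta_data_before_header_rejected(self):
        with pytest.raises(MalformedInputError):
            parse_str("ACGT\n>r1\nAC\n", FASTA)

    def test_empty_input_yields_nothing(self):
        assert parse_str("") == []
        assert parse_str("", FASTA) == []


class TestRoundTrip:
    def test_single_record_round_trip(self):
        rec = SeqRecord(id="r1", sequence="AcGtn", quality="II!~I", comment="c 1")
        sink = io.StringIO()
        assert write_records([rec], sink, FASTQ) == 1
        assert parse_str(sink.getvalue()) == [rec]

    def test_empty_write(self, tmp_path):
        path = tmp_path / "empty.fastq"
        assert write_records_path([], path, FASTQ) == 0
        assert list(read_records(path, FASTQ)) == []

    @pytest.mark.parametrize("compression", ["none", "gzip"])
    def test_thousand_random_records_round_trip(self, tmp_path, compression):
        rng = random.Random(5)
        records = [random_record(rng, i) for i in range(1000)]
        spec = FormatSpec(format="fastq", compression=compression)
        path = tmp_path / "rt.fastq"
        write_records_path(records, path, spec)
        back = list(read_records(path, FormatSpec(format="fastq", compression="auto")))
        assert back == records

    def test_round_trip_agrees_with_biopython(self, tmp_path):
        """Independent cross-check: Biopython parses our output to the same fields."""
        rng = random.Random(6)
        records = [random_record(rng, i) for i in range(100)]
        path = tmp_path / "bio.fastq"
        write_records_path(records, path, FASTQ)
        with open(path) as fh:
            bio = list(FastqGeneralIterator(fh))
        assert len(bio) == len(records)
        for (title, seq, qual), rec in zip(bio, records):
            expected_title = rec.id if rec.comment is None else f"{rec.id} {rec.comment}"
            assert (title, seq, qual) == (expected_title, rec.sequence, rec.quality)

    def test_fasta_round_trip(self, tmp_path):
        records = [SeqRecord(id="a", sequence="ACGT"), SeqRecord(id="b", sequence="")]
        path = tmp_path / "x.fasta"
        write_records_path(records, path, FASTA)
        assert list(read_records(path, FASTA)) == records

    def test_fastq_output_requires_quality(self):
        with pytest.raises(ContractViolationError):
            write_records([SeqRecord(id="a", sequence="AC")], io.StringIO(), FASTQ)

    def test_gzip_output_is_deterministic_bytes(self, tmp_path):
        rec = SeqRecord(id="r", sequence="ACGT", quality="IIII")
        spec = FormatSpec(format="fastq", compression="gzip")
        p1, p2 = tmp_path / "a.fastq.gz", tmp_path / "b.fastq.gz"
        write_records_path([rec], p1, spec)
        write_records_path([rec], p2, spec)
        assert p1.read_bytes() == p2.read_bytes()
        with gzip.open(p1, "rt") as fh:
            assert fh.read() == "@r\nACGT\n+\nIIII\n"


class TestCompressionDetection:
    def test_gzip_magic(self, tmp_path):
        path = tmp_path / "x.gz"
        with gzip.open(path, "wb") as fh:
            fh.write(b"@r\nAC\n+\nII\n")
        assert detect_compression(path) == "gzip"

    def test_plain_text(self, tmp_path):
        path = tmp_path / "x.fastq"
        path.write_text("@r\nAC\n+\nII\n")
        assert detect_compression(path) == "none"

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty"
        path.touch()
        assert detect_compression(path) == "none"

    def test_unreadable_file_raises(self, tmp_path):
        with pytest.raises(OSError):
            detect_compression(tmp_path / "missing")

    @pytest.mark.parametrize(
        "name,expected",
        [("a.fastq", "fastq"), ("a.fq.gz", "fastq"), ("a.fasta", "fasta"),
         ("a.fa.gz", "fasta"), ("a.txt", "fastq")],
    )
    def test_format_inference(self, name, expected):
        assert infer_format(name) == expected


def _write_fastq(path, ids):
    with open(path, "w") as fh:
        for rid in ids:
            fh.write(f"@{rid}\nACGT\n+\nIIII\n")


class TestPairing:
    def test_positional_pairing(self, tmp_path):
        pl, pr = tmp_path / "1.fastq", tmp_path / "2.fastq"
        _write_fastq(pl, ["a1", "a2"])
        _write_fastq(pr, ["b1", "b2"])
        units = list(paired_reader(pl, pr, FASTQ))
        assert [(u.left.id, u.right.id, u.index) for u in units] == [
            ("a1", "b1", 0), ("a2", "b2", 1)
        ]

    def test_unequal_counts_abort_with_both_counts(self, tmp_path):
        pl, pr = tmp_path / "1.fastq", tmp_path / "2.fastq"
        _write_fastq(pl, ["a1", "a2"])
        _write_fastq(pr, ["b1", "b2", "b3"])
        with pytest.raises(PairSyncError, match=r"2 .* 3 "):
            list(paired_reader(pl, pr, FASTQ))

    def test_swapping_paths_swaps_mates(self, tmp_path):
        pl, pr = tmp_path / "1.fastq", tmp_path / "2.fastq"
        _write_fastq(pl, ["a1"])
        _write_fastq(pr, ["b1"])
        fwd = list(paired_reader(pl, pr, FASTQ))
        rev = list(paired_reader(pr, pl, FASTQ))
        assert (fwd[0].left.id, fwd[0].right.id) == ("a1", "b1")
        assert (rev[0].left.id, rev[0].right.id) == ("b1", "a1")

    def test_paired_writer_round_trip(self, tmp_path):
        rng = random.Random(7)
        units = [
            DedupUnit(left=random_record(rng, i), right=random_record(rng, 1000 + i), index=i)
            for i in range(50)
        ]
        pl, pr = tmp_path / "o1.fastq", tmp_path / "o2.fastq"
        assert paired_writer(units, pl, pr, FASTQ) == (50, 50)
        back = list(paired_reader(pl, pr, FASTQ))
        assert [(u.left, u.right) for u in back] == [(u.left, u.right) for u in units]

    def test_paired_writer_empty(self, tmp_path):
        pl, pr = tmp_path / "o1.fastq", tmp_path / "o2.fastq"
        assert paired_writer([], pl, pr, FASTQ) == (0, 0)
        assert pl.read_text() == "" and pr.read_text() == ""

    def test_paired_writer_rejects_missing_mate(self, tmp_path):
        unit = DedupUnit(left=SeqRecord(id="a", sequence="AC", quality="II"))
        with pytest.raises(ContractViolationError):
            paired_writer([unit], tmp_path / "1.fastq", tmp_path / "2.fastq", FASTQ)
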