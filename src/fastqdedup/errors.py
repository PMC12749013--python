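"""Exception hierarchy.

Every error class carries a distinct process exit code so the CLI can map
failures deterministically.
"""


class FastqDedupError(Exception):
    """Base class for all errors raised by this package."""

    exit_code = 1


class MalformedInputError(FastqDedupError):
    """Input file violates the FASTQ/FASTA dialect this tool accepts."""

    exit_code = 3


class PairSyncError(FastqDedupError):
    """Paired-end input files hold different numbers of records."""

    exit_code = 4


class UnsupportedSymbolError(FastqDedupError):
    """Sequence letter outside the supported 16-symbol nucleotide alphabet."""

    exit_code = 5


class ContractViolationError(FastqDedupError):
    """Internal precondition broken (e.g. unsorted stream, mixed pairedness)."""

    exit_code = 7


class InternalFormatError(FastqDedupError):
    """Corrupt private run file produced during external sorting."""

    exit_code = 8
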