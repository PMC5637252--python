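"""Exception hierarchy shared across the pipeline."""


class RepseqPrepError(Exception):
    """Base class for all errors raised by repseqprep."""


class FormatError(RepseqPrepError):
    """A sequence file record is malformed (bad FASTQ structure, invalid
    characters, quality out of the Phred range)."""


class PairingError(FormatError):
    """FASTA/QUAL (or mate-pair) records do not line up: mismatched ids,
    mismatched lengths, or one file ending before the other."""


class InputError(RepseqPrepError):
    """A problem with an input path or its compression."""


class ConfigError(RepseqPrepError):
    """The JSON pipeline configuration (or an element panel / CSV table)
    failed validation."""


class ContractError(RepseqPrepError):
    """An operation was invoked on a read that violates its precondition,
    e.g. a quality-based filter on a read without quality scores."""
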