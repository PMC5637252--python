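"""Sequence-file readers and writers.

Every input — FASTQ (Sanger / Phred+33), FASTA, or a FASTA/QUAL file pair,
optionally gzip- or bz2-compressed — is exposed as a lazy stream of
:class:`SequenceRead`, so the pipeline never holds more than a handful of
reads in memory.  Parsing of the standard formats is delegated to Biopython;
this module adds transparent decompression, strict validation (alphabet,
Phred range, FASTA/QUAL pairing) and the error contract the pipeline relies
on.

Output is FASTA (one line per sequence, ``name=value`` tag pairs in the
header) or canonical Phred+33 FASTQ; the FASTQ writer is the bit-exact
inverse of the reader on well-formed input.
"""
from __future__ import annotations

import bz2
import gzip
import io
import os
from dataclasses import dataclass, field
from itertools import zip_longest
from typing import IO, Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ContractError, FormatError, InputError, PairingError

PHRED_OFFSET = 33
MAX_PHRED = 93

_ALLOWED_CHARS = frozenset("ACGTNacgtn")

#: magic bytes used by compression sniffing
_GZIP_MAGIC = b"\x1f\x8b"
_BZ2_MAGIC = b"BZh"


@dataclass
class SequenceRead:
    """One sequencing read flowing through the pipeline.

    ``read_id`` is the first whitespace-delimited token of the header;
    ``description`` the remainder (possibly empty).  ``quality`` is a list of
    Phred scores (one per base) or ``None`` for FASTA input.  ``tags`` is an
    insertion-ordered mapping accumulated by match / dedup steps (barcode
    ids, primer ids, duplicate counts).
    """

    read_id: str
    sequence: str
    quality: Optional[list[int]] = None
    description: str = ""
    tags: dict[str, str] = field(default_factory=dict)
    pair_role: str = "single"  # single | forward | reverse

    def __len__(self) -> int:
        return len(self.sequence)

    def copy(self) -> "SequenceRead":
        return SequenceRead(
            read_id=self.read_id,
            sequence=self.sequence,
            quality=None if self.quality is None else list(self.quality),
            description=self.description,
            tags=dict(self.tags),
            pair_role=self.pair_role,
        )

    def trimmed(self, start: int, end: int) -> "SequenceRead":
        """Return a copy restricted to ``sequence[start:end]``, quality kept
        in lockstep."""
        out = self.copy()
        out.sequence = self.sequence[start:end]
        if self.quality is not None:
            out.quality = self.quality[start:end]
        return out

    def spliced(self, start: int, end: int) -> "SequenceRead":
        """Return a copy with ``[start, end)`` excised and the flanks joined."""
        out = self.copy()
        out.sequence = self.sequence[:start] + self.sequence[end:]
        if self.quality is not None:
            out.quality = self.quality[:start] + self.quality[end:]
        return out


@dataclass
class ReadSource:
    """Where and how to read sequences.

    ``format`` is one of ``fastq``, ``fasta``, ``fasta_qual``; ``compression``
    one of ``auto`` (sniff magic bytes), ``none``, ``gzip``, ``bz2``.
    """

    path: str
    format: str = "fastq"
    qual_path: Optional[str] = None
    compression: str = "auto"


def _validate_sequence(seq: str, read_id: str, index: int) -> None:
    if not _ALLOWED_CHARS.issuperset(seq):
        bad = sorted(set(seq) - _ALLOWED_CHARS)
        raise FormatError(
            f"record {index} ({read_id!r}): invalid sequence character(s) "
            f"{bad}; allowed alphabet is A,C,G,T,N (either case)"
        )


def _split_title(title: str) -> tuple[str, str]:
    parts = title.split(None, 1)
    if not parts:
        return "", ""
    return parts[0], (parts[1] if len(parts) > 1 else "")


def _open_decompressed(path: str, compression: str) -> IO[str]:
    if not os.path.exists(path):
        raise InputError(f"input file not found: {path}")
    if compression == "auto":
        with open(path, "rb") as probe:
            magic = probe.read(3)
        if magic[:2] == _GZIP_MAGIC:
            compression = "gzip"
        elif magic[:3] == _BZ2_MAGIC:
            compression = "bz2"
        else:
            compression = "none"
    if compression == "none":
        return open(path, "rt", encoding="ascii", newline=None)
    if compression == "gzip":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    if compression == "bz2":
        return io.TextIOWrapper(bz2.open(path, "rb"), encoding="ascii")
    raise InputError(f"unsupported compression {compression!r} for {path}")


def _iter_fastq(handle: IO[str], path: str) -> Iterator[SequenceRead]:
    index = 0
    iterator = FastqGeneralIterator(handle)
    while True:
        try:
            title, seq, qual = next(iterator)
        except StopIteration:
            return
        except ValueError as exc:  # Biopython's structural checks
            raise FormatError(f"{path}: malformed FASTQ at record {index}: {exc}") from exc
        read_id, desc = _split_title(title)
        _validate_sequence(seq, read_id, index)
        quality = [ord(c) - PHRED_OFFSET for c in qual]
        for q in quality:
            if q < 0 or q > MAX_PHRED:
                raise FormatError(
                    f"{path}: record {index} ({read_id!r}): quality {q} outside "
                    f"Phred+33 range [0, {MAX_PHRED}]"
                )
        yield SequenceRead(read_id=read_id, sequence=seq, quality=quality, description=desc)
        index += 1


def _iter_fasta(handle: IO[str], path: str) -> Iterator[SequenceRead]:
    for index, rec in enumerate(SeqIO.parse(handle, "fasta")):
        read_id, desc = _split_title(rec.description)
        seq = str(rec.seq)
        _validate_sequence(seq, read_id, index)
        yield SequenceRead(read_id=read_id, sequence=seq, description=desc)


def _iter_fasta_qual(
    fasta_handle: IO[str], qual_handle: IO[str], path: str, qual_path: str
) -> Iterator[SequenceRead]:
    fasta_iter = SeqIO.parse(fasta_handle, "fasta")
    qual_iter = SeqIO.parse(qual_handle, "qual")
    for index, (frec, qrec) in enumerate(zip_longest(fasta_iter, qual_iter)):
        if frec is None or qrec is None:
            longer = qual_path if frec is None else path
            raise PairingError(
                f"FASTA/QUAL record count mismatch at record {index}: "
                f"{longer} has extra records"
            )
        if frec.id != qrec.id:
            raise PairingError(
                f"FASTA/QUAL id mismatch at record {index}: "
                f"{frec.id!r} (FASTA) vs {qrec.id!r} (QUAL)"
            )
        seq = str(frec.seq)
        quality = list(qrec.letter_annotations["phred_quality"])
        if len(quality) != len(seq):
            raise PairingError(
                f"FASTA/QUAL length mismatch for record {index} ({frec.id!r}): "
                f"{len(seq)} bases vs {len(quality)} quality values"
            )
        read_id, desc = _split_title(frec.description)
        _validate_sequence(seq, read_id, index)
        for q in quality:
            if q < 0 or q > MAX_PHRED:
                raise FormatError(
                    f"{qual_path}: record {index} ({read_id!r}): quality {q} "
                    f"outside [0, {MAX_PHRED}]"
                )
        yield SequenceRead(read_id=read_id, sequence=seq, quality=quality, description=desc)


def open_read_stream(source: ReadSource) -> Iterator[SequenceRead]:
    """Yield :class:`SequenceRead` objects lazily, in file order.

    Compression is sniffed from magic bytes when ``compression == "auto"``.
    FASTA/QUAL pairs are joined record-for-record; any id, length or count
    mismatch raises :class:`PairingError`.
    """
    if source.format == "fastq":
        handle = _open_decompressed(source.path, source.compression)
        return _close_after(_iter_fastq(handle, source.path), handle)
    if source.format == "fasta":
        handle = _open_decompressed(source.path, source.compression)
        return _close_after(_iter_fasta(handle, source.path), handle)
    if source.format == "fasta_qual":
        if not source.qual_path:
            raise InputError("format 'fasta_qual' requires qual_path")
        fh = _open_decompressed(source.path, source.compression)
        qh = _open_decompressed(source.qual_path, source.compression)
        return _close_after(
            _iter_fasta_qual(fh, qh, source.path, source.qual_path), fh, qh
        )
    raise InputError(f"unsupported input format {source.format!r}")


def _close_after(it: Iterator[SequenceRead], *handles: IO[str]) -> Iterator[SequenceRead]:
    try:
        yield from it
    finally:
        for h in handles:
            h.close()


def format_fasta_record(read: SequenceRead, include_tags: bool = False) -> str:
    header = read.read_id
    if include_tags and read.tags:
        header += " " + " ".join(f"{k}={v}" for k, v in read.tags.items())
    return f">{header}\n{read.sequence}\n"


def write_fasta(reads: Iterable[SequenceRead], sink: str, include_tags: bool = False) -> int:
    """Write reads as single-line FASTA; returns the record count.

    With ``include_tags`` the header carries every accumulated tag as
    space-separated ``name=value`` pairs, in insertion order.
    """
    count = 0
    try:
        with open(sink, "w", encoding="ascii") as fh:
            for read in reads:
                fh.write(format_fasta_record(read, include_tags))
                count += 1
    except OSError as exc:
        raise InputError(f"cannot write FASTA to {sink}: {exc}") from exc
    return count


def format_fastq_record(read: SequenceRead) -> str:
    if read.quality is None:
        raise ContractError(f"read {read.read_id!r} has no quality; cannot write FASTQ")
    qual = "".join(chr(q + PHRED_OFFSET) for q in read.quality)
    title = read.read_id if not read.description else f"{read.read_id} {read.description}"
    return f"@{title}\n{read.sequence}\n+\n{qual}\n"


def write_fastq(reads: Iterable[SequenceRead], sink: str) -> int:
    """Write canonical Phred+33 FASTQ (exactly one newline after the final
    record); bit-exact inverse of :func:`open_read_stream` for well-formed
    input."""
    count = 0
    try:
        with open(sink, "w", encoding="ascii") as fh:
            for read in reads:
                fh.write(format_fastq_record(read))
                count += 1
    except OSError as exc:
        raise InputError(f"cannot write FASTQ to {sink}: {exc}") from exc
    return count
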