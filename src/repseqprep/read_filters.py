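"""Per-read filters: quality, length, ambiguous-base and homopolymer.

Each filter is a pure function ``SequenceRead -> FilterResult``.  All
thresholds are inclusive (pass means ``min <= value <= max``); absent bounds
are unbounded.  Quality filters require Phred scores and raise
:class:`~repseqprep.errors.ContractError` without them.  Trimming variants
(per-base and window quality) cut from the first offending position to the
3' end, quality kept in lockstep with the sequence; drop variants reject the
whole read.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import ContractError
from .io_formats import SequenceRead

_UNAMBIGUOUS = frozenset("ACGT")


@dataclass
class FilterResult:
    outcome: str  # "pass" | "drop"
    read: SequenceRead
    reason: Optional[str] = None

    @property
    def passed(self) -> bool:
        return self.outcome == "pass"


def _require_quality(read: SequenceRead, op: str) -> list[int]:
    if read.quality is None:
        raise ContractError(f"{op}: read {read.read_id!r} has no quality scores")
    return read.quality


def filter_average_quality(
    read: SequenceRead, min_avg: Optional[float] = None, max_avg: Optional[float] = None
) -> FilterResult:
    """Pass iff the arithmetic mean Phred quality lies in [min_avg, max_avg]."""
    qual = _require_quality(read, "average_quality")
    if not qual:
        raise ContractError(f"average_quality: read {read.read_id!r} is empty")
    mean = sum(qual) / len(qual)
    if min_avg is not None and mean < min_avg:
        return FilterResult("drop", read, "average_quality")
    if max_avg is not None and mean > max_avg:
        return FilterResult("drop", read, "average_quality")
    return FilterResult("pass", read)


def filter_per_base_quality(
    read: SequenceRead, min_q: float, action: str = "drop"
) -> FilterResult:
    """Nucleotide-level quality filter.

    ``action="drop"``: drop if any base quality < min_q.
    ``action="trim"``: truncate at the first base (5'→3') with quality < min_q.
    """
    qual = _require_quality(read, "per_base_quality")
    cut = next((i for i, q in enumerate(qual) if q < min_q), None)
    if cut is None:
        return FilterResult("pass", read)
    if action == "drop":
        return FilterResult("drop", read, "per_base_quality")
    return FilterResult("pass", read.trimmed(0, cut))


def window_quality_cut(quality: list[int], window_length: int, min_avg: float) -> Optional[int]:
    """Start position of the first sliding window (step 1, anchored 5') whose
    mean quality falls below ``min_avg``; ``None`` if every window passes.
    Reads shorter than the window are evaluated as one full-length window."""
    n = len(quality)
    w = min(window_length, n)
    if w == 0:
        return None
    running = sum(quality[:w])
    if running / w < min_avg:
        return 0
    for start in range(1, n - w + 1):
        running += quality[start + w - 1] - quality[start - 1]
        if running / w < min_avg:
            return start
    return None


def filter_window_quality(
    read: SequenceRead, window_length: int, min_avg: float, action: str = "drop"
) -> FilterResult:
    """Sliding-window mean-quality filter (window anchored at the 5' end,
    step 1).  ``drop`` rejects the read if any window fails; ``trim`` keeps
    ``[0, p)`` where p is the start of the first failing window."""
    if window_length < 1:
        raise ContractError("window_quality: window_length must be >= 1")
    qual = _require_quality(read, "window_quality")
    if not qual:
        raise ContractError(f"window_quality: read {read.read_id!r} is empty")
    cut = window_quality_cut(qual, window_length, min_avg)
    if cut is None:
        return FilterResult("pass", read)
    if action == "drop":
        return FilterResult("drop", read, "window_quality")
    return FilterResult("pass", read.trimmed(0, cut))


def filter_length(
    read: SequenceRead, min_len: Optional[int] = None, max_len: Optional[int] = None
) -> FilterResult:
    """Pass iff min_len <= len(read) <= max_len (inclusive, absent = unbounded)."""
    n = len(read.sequence)
    if (min_len is not None and n < min_len) or (max_len is not None and n > max_len):
        return FilterResult("drop", read, "length")
    return FilterResult("pass", read)


def filter_ambiguous(read: SequenceRead, max_n: int) -> FilterResult:
    """Pass iff at most ``max_n`` characters are not A/C/G/T (case-insensitive)."""
    count = sum(1 for c in read.sequence.upper() if c not in _UNAMBIGUOUS)
    if count > max_n:
        return FilterResult("drop", read, "ambiguous")
    return FilterResult("pass", read)


def longest_homopolymer(sequence: str) -> int:
    """Length of the longest run of one repeated character (case-insensitive;
    N runs count like any other)."""
    best = run = 0
    prev = ""
    for c in sequence.upper():
        run = run + 1 if c == prev else 1
        prev = c
        if run > best:
            best = run
    return best


def filter_homopolymer(read: SequenceRead, max_run: int) -> FilterResult:
    """Pass iff the longest single-nucleotide run is <= max_run (inclusive)."""
    if max_run < 1:
        raise ContractError("homopolymer: max_run must be >= 1")
    if longest_homopolymer(read.sequence) > max_run:
        return FilterResult("drop", read, "homopolymer")
    return FilterResult("pass", read)
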