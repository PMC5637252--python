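"""The *match* operation: aligning barcode / primer elements to reads.

A panel of short named elements (sample barcodes, 5' or 3' PCR primers) is
aligned against a window of each read, on the forward strand, the reverse
strand (the element is reverse-complemented, never the read), or both.  Two
scoring modes follow the classic substitution-matrix formulation:

* ``score`` — Smith-Waterman local alignment with match +2 / mismatch −2 and,
  when gaps are enabled, a linear penalty per gap position (default −3; the
  gap penalty is this package's own choice).  The best match is the
  maximal-scoring local alignment at or above a minimum-score threshold.
* ``mismatch`` — the 0-for-match / +1-for-mismatch cost matrix, realised as
  an ungapped scan over every offset at which the full element fits inside
  the window, minimising the mismatch count; a match succeeds when that
  count is at or below a maximum-mismatch threshold.

``N`` never matches anything (scores −2 / counts as a mismatch), including
another ``N``.  Ties are broken deterministically: smallest read offset,
then panel order, then forward strand before reverse.

On success the read is tagged ``tag_name=element_id`` and optionally
trimmed (everything up to the match end, everything from the match start,
or just the matched span).  Reads failing a required match are dropped.
Combinatorial barcode schemes are resolved by looking up a tuple of
previously assigned tags in a CSV table.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import ConfigError, ContractError
from .io_formats import ReadSource, SequenceRead, open_read_stream

MATCH_SCORE = 2
MISMATCH_SCORE = -2
DEFAULT_GAP_PENALTY = -3
NO_FIT = float("inf")  # mismatch-mode sentinel: element does not fit the window

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_RC = frozenset("ACGTNacgtn")


def reverse_complement(sequence: str) -> str:
    """Reverse complement over {A,C,G,T,N}, case preserved, N -> N."""
    if not _VALID_RC.issuperset(sequence):
        bad = sorted(set(sequence) - _VALID_RC)
        raise ContractError(f"reverse_complement: invalid character(s) {bad}")
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class MatchElement:
    """A named barcode or primer sequence."""

    element_id: str
    sequence: str
    source_role: str = "custom"  # barcode | primer5 | primer3 | custom

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ConfigError(f"element {self.element_id!r}: empty sequence")
        if not _VALID_RC.issuperset(self.sequence):
            raise ConfigError(
                f"element {self.element_id!r}: alphabet must be A,C,G,T,N"
            )


@dataclass
class MatchSpec:
    """Parameters of one match step (window is [start, end) on the read,
    0-based; negative start counts from the read end; end=None means the
    read end)."""

    elements: Sequence[MatchElement]
    tag_name: str
    mode: str = "score"  # score | mismatch
    threshold: float = 0.0
    strand: str = "forward"  # forward | reverse | both
    window_start: int = 0
    window_end: Optional[int] = None
    gapped: bool = False
    gap_penalty: float = DEFAULT_GAP_PENALTY
    trim: str = "none"  # none | cut_leading | cut_trailing | cut_element
    require_match: bool = True

    def __post_init__(self) -> None:
        if not self.elements:
            raise ConfigError("match: element panel is empty")
        if self.mode not in ("score", "mismatch"):
            raise ConfigError(f"match: unknown mode {self.mode!r}")
        if self.mode == "mismatch" and self.gapped:
            raise ConfigError("match: mismatch counting is defined for ungapped alignment only")
        if self.strand not in ("forward", "reverse", "both"):
            raise ConfigError(f"match: unknown strand {self.strand!r}")
        if self.trim not in ("none", "cut_leading", "cut_trailing", "cut_element"):
            raise ConfigError(f"match: unknown trim {self.trim!r}")


@dataclass
class MatchResult:
    """Outcome of aligning one element against one read window; spans are
    0-based half-open on the original read / the element."""

    element_id: str
    score: float
    mismatches: float
    read_span: tuple[int, int]
    element_span: tuple[int, int]
    strand: str


@dataclass
class MatchOutcome:
    outcome: str  # "pass" | "drop"
    read: SequenceRead
    result: Optional[MatchResult] = None
    window_outside: bool = False

    @property
    def passed(self) -> bool:
        return self.outcome == "pass"


def _bases_match(a: str, b: str) -> bool:
    a = a.upper()
    return a == b.upper() and a != "N"


# ---------------------------------------------------------------------------
# core alignment kernels
# ---------------------------------------------------------------------------

@dataclass
class _Hit:
    score: float
    mismatches: float
    seg_span: tuple[int, int]
    elem_span: tuple[int, int]


def _ungapped_local(element: str, segment: str) -> Optional[_Hit]:
    """Best ungapped local alignment (Smith-Waterman with gaps forbidden):
    Kadane's maximum-sum window on every diagonal with +2/−2 scoring.
    Ties: smaller segment offset, then smaller element offset, then shorter
    alignment."""
    m, n = len(element), len(segment)
    el = element.upper()
    sg = segment.upper()
    best: Optional[tuple[float, int, int, int, int]] = None  # score,segstart,elstart,len,mm
    for d in range(-(m - 1), n):
        i_lo, i_hi = max(0, -d), min(m, n - d)
        cur = 0
        cur_mm = 0
        start = i_lo
        for i in range(i_lo, i_hi):
            hit = el[i] == sg[i + d] and el[i] != "N"
            s = MATCH_SCORE if hit else MISMATCH_SCORE
            if cur < 0:
                cur, cur_mm, start = s, (0 if hit else 1), i
            else:
                cur += s
                cur_mm += 0 if hit else 1
            if cur > 0:
                cand = (cur, start + d, start, i - start + 1, cur_mm)
                if best is None or (-cand[0], cand[1], cand[2], cand[3]) < (
                    -best[0], best[1], best[2], best[3]
                ):
                    best = cand
    if best is None:
        return None
    score, seg_start, el_start, length, mm = best
    return _Hit(
        score=float(score),
        mismatches=float(mm),
        seg_span=(seg_start, seg_start + length),
        elem_span=(el_start, el_start + length),
    )


def _gapped_local(element: str, segment: str, gap_penalty: float) -> Optional[_Hit]:
    """Full Smith-Waterman with a linear gap penalty per gap position.
    Tie-break on the maximal cell: smallest segment end, then smallest
    element end; traceback prefers diagonal, then a gap in the segment,
    then a gap in the element."""
    m, n = len(element), len(segment)
    el = element.upper()
    sg = segment.upper()
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    best_score, best_i, best_j = 0.0, 0, 0
    for i in range(1, m + 1):
        row = H[i]
        prev = H[i - 1]
        ei = el[i - 1]
        for j in range(1, n + 1):
            sub = MATCH_SCORE if (ei == sg[j - 1] and ei != "N") else MISMATCH_SCORE
            h = max(0.0, prev[j - 1] + sub, prev[j] + gap_penalty, row[j - 1] + gap_penalty)
            row[j] = h
            if h > best_score or (h == best_score and h > 0 and (j, i) < (best_j, best_i)):
                best_score, best_i, best_j = h, i, j
    if best_score <= 0:
        return None
    # traceback
    i, j = best_i, best_j
    mm = 0
    while i > 0 and j > 0 and H[i][j] > 0:
        h = H[i][j]
        sub = MATCH_SCORE if (el[i - 1] == sg[j - 1] and el[i - 1] != "N") else MISMATCH_SCORE
        if H[i - 1][j - 1] + sub == h:
            if sub == MISMATCH_SCORE:
                mm += 1
            i, j = i - 1, j - 1
        elif H[i - 1][j] + gap_penalty == h:
            i -= 1
        elif H[i][j - 1] + gap_penalty == h:
            j -= 1
        else:  # unreachable for a consistent matrix
            break
    return _Hit(
        score=best_score,
        mismatches=float(mm),
        seg_span=(j, best_j),
        elem_span=(i, best_i),
    )


def _mismatch_scan(element: str, segment: str) -> _Hit:
    """Ungapped scan of every offset at which the full element fits inside
    the segment, minimising the mismatch count (ties: smallest offset).
    Returns a no-fit sentinel (mismatches = inf) when the element is longer
    than the segment."""
    m, n = len(element), len(segment)
    if m > n:
        return _Hit(score=NO_FIT, mismatches=NO_FIT, seg_span=(0, 0), elem_span=(0, 0))
    el = element.upper()
    sg = segment.upper()
    best_mm: Optional[int] = None
    best_off = 0
    for off in range(n - m + 1):
        mm = 0
        for i in range(m):
            a = el[i]
            if a != sg[off + i] or a == "N":
                mm += 1
                if best_mm is not None and mm > best_mm:
                    break
        else:
            if best_mm is None or mm < best_mm:
                best_mm, best_off = mm, off
                if mm == 0:
                    break
    assert best_mm is not None
    return _Hit(
        score=float(best_mm),  # in mismatch mode the "score" is the 0/+1 cost
        mismatches=float(best_mm),
        seg_span=(best_off, best_off + m),
        elem_span=(0, m),
    )


def local_align(
    element: MatchElement,
    read_segment: str,
    mode: str = "score",
    gapped: bool = False,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
) -> Optional[MatchResult]:
    """Align one element against one segment; strand handling and windowing
    belong to :func:`best_match`.  Returns ``None`` when no positive-scoring
    local alignment exists (score mode); in mismatch mode an element longer
    than the segment yields a result with ``mismatches == inf``."""
    if not element.sequence or not read_segment:
        raise ContractError("local_align: empty element or segment")
    if mode == "score":
        hit = (
            _gapped_local(element.sequence, read_segment, gap_penalty)
            if gapped
            else _ungapped_local(element.sequence, read_segment)
        )
        if hit is None:
            return None
    elif mode == "mismatch":
        if gapped:
            raise ContractError("local_align: mismatch mode is ungapped only")
        hit = _mismatch_scan(element.sequence, read_segment)
    else:
        raise ContractError(f"local_align: unknown mode {mode!r}")
    return MatchResult(
        element_id=element.element_id,
        score=hit.score,
        mismatches=hit.mismatches,
        read_span=hit.seg_span,
        element_span=hit.elem_span,
        strand="forward",
    )


# ---------------------------------------------------------------------------
# whole-read matching
# ---------------------------------------------------------------------------

def resolve_window(start: int, end: Optional[int], read_length: int) -> Optional[tuple[int, int]]:
    """Clamp a configured window to the read; negative start counts from the
    read end.  Returns ``None`` when the window misses the read entirely."""
    s = start if start >= 0 else read_length + start
    s = min(max(s, 0), read_length)
    e = read_length if end is None else min(max(end, 0), read_length)
    if s >= e:
        return None
    return s, e


def best_match(read: SequenceRead, spec: MatchSpec) -> MatchOutcome:
    """Evaluate every panel element (and strand) inside the window, pick the
    best result passing the threshold, then tag and trim the read.

    On failure with ``require_match`` the read is dropped (reason
    ``no_match:<tag_name>``); otherwise it passes through untagged.
    """
    window = resolve_window(spec.window_start, spec.window_end, len(read.sequence))
    if window is None:
        if spec.require_match:
            return MatchOutcome("drop", read, window_outside=True)
        return MatchOutcome("pass", read, window_outside=True)
    w_start, w_end = window
    segment = read.sequence[w_start:w_end]

    strands = {"forward": ("forward",), "reverse": ("reverse",), "both": ("forward", "reverse")}[
        spec.strand
    ]
    best: Optional[MatchResult] = None
    best_key: Optional[tuple] = None
    for panel_idx, element in enumerate(spec.elements):
        for strand_idx, strand in enumerate(strands):
            seq = element.sequence if strand == "forward" else reverse_complement(element.sequence)
            candidate = MatchElement(element.element_id, seq, element.source_role)
            result = local_align(candidate, segment, spec.mode, spec.gapped, spec.gap_penalty)
            if result is None:
                continue
            if spec.mode == "score":
                if result.score < spec.threshold:
                    continue
                key = (-result.score, result.read_span[0], panel_idx, strand_idx)
            else:
                if result.mismatches > spec.threshold:
                    continue
                key = (result.mismatches, result.read_span[0], panel_idx, strand_idx)
            if best_key is None or key < best_key:
                result.strand = strand
                best, best_key = result, key

    if best is None:
        if spec.require_match:
            return MatchOutcome("drop", read)
        return MatchOutcome("pass", read)

    # lift the span from window to read coordinates
    span = (best.read_span[0] + w_start, best.read_span[1] + w_start)
    best.read_span = span
    out = read.copy()
    out.tags[spec.tag_name] = best.element_id
    if spec.trim == "cut_leading":
        out = out.trimmed(span[1], len(out.sequence))
    elif spec.trim == "cut_trailing":
        out = out.trimmed(0, span[0])
    elif spec.trim == "cut_element":
        out = out.spliced(span[0], span[1])
    return MatchOutcome("pass", out, result=best)


# ---------------------------------------------------------------------------
# panels and combinatorial tables
# ---------------------------------------------------------------------------

def load_elements_fasta(path: str, source_role: str = "custom") -> list[MatchElement]:
    """Read an element panel from FASTA; the header token is the element id."""
    elements = [
        MatchElement(rec.read_id, rec.sequence, source_role)
        for rec in open_read_stream(ReadSource(path=path, format="fasta"))
    ]
    if not elements:
        raise ConfigError(f"element panel {path} contains no sequences")
    seen: set[str] = set()
    for el in elements:
        if el.element_id in seen:
            raise ConfigError(f"element panel {path}: duplicate id {el.element_id!r}")
        seen.add(el.element_id)
    return elements


@dataclass
class CombinatorialTable:
    """CSV-driven mapping from a tuple of tag values to a sample id.

    The header row names the K tag columns followed by ``sample_id``; each
    data row maps one combination of tag values to one sample.
    """

    tag_names: list[str]
    mapping: dict[tuple[str, ...], str] = field(default_factory=dict)


def load_combinatorial_csv(path: str) -> CombinatorialTable:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or len(rows[0]) < 2:
        raise ConfigError(f"{path}: combinatorial CSV needs >= 2 columns (tags..., sample_id)")
    header = [c.strip() for c in rows[0]]
    tag_names = header[:-1]
    width = len(header)
    table = CombinatorialTable(tag_names=tag_names)
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != width:
            raise ConfigError(
                f"{path}:{lineno}: expected {width} columns, found {len(row)}"
            )
        key = tuple(c.strip() for c in row[:-1])
        if key in table.mapping:
            raise ConfigError(f"{path}:{lineno}: duplicate combination {key}")
        table.mapping[key] = row[-1].strip()
    return table


def resolve_combinatorial(
    read: SequenceRead,
    table: CombinatorialTable,
    tag_names: Optional[Sequence[str]] = None,
    out_tag: str = "sample",
) -> SequenceRead:
    """Set ``tags[out_tag]`` to the sample id when every component tag is
    present and the tuple is in the table; otherwise leave the read
    untouched (it will route to the unmatched output)."""
    names = list(tag_names) if tag_names is not None else table.tag_names
    try:
        key = tuple(read.tags[name] for name in names)
    except KeyError:
        return read
    sample = table.mapping.get(key)
    if sample is None:
        return read
    out = read.copy()
    out.tags[out_tag] = sample
    return out
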