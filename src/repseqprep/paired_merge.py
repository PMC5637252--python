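"""Paired-end read merging by ungapped overlap alignment.

The reverse mate is reverse-complemented (sequence reversed and
complemented, quality reversed), then every ungapped overlap between the 3'
suffix of the forward mate and the 5' prefix of the transformed reverse mate
is scored as matches − mismatches (N always counts as a mismatch).  The
longest overlap with the maximal score whose mismatch fraction is within
``max_mismatch_fraction`` is accepted — the suffix-prefix scan of the
FLASH / PANDAseq family, without gaps.

Consensus over the overlap: agreeing bases keep the base with quality
``max(q_f, q_r)``; disagreeing bases keep the higher-quality base with
quality ``|q_f − q_r|``; a disagreement at equal quality yields ``N`` with
quality 0.  This is a stated convention, not a posterior probability.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .element_match import reverse_complement
from .errors import ContractError
from .io_formats import SequenceRead


@dataclass
class MergeSpec:
    min_overlap: int = 10
    max_mismatch_fraction: float = 0.1
    reverse_mate_is_revcomp: bool = True

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ContractError("merge: min_overlap must be >= 1")
        if not 0.0 <= self.max_mismatch_fraction <= 1.0:
            raise ContractError("merge: max_mismatch_fraction must be in [0, 1]")


@dataclass
class MergeResult:
    read: Optional[SequenceRead]
    overlap: int = 0
    mismatches: int = 0
    reason: Optional[str] = None  # "no_overlap" on failure

    @property
    def merged(self) -> bool:
        return self.read is not None


def merge_pair(fwd: SequenceRead, rev: SequenceRead, spec: MergeSpec = MergeSpec()) -> MergeResult:
    """Merge one mate pair; returns the merged read or reason ``no_overlap``."""
    if fwd.quality is None or rev.quality is None:
        raise ContractError(
            f"merge: pair {fwd.read_id!r}/{rev.read_id!r} lacks quality scores"
        )
    if not fwd.sequence or not rev.sequence:
        raise ContractError(f"merge: empty mate in pair {fwd.read_id!r}")

    if spec.reverse_mate_is_revcomp:
        r_seq = reverse_complement(rev.sequence)
        r_qual = rev.quality[::-1]
    else:
        r_seq = rev.sequence
        r_qual = list(rev.quality)

    f_seq, f_qual = fwd.sequence, fwd.quality
    lf, lr = len(f_seq), len(r_seq)
    f_up, r_up = f_seq.upper(), r_seq.upper()

    best: Optional[tuple[int, int, int]] = None  # (score, L, mismatches)
    for L in range(min(lf, lr), spec.min_overlap - 1, -1):
        mm = 0
        off = lf - L
        for i in range(L):
            a = f_up[off + i]
            if a != r_up[i] or a == "N":
                mm += 1
        if mm > spec.max_mismatch_fraction * L:
            continue
        score = (L - mm) - mm
        if best is None or score > best[0]:  # ties keep the larger (earlier) L
            best = (score, L, mm)

    if best is None:
        return MergeResult(read=None, reason="no_overlap")

    _, L, mm = best
    off = lf - L
    seq_parts: list[str] = [f_seq[:off]]
    qual: list[int] = list(f_qual[:off])
    for i in range(L):
        fb, rb = f_seq[off + i], r_seq[i]
        fq, rq = f_qual[off + i], r_qual[i]
        if fb.upper() == rb.upper():
            seq_parts.append(fb)
            qual.append(max(fq, rq))
        elif fq > rq:
            seq_parts.append(fb)
            qual.append(fq - rq)
        elif rq > fq:
            seq_parts.append(rb)
            qual.append(rq - fq)
        else:
            seq_parts.append("N")
            qual.append(0)
    seq_parts.append(r_seq[L:])
    qual.extend(r_qual[L:])

    tags = dict(fwd.tags)
    for k, v in rev.tags.items():
        tags.setdefault(k, v)
    merged = SequenceRead(
        read_id=fwd.read_id,
        sequence="".join(seq_parts),
        quality=qual,
        description=fwd.description,
        tags=tags,
        pair_role="single",
    )
    return MergeResult(read=merged, overlap=L, mismatches=mm)
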