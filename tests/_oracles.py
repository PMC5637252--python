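"""Independent reference implementations used only to check results.

These are deliberately written in a different style from the package (plain
dynamic programming / direct counting / sort-and-group) and never share code
with the implementation under test.
"""
from __future__ import annotations

from collections import Counter
from itertools import groupby


def sw_score_dp(element: str, segment: str, gapped: bool = False, gap: int = -3) -> int:
    """Smith-Waterman best local score, match +2 / mismatch -2, N never
    matches; gapped variant uses a linear per-position gap penalty."""
    el, sg = element.upper(), segment.upper()
    m, n = len(el), len(sg)
    prev = [0] * (n + 1)
    best = 0
    for i in range(1, m + 1):
        cur = [0] * (n + 1)
        for j in range(1, n + 1):
            s = 2 if (el[i - 1] == sg[j - 1] and el[i - 1] != "N") else -2
            h = prev[j - 1] + s
            if gapped:
                h = max(h, prev[j] + gap, cur[j - 1] + gap)
            cur[j] = max(0, h)
            if cur[j] > best:
                best = cur[j]
        prev = cur
    return best


def sw_score_enumerate(element: str, segment: str) -> int:
    """Ungapped local alignment by exhaustive enumeration of every
    (element offset, segment offset, length) window.  Slow; tiny inputs only."""
    el, sg = element.upper(), segment.upper()
    best = 0
    for i in range(len(el)):
        for j in range(len(sg)):
            score = 0
            for k in range(min(len(el) - i, len(sg) - j)):
                score += 2 if (el[i + k] == sg[j + k] and el[i + k] != "N") else -2
                if score > best:
                    best = score
    return best


def min_mismatch_scan(element: str, segment: str) -> tuple[float, int]:
    """(min mismatches, offset) over every full-fit offset; (inf, -1) if the
    element does not fit.  N counts as a mismatch everywhere."""
    el, sg = element.upper(), segment.upper()
    m, n = len(el), len(sg)
    if m > n:
        return float("inf"), -1
    best, best_off = None, -1
    for off in range(n - m + 1):
        mm = sum(1 for a, b in zip(el, sg[off : off + m]) if a != b or a == "N")
        if best is None or mm < best:
            best, best_off = mm, off
    return float(best), best_off


def dedup_sort_and_group(seq_group_pairs: list[tuple[str, str]]) -> dict[str, Counter]:
    """Naive dedup: per group, the multiset of (uppercased sequence -> count)."""
    out: dict[str, Counter] = {}
    for seq, group in seq_group_pairs:
        out.setdefault(group, Counter())[seq.upper()] += 1
    return out


def longest_run(sequence: str) -> int:
    return max((len(list(g)) for _, g in groupby(sequence.upper())), default=0)


def tally_reads(reads) -> dict:
    """Direct tally of every read statistic (dict/Counter based)."""
    comp: dict[int, Counter] = {}
    qual_sum: dict[int, int] = {}
    qual_n: dict[int, int] = {}
    gc = Counter()
    lengths = Counter()
    meanq = Counter()
    for read in reads:
        seq = read.sequence.upper()
        lengths[len(seq)] += 1
        for p, base in enumerate(seq):
            comp.setdefault(p, Counter())[base] += 1
        acgt = sum(seq.count(b) for b in "ACGT")
        if acgt:
            gc[(100 * (seq.count("G") + seq.count("C"))) // acgt] += 1
        if read.quality is not None and seq:
            for p, q in enumerate(read.quality):
                qual_sum[p] = qual_sum.get(p, 0) + q
                qual_n[p] = qual_n.get(p, 0) + 1
            meanq[sum(read.quality) // len(read.quality)] += 1
    return {
        "composition": comp,
        "qual_sum": qual_sum,
        "qual_n": qual_n,
        "gc": gc,
        "lengths": lengths,
        "mean_quality": meanq,
    }


def stats_agree(acc, oracle: dict) -> bool:
    """Compare a StatsAccumulator with the direct tally."""
    from repseqprep.read_statistics import BASES

    L = acc.max_length
    for p in range(L):
        expected = oracle["composition"].get(p, Counter())
        for i, base in enumerate(BASES):
            if int(acc.base_counts[p, i]) != expected.get(base, 0):
                return False
    for p in range(L):
        if int(acc.qual_sum[p]) != oracle["qual_sum"].get(p, 0):
            return False
        if int(acc.qual_count[p]) != oracle["qual_n"].get(p, 0):
            return False
    if {k: v for k, v in enumerate(acc.gc_histogram.tolist()) if v} != dict(oracle["gc"]):
        return False
    if dict(acc.length_histogram) != dict(oracle["lengths"]):
        return False
    if {k: v for k, v in enumerate(acc.mean_quality_histogram.tolist()) if v} != dict(
        oracle["mean_quality"]
    ):
        return False
    return True
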