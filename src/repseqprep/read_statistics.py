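"""Streaming read statistics.

A :class:`StatsAccumulator` observes reads one at a time at any point in the
pipeline and maintains: per-position base composition (A/C/G/T/N), per-position
mean base-call quality, a GC-content histogram (integer percent, floored,
computed over unambiguous bases only), a read-length histogram and a mean
read-quality histogram (floored Phred).  Accumulators placed before and after
a filtering step show how the read population changes.

Accumulators merge associatively, so tallies over any partition of the input
equal the tally over the whole — the property the tests exercise.
"""
from __future__ import annotations

import json
import os
from typing import Iterable, Optional

import numpy as np

from .io_formats import SequenceRead

BASES = "ACGTN"
_BASE_INDEX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i

MAX_MEAN_Q = 93


class StatsAccumulator:
    """Positional and whole-read statistics, updatable one read at a time."""

    def __init__(self) -> None:
        self._capacity = 0
        self.base_counts = np.zeros((0, len(BASES)), dtype=np.int64)
        self.qual_sum = np.zeros(0, dtype=np.int64)
        self.qual_count = np.zeros(0, dtype=np.int64)
        self.gc_histogram = np.zeros(101, dtype=np.int64)
        self.length_histogram: dict[int, int] = {}
        self.mean_quality_histogram = np.zeros(MAX_MEAN_Q + 1, dtype=np.int64)
        self.reads_seen = 0

    # -- internal -----------------------------------------------------------
    def _grow(self, n: int) -> None:
        if n <= self._capacity:
            return
        cap = max(n, 2 * self._capacity, 64)
        self.base_counts = np.vstack(
            [self.base_counts, np.zeros((cap - self._capacity, len(BASES)), dtype=np.int64)]
        )
        self.qual_sum = np.concatenate(
            [self.qual_sum, np.zeros(cap - self._capacity, dtype=np.int64)]
        )
        self.qual_count = np.concatenate(
            [self.qual_count, np.zeros(cap - self._capacity, dtype=np.int64)]
        )
        self._capacity = cap

    @property
    def max_length(self) -> int:
        return max(self.length_histogram, default=0)

    # -- updates ------------------------------------------------------------
    def update(self, read: SequenceRead) -> "StatsAccumulator":
        """Fold one read into every statistic (quality fields skipped when
        the read has no quality)."""
        n = len(read.sequence)
        self._grow(n)
        self.reads_seen += 1
        self.length_histogram[n] = self.length_histogram.get(n, 0) + 1

        if n:
            codes = _BASE_INDEX[np.frombuffer(read.sequence.encode("ascii"), dtype=np.uint8)]
            np.add.at(self.base_counts, (np.arange(n), codes), 1)
            counts = np.bincount(codes, minlength=len(BASES))
            acgt = int(counts[:4].sum())
            if acgt:  # all-N reads have no defined GC content
                gc = (100 * int(counts[1] + counts[2])) // acgt
                self.gc_histogram[gc] += 1

        if read.quality is not None and n:
            qual = np.asarray(read.quality, dtype=np.int64)
            self.qual_sum[:n] += qual
            self.qual_count[:n] += 1
            # floor of the mean, computed exactly in integer arithmetic
            self.mean_quality_histogram[int(qual.sum()) // n] += 1
        return self

    def merge(self, other: "StatsAccumulator") -> "StatsAccumulator":
        """Fold ``other`` into ``self`` (associative, commutative up to
        array sizing)."""
        self._grow(other._capacity)
        n = other._capacity
        self.base_counts[:n] += other.base_counts
        self.qual_sum[:n] += other.qual_sum
        self.qual_count[:n] += other.qual_count
        self.gc_histogram += other.gc_histogram
        self.mean_quality_histogram += other.mean_quality_histogram
        for length, count in other.length_histogram.items():
            self.length_histogram[length] = self.length_histogram.get(length, 0) + count
        self.reads_seen += other.reads_seen
        return self

    # -- finalization -------------------------------------------------------
    def composition_fractions(self) -> np.ndarray:
        """(max_length x 5) matrix of base fractions per position (rows with
        zero coverage are all-zero)."""
        L = self.max_length
        counts = self.base_counts[:L].astype(float)
        totals = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, counts / totals, 0.0)
        return frac

    def mean_quality_by_position(self) -> np.ndarray:
        L = self.max_length
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.qual_count[:L] > 0,
                self.qual_sum[:L] / np.maximum(self.qual_count[:L], 1),
                np.nan,
            )

    def report(self) -> dict:
        """JSON-serializable summary of every statistic."""
        L = self.max_length
        return {
            "reads_seen": self.reads_seen,
            "composition": {
                base: self.base_counts[:L, i].tolist() for i, base in enumerate(BASES)
            },
            "mean_quality_by_position": [
                None if not c else s / c
                for s, c in zip(self.qual_sum[:L].tolist(), self.qual_count[:L].tolist())
            ],
            "gc_histogram": {
                str(pct): int(v) for pct, v in enumerate(self.gc_histogram) if v
            },
            "length_histogram": {
                str(k): v for k, v in sorted(self.length_histogram.items())
            },
            "mean_quality_histogram": {
                str(q): int(v) for q, v in enumerate(self.mean_quality_histogram) if v
            },
        }

    def write_reports(self, out_dir: str, name: str) -> dict[str, str]:
        """Write one TSV per statistic plus a combined JSON; returns the
        mapping statistic -> path.  Positions are 0-based in the data rows
        (stated 1-based in the commented human-readable header)."""
        os.makedirs(out_dir, exist_ok=True)
        L = self.max_length
        paths: dict[str, str] = {}

        def path_for(stat: str) -> str:
            p = os.path.join(out_dir, f"{name}.{stat}.tsv")
            paths[stat] = p
            return p

        frac = self.composition_fractions()
        with open(path_for("composition"), "w") as fh:
            fh.write("# per-position base composition (position 0 = base 1 of the read)\n")
            fh.write("position\t" + "\t".join(BASES) + "\t" + "\t".join(f"frac_{b}" for b in BASES) + "\n")
            for p in range(L):
                counts = "\t".join(str(int(c)) for c in self.base_counts[p])
                fracs = "\t".join(f"{f:.6f}" for f in frac[p])
                fh.write(f"{p}\t{counts}\t{fracs}\n")

        meanq = self.mean_quality_by_position()
        with open(path_for("quality_by_position"), "w") as fh:
            fh.write("# per-position mean Phred quality (position 0 = base 1 of the read)\n")
            fh.write("position\tmean_quality\tn\n")
            for p in range(L):
                if self.qual_count[p]:
                    fh.write(f"{p}\t{meanq[p]:.4f}\t{int(self.qual_count[p])}\n")

        with open(path_for("gc_histogram"), "w") as fh:
            fh.write("# GC content over unambiguous bases, integer percent (floor)\n")
            fh.write("gc_percent\tcount\n")
            for pct, v in enumerate(self.gc_histogram):
                if v:
                    fh.write(f"{pct}\t{int(v)}\n")

        with open(path_for("length_histogram"), "w") as fh:
            fh.write("# read length distribution\n")
            fh.write("length\tcount\n")
            for k in sorted(self.length_histogram):
                fh.write(f"{k}\t{self.length_histogram[k]}\n")

        with open(path_for("mean_quality_histogram"), "w") as fh:
            fh.write("# mean read quality, floored Phred\n")
            fh.write("mean_quality\tcount\n")
            for q, v in enumerate(self.mean_quality_histogram):
                if v:
                    fh.write(f"{q}\t{int(v)}\n")

        combined = os.path.join(out_dir, f"{name}.stats.json")
        with open(combined, "w") as fh:
            json.dump(self.report(), fh, indent=1, sort_keys=True)
        paths["combined_json"] = combined
        return paths


def update_stats(acc: StatsAccumulator, read: SequenceRead) -> StatsAccumulator:
    """Functional alias for :meth:`StatsAccumulator.update`."""
    return acc.update(read)


def tally(reads: Iterable[SequenceRead]) -> StatsAccumulator:
    acc = StatsAccumulator()
    for read in reads:
        acc.update(read)
    return acc
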