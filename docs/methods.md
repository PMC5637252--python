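# Methods

This note documents the models, conventions and numerical choices behind
`repseqprep`, in the order a read travels through the pipeline.

## Input and output formats

Reads are accepted as Sanger FASTQ (Phred+33) or FASTA with a parallel QUAL
file, optionally gzip- or bz2-compressed; compression is detected from
magic bytes (`1f 8b` gzip, `42 5a 68` bz2), not the file extension, so
misnamed files still parse. The quality encoding is fixed to Phred+33:
modern instruments emit nothing else, and decoded values outside [0, 93]
are treated as format errors rather than evidence of Phred+64. QUAL files
follow the classic 454 convention — whitespace-separated integers in
records that parallel the FASTA file record-for-record; ids are checked but
records are never reordered by id. `U` is rejected (the pipeline is
DNA-space); lowercase is preserved on output but all comparisons are
case-insensitive. Output FASTA is single-line per sequence, with
accumulated tags written as `name=value` pairs in the header when
requested. FASTQ output is the bit-exact inverse of the reader on
well-formed input, with exactly one newline after the final record.

## Pipeline semantics

The JSON configuration is this package's own dialect (versioned with a
top-level `"version"` key); no compatibility is claimed with any other
tool's configuration format. A run streams read units — single reads, or
mate pairs until a `merge_paired` step — through every step before
fetching the next unit, so each input file is opened exactly once and
memory is bounded by the statistics accumulators and the duplicate store,
not the file size. Intermediate files exist only where an explicit
`write_sequences` step is placed.

Paired-end rules: steps before the merge run per mate (`applies_to`
selects forward, reverse or both), and a pair is dropped whenever either
mate is dropped; steps after the merge see single merged reads.
`find_duplicates` requires single reads (single-end input or a preceding
merge). Step failures abort with the step name (fail-fast); the
`--permissive` flag downgrades per-read step errors to counted drops.

Every filtering step maintains `seen = passed + dropped` with a per-reason
histogram, written to `report.json`. There is no randomness anywhere in
the pipeline, so identical inputs and configuration produce byte-identical
outputs.

## Filters

All thresholds are inclusive (`min ≤ x ≤ max`), the least-surprise
convention. The sliding-window quality filter anchors windows at the 5′
end with step 1; reads shorter than the window are evaluated as a single
full-length window. With `action=trim` the read is truncated at the start
of the first window whose mean falls below the minimum; with `drop` it is
discarded if any window fails. The per-base filter trims at the first base
below the minimum (5′→3′) or drops on any such base. One documented
boundary: a trim that leaves fewer bases than the window length is
re-evaluated as a single short window on a second application, so
idempotence is guaranteed only for trimmed outputs at least one window
long. The homopolymer filter is drop-only and counts runs of any letter,
including `N` runs — conservative, since long `N` runs are certainly
artefactual. The ambiguous filter counts every non-ACGT character.

## Statistics

Accumulators track per-position base counts (A/C/G/T/N), per-position
quality sums/counts, and three histograms: GC percent (integer, floored,
computed over unambiguous bases only — all-`N` reads are skipped for this
histogram since their GC content is undefined, but still contribute to
composition, length and quality statistics), read length, and floored mean
read quality. Accumulators merge associatively, so statistics can be
computed in chunks and combined. Machine-readable TSVs use 0-based
positions; the commented headers state the 1-based convention for human
readers. Plotting is out of scope.

## The match operation

Score mode is Smith–Waterman local alignment with the +2/−2 substitution
scores; the ungapped case is computed exactly as the maximal-sum window
per diagonal (Kadane's algorithm), which is equivalent to Smith–Waterman
with gaps forbidden. The gapped case uses a linear gap penalty per gap
position, default −3 — the substitution scores are fixed by the method,
but the gap penalty is this package's own default and is configurable;
no compatibility with any particular historical value is claimed.
Mismatch mode interprets the 0/+1 cost matrix as minimisation: an
ungapped scan over every offset at which the full element fits inside the
window, which makes a "maximum number of mismatches" threshold exact. An
element longer than the window yields a no-fit sentinel (infinite
mismatches).

Determinism requires explicit tie-breaks: best score (or fewest
mismatches) first, then smallest read offset, then panel order (first
element in the FASTA wins), then forward strand before reverse. Reverse-
strand matching reverse-complements the **element**, never the read, so
spans are always reported in the read's own coordinates. `N` scores −2 /
counts as a mismatch against everything, including `N` — a conservative
choice that prevents ambiguous bases from manufacturing matches. Windows
are clamped to read bounds; a negative window start counts from the read
end (e.g. `[-30, end)` for 3′ primers on variable-length reads); a window
that misses the read entirely is a separately counted non-match.
Combinatorial barcode resolution is exposed as an optional
`combinatorial` block on a match step (and as a library function): after
tagging, the tuple of configured tag values is looked up in the CSV table
and the sample tag set on success.

## Paired-end merging

Merging is the ungapped suffix–prefix scan of the FLASH/PANDAseq family:
after reverse-complementing the reverse mate, every overlap length L from
`min(len_f, len_r)` down to `min_overlap` (default 10) is scored as
matches − mismatches; the candidate must satisfy
`mismatches/L ≤ max_mismatch_fraction` (default 0.1), and among admissible
candidates the maximal score wins with ties to the larger L. Consensus
per overlap column: agreement keeps the base with quality
`max(q_f, q_r)`; disagreement keeps the higher-quality base with quality
`|q_f − q_r|`; disagreement at equal quality yields `N` with quality 0.
This quality rule is a stated convention, not a posterior error
probability. Gapped overlap alignment and adapter read-through handling
are out of scope.

## Duplicate collapsing

Duplication means the complete read sequence is identical,
case-insensitively, with `N` equal only to `N` — reads differing A vs `N`
are kept apart, because a single real nucleotide difference can separate
alleles or gene segments. Collapsing is per sample group (keyed by a
configurable tag; untagged reads form one implicit group). The contract
is exact full-string identity, which a per-group hash index satisfies
exactly; a suffix-tree index is an interchangeable implementation of the
same semantics and would have to pass the same oracle tests. The
first-seen read is the representative (its id, case and qualities are
kept); the count multiset is therefore invariant under input permutation
even though representative identities are not.

## Synthetic data generator

Fixtures emulate amplicon-style Rep-seq reads: random uniform-ACGT
templates concatenated as `[barcode][barcode2][primer5][template][rc(primer3)]`,
with substitutions and `N`s planted at recorded positions, duplicate
structure realised by re-emitting the identical final string, and mate
pairs cut from the construct with a chosen overlap. Defaults reflect the
study conditions the tests exercise: barcode panels with pairwise Hamming
distance ≥ 3, per-base substitution rate 0.01–0.02 where errors are
wanted (with at most one substitution inside the barcode, so that
assignment at mismatch threshold 1 is analytically unambiguous for
distance-≥3 panels), declining piecewise-constant quality profiles
(38 → 30 → 22), and read/overlap geometries in the ranges real 2×150–250
protocols produce. A single `random.Random(seed)` stream drawn in a fixed
order makes fixtures byte-reproducible; integer-only RNG use keeps them
platform-stable.

What the generator does **not** emulate: sequencer-specific error
profiles (no quality-dependent miscalls, no homopolymer slippage),
chimeras, V(D)J recombination structure or somatic hypermutation. Passing
tests therefore demonstrate algorithmic correctness on reads with known
planted structure, not end-to-end accuracy on any particular instrument's
data.

## Problem sizes and verification

The test suite and the acceptance script verify, at sizes chosen to keep
a full run in seconds: aligner agreement with an independently written
dynamic-programming Smith–Waterman and an exhaustive offset scan on 500
random element (≤30 nt) / segment (≤100 nt) pairs; 100% barcode recovery
with zero unmatched on 2,000 reads under the distance-≥3 / ≤1-substitution
conditions above; exact per-group (sequence, count) multiset agreement
with a sort-and-group oracle on 10⁴ reads from 500 templates of
multiplicity 20 across 3 samples; exact template recovery for 1,000
error-free pairs with overlap ≥ 15; conservation, single-open and
byte-identical-rerun properties of a five-step pipeline on 500 reads;
statistics tally agreement on 10⁴ reads plus the 4-way merge property;
and byte-exact FASTQ round trips with gzip/bz2 transparency. The gapped
aligner is additionally cross-checked against Biopython's
`PairwiseAligner` in the unit tests; that library is never used in the
implementation path.

## Known limitations

No UMI extraction or consensus building; no multiprocessing; no
quality-aware (posterior) merging; no error-tolerant (clustered) dedup;
no SAM/BAM or interleaved-FASTQ input; no Phred+64 detection. The
original-tool configuration dialect is not reproduced, so configurations
are not drop-in portable.
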