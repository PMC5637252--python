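"""Seeded synthetic-data generator for pipeline inputs.

Builds FASTQ / FASTA+QUAL inputs with planted structure — sample barcodes,
5'/3' PCR primers, overlapping mate pairs cut from known templates,
substitution and N errors at recorded positions, and duplicate reads
realised by re-emitting the identical final string — together with a
machine-readable truth table, so every operation can be checked against
ground truth without external data.

Reads are constructed as ``[barcode][barcode2][primer5][template][rc(primer3)]``
(any part may be absent); paired mode cuts two overlapping mates from that
construct and reverse-complements the reverse mate.  All randomness flows
from a single ``random.Random(seed)`` stream drawn in a fixed documented
order (per unique read: length, template bases, substitutions 5'→3', N's
5'→3'), so a fixture is byte-reproducible from its spec.  Substitutions
inside the barcode region are capped at one per read, keeping barcode
assignment unambiguous for panels with pairwise Hamming distance >= 3.

Quality profiles are simple declining piecewise-constant curves; no
sequencer error-model realism is claimed, so conclusions from these
fixtures concern algorithmic correctness, not platform-specific behaviour.
"""
from __future__ import annotations

import csv
import gzip
import bz2
import os
import random
from dataclasses import dataclass, field
from typing import Optional

from .errors import ConfigError
from .element_match import reverse_complement
from .io_formats import SequenceRead, write_fasta, write_fastq

_BASES = "ACGT"


@dataclass
class MultiplicitySpec:
    """Duplicate multiplicity per unique read: ``constant`` (value) or
    ``geometric`` (mean >= 1; support {1, 2, ...})."""

    kind: str = "constant"
    value: int = 1
    mean: float = 1.0


@dataclass
class QualityStep:
    """Constant Phred value up to a fraction of the read length."""

    upto_fraction: float
    phred: int


@dataclass
class FixtureSpec:
    n_templates: int = 100
    template_length: tuple[int, int] = (150, 250)
    barcodes: list[tuple[str, str]] = field(default_factory=list)
    barcodes2: list[tuple[str, str]] = field(default_factory=list)  # combinatorial 2nd tier
    primers5: list[tuple[str, str]] = field(default_factory=list)
    primers3: list[tuple[str, str]] = field(default_factory=list)
    duplicate_multiplicity: MultiplicitySpec = field(default_factory=MultiplicitySpec)
    substitution_rate: float = 0.0
    n_rate: float = 0.0
    max_barcode_substitutions: int = 1
    paired: bool = False
    read_length: int = 150
    overlap: tuple[int, int] = (20, 60)
    quality_profile: list[QualityStep] = field(
        default_factory=lambda: [QualityStep(0.6, 38), QualityStep(0.9, 30), QualityStep(1.0, 22)]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.substitution_rate, self.n_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError("fixture: rates must be in [0, 1]")
        if self.n_templates < 1:
            raise ConfigError("fixture: n_templates must be >= 1")


@dataclass
class TruthRow:
    read_id: str
    sample_id: str
    template_id: str
    duplicate_group: str
    barcode_span: Optional[tuple[int, int]]
    barcode2_span: Optional[tuple[int, int]]
    primer5_span: Optional[tuple[int, int]]
    primer3_span: Optional[tuple[int, int]]
    substitution_positions: list[int]
    n_positions: list[int]


@dataclass
class Fixture:
    """In-memory fixture: reads (or mate pairs), the element panels, the
    combinatorial table rows, and one truth row per emitted read."""

    spec: FixtureSpec
    reads: list[SequenceRead] = field(default_factory=list)
    pairs: list[tuple[SequenceRead, SequenceRead]] = field(default_factory=list)
    templates: dict[str, str] = field(default_factory=dict)
    truth: list[TruthRow] = field(default_factory=list)
    combo_rows: list[tuple[str, str, str]] = field(default_factory=list)  # (bc1, bc2, sample)
    truth_by_id: dict[str, TruthRow] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def sample_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for row in self.truth:
            counts[row.sample_id] = counts.get(row.sample_id, 0) + 1
        return counts


def _random_template(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def _quality_for(spec: FixtureSpec, length: int) -> list[int]:
    qual: list[int] = []
    for i in range(length):
        frac = (i + 1) / length
        phred = spec.quality_profile[-1].phred
        for step in spec.quality_profile:
            if frac <= step.upto_fraction:
                phred = step.phred
                break
        qual.append(phred)
    return qual


def _check_barcode_distances(spec: FixtureSpec) -> list[str]:
    warnings = []
    panel = spec.barcodes + spec.barcodes2
    for i in range(len(panel)):
        for j in range(i + 1, len(panel)):
            a, b = panel[i][1], panel[j][1]
            if len(a) == len(b):
                dist = sum(x != y for x, y in zip(a, b))
                if dist < 3 and spec.substitution_rate > 0:
                    warnings.append(
                        f"barcodes {panel[i][0]}/{panel[j][0]} have Hamming distance "
                        f"{dist} < 3 with substitution_rate > 0: truth may be ambiguous"
                    )
    return warnings


def build_fixture(spec: FixtureSpec) -> Fixture:
    """Generate the fixture in memory (deterministic given ``spec.seed``)."""
    rng = random.Random(spec.seed)
    fx = Fixture(spec=spec)
    fx.warnings = _check_barcode_distances(spec)

    n_bc = len(spec.barcodes)
    n_bc2 = len(spec.barcodes2)
    combo_samples: dict[tuple[str, str], str] = {}
    if n_bc and n_bc2:
        k = 0
        for bid, _ in spec.barcodes:
            for b2id, _ in spec.barcodes2:
                k += 1
                sample = f"sample{k:02d}"
                combo_samples[(bid, b2id)] = sample
                fx.combo_rows.append((bid, b2id, sample))

    serial = 0
    emissions: list[tuple[SequenceRead, TruthRow] | tuple[SequenceRead, SequenceRead, TruthRow]] = []

    for t in range(spec.n_templates):
        template_id = f"tmpl{t:04d}"
        bc = spec.barcodes[t % n_bc] if n_bc else None
        bc2 = spec.barcodes2[(t // n_bc) % n_bc2] if n_bc and n_bc2 else None
        p5 = spec.primers5[t % len(spec.primers5)] if spec.primers5 else None
        p3 = spec.primers3[t % len(spec.primers3)] if spec.primers3 else None
        if bc is None:
            sample_id = "none"
        elif bc2 is not None:
            sample_id = combo_samples[(bc[0], bc2[0])]
        else:
            sample_id = bc[0]

        if spec.paired:
            # choose the construct length from the requested overlap range
            ov = rng.randint(spec.overlap[0], spec.overlap[1])
            total = 2 * spec.read_length - ov
            fixed = sum(len(p[1]) for p in (bc, bc2, p5, p3) if p is not None)
            tlen = total - fixed
            if tlen < 1:
                raise ConfigError("fixture: read_length/overlap leave no room for a template")
        else:
            tlen = rng.randint(spec.template_length[0], spec.template_length[1])

        while True:
            template = _random_template(rng, tlen)
            if template not in fx.templates.values():
                break
        fx.templates[template_id] = template

        parts: list[tuple[Optional[str], str]] = []
        if bc is not None:
            parts.append(("barcode", bc[1]))
        if bc2 is not None:
            parts.append(("barcode2", bc2[1]))
        if p5 is not None:
            parts.append(("primer5", p5[1]))
        parts.append(("template", template))
        if p3 is not None:
            parts.append(("primer3", reverse_complement(p3[1])))

        spans: dict[str, tuple[int, int]] = {}
        pos = 0
        pieces = []
        for label, seq in parts:
            spans[label] = (pos, pos + len(seq))
            pieces.append(seq)
            pos += len(seq)
        construct = "".join(pieces)

        # plant errors once per unique read; duplicates re-emit the result
        sub_positions: list[int] = []
        n_positions: list[int] = []
        chars = list(construct)
        bc_lo, bc_hi = spans.get("barcode", (0, 0))
        bc_subs = 0
        for i in range(len(chars)):
            if spec.substitution_rate and rng.random() < spec.substitution_rate:
                if bc_lo <= i < bc_hi:
                    if bc_subs >= spec.max_barcode_substitutions:
                        continue
                    bc_subs += 1
                choices = [b for b in _BASES if b != chars[i]]
                chars[i] = rng.choice(choices)
                sub_positions.append(i)
        for i in range(len(chars)):
            if spec.n_rate and rng.random() < spec.n_rate:
                chars[i] = "N"
                n_positions.append(i)
        final = "".join(chars)

        mult = spec.duplicate_multiplicity
        if mult.kind == "constant":
            copies = mult.value
        elif mult.kind == "geometric":
            p = 1.0 / max(mult.mean, 1.0)
            copies = 1
            while rng.random() > p:
                copies += 1
        else:
            raise ConfigError(f"fixture: unknown multiplicity kind {mult.kind!r}")

        for _ in range(copies):
            read_id = f"read{serial:06d}"
            serial += 1
            row = TruthRow(
                read_id=read_id,
                sample_id=sample_id,
                template_id=template_id,
                duplicate_group=template_id,
                barcode_span=spans.get("barcode"),
                barcode2_span=spans.get("barcode2"),
                primer5_span=spans.get("primer5"),
                primer3_span=spans.get("primer3"),
                substitution_positions=list(sub_positions),
                n_positions=list(n_positions),
            )
            if spec.paired:
                fwd = SequenceRead(
                    read_id=read_id,
                    sequence=final[: spec.read_length],
                    quality=_quality_for(spec, spec.read_length),
                    pair_role="forward",
                )
                rev = SequenceRead(
                    read_id=read_id,
                    sequence=reverse_complement(final[-spec.read_length:]),
                    quality=_quality_for(spec, spec.read_length)[::-1],
                    pair_role="reverse",
                )
                emissions.append((fwd, rev, row))
            else:
                read = SequenceRead(
                    read_id=read_id,
                    sequence=final,
                    quality=_quality_for(spec, len(final)),
                )
                emissions.append((read, row))

    rng.shuffle(emissions)
    # re-assign ids in emission order so read ids follow file order
    for i, emission in enumerate(emissions):
        new_id = f"read{i:06d}"
        row = emission[-1]
        row.read_id = new_id
        for part in emission[:-1]:
            part.read_id = new_id
        if spec.paired:
            fx.pairs.append((emission[0], emission[1]))
        else:
            fx.reads.append(emission[0])
        fx.truth.append(row)
        fx.truth_by_id[new_id] = row
    return fx


def _write_panel(panel: list[tuple[str, str]], path: str) -> None:
    write_fasta(
        (SequenceRead(read_id=eid, sequence=seq) for eid, seq in panel), path
    )


def _compress(path: str, kind: str) -> str:
    opener = gzip.open if kind == "gzip" else bz2.open
    out = path + (".gz" if kind == "gzip" else ".bz2")
    with open(path, "rb") as src, opener(out, "wb") as dst:
        dst.write(src.read())
    return out


def generate_fixture(spec: FixtureSpec, out_dir: str, compress: Optional[str] = None) -> dict[str, str]:
    """Write the fixture to ``out_dir``; returns the name -> path map.

    Files: ``reads.fastq`` (or ``reads_1.fastq``/``reads_2.fastq``),
    element panels as FASTA, ``combinations.csv`` when two barcode tiers are
    configured, and ``truth.tsv`` (one row per emitted read).  ``compress``
    ("gzip" or "bz2") additionally writes compressed copies of the read files.
    """
    fx = build_fixture(spec)
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    if spec.paired:
        p1 = os.path.join(out_dir, "reads_1.fastq")
        p2 = os.path.join(out_dir, "reads_2.fastq")
        write_fastq((f for f, _ in fx.pairs), p1)
        write_fastq((r for _, r in fx.pairs), p2)
        paths["reads_1"], paths["reads_2"] = p1, p2
    else:
        p = os.path.join(out_dir, "reads.fastq")
        write_fastq(iter(fx.reads), p)
        paths["reads"] = p
    if compress:
        for key in [k for k in paths if k.startswith("reads")]:
            paths[key + "_" + compress] = _compress(paths[key], compress)

    for name, panel in (
        ("barcodes", spec.barcodes),
        ("barcodes2", spec.barcodes2),
        ("primers5", spec.primers5),
        ("primers3", spec.primers3),
    ):
        if panel:
            path = os.path.join(out_dir, f"{name}.fasta")
            _write_panel(panel, path)
            paths[name] = path

    if fx.combo_rows:
        path = os.path.join(out_dir, "combinations.csv")
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["MID1", "MID2", "sample_id"])
            writer.writerows(fx.combo_rows)
        paths["combinations"] = path

    truth_path = os.path.join(out_dir, "truth.tsv")
    with open(truth_path, "w") as fh:
        fh.write(
            "read_id\tsample_id\ttemplate_id\tduplicate_group\tbarcode_span\t"
            "barcode2_span\tprimer5_span\tprimer3_span\tsubstitutions\tn_positions\n"
        )
        for row in fx.truth:
            def span(s: Optional[tuple[int, int]]) -> str:
                return f"{s[0]}-{s[1]}" if s else "."
            subs = ",".join(map(str, row.substitution_positions)) or "."
            ns = ",".join(map(str, row.n_positions)) or "."
            fh.write(
                f"{row.read_id}\t{row.sample_id}\t{row.template_id}\t{row.duplicate_group}\t"
                f"{span(row.barcode_span)}\t{span(row.barcode2_span)}\t"
                f"{span(row.primer5_span)}\t{span(row.primer3_span)}\t{subs}\t{ns}\n"
            )
    paths["truth"] = truth_path
    return paths


# a small default barcode panel (pairwise Hamming distance >= 3)
DEFAULT_BARCODES = [
    ("S1", "ACGTACGT"),
    ("S2", "TGCATGCA"),
    ("S3", "CAGTTCAG"),
]
DEFAULT_PRIMERS5 = [("P5A", "GGTCACCGTCTCCTCA")]
DEFAULT_PRIMERS3 = [("P3A", "GAGGAGACGGTGACC")]
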