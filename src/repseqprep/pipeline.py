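"""JSON-configured single-pass pipeline engine.

A pipeline is an ordered list of steps applied to a stream of read units
(one read for single-end input, one mate pair for paired-end input until a
``merge_paired`` step collapses the pair).  Each unit flows through every
step before the next unit is fetched, so a run makes exactly one pass over
each input file and never materialises the dataset — the only stateful
components are the statistics accumulators and the duplicate store, whose
memory scales with unique content, not file size.

The configuration dialect is this package's own (versioned with a top-level
``"version"`` key); it is validated up front with pydantic — unknown keys,
unknown step kinds and type errors are rejected before any data is read.

Step kinds: ``statistics``, ``quality_filter``, ``length_filter``,
``ambiguous_filter``, ``homopolymer_filter``, ``match``, ``merge_paired``,
``find_duplicates``, ``write_sequences``.
"""
from __future__ import annotations

import json
import os
import re
from dataclasses import dataclass, field as dc_field
from typing import Iterator, Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import element_match, io_formats, read_filters
from .dedup_collapse import DuplicateStore
from .errors import ConfigError, PairingError, RepseqPrepError
from .io_formats import ReadSource, SequenceRead
from .paired_merge import MergeSpec, merge_pair
from .read_statistics import StatsAccumulator

# One unit = the reads travelling together: {"single": r} or
# {"forward": r1, "reverse": r2} before the merge step.
ReadUnit = dict[str, SequenceRead]

CONFIG_VERSION = 1

STEP_KINDS = (
    "statistics",
    "quality_filter",
    "length_filter",
    "ambiguous_filter",
    "homopolymer_filter",
    "match",
    "merge_paired",
    "find_duplicates",
    "write_sequences",
)


# ---------------------------------------------------------------------------
# configuration schema
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class InputModel(_Strict):
    path: str
    format: Literal["fastq", "fasta", "fasta_qual"] = "fastq"
    qual_path: Optional[str] = None
    compression: Literal["auto", "none", "gzip", "bz2"] = "auto"

    @model_validator(mode="after")
    def _check_qual(self) -> "InputModel":
        if self.format == "fasta_qual" and not self.qual_path:
            raise ValueError("format 'fasta_qual' requires qual_path")
        return self


class StatisticsParams(_Strict):
    pass


class QualityFilterParams(_Strict):
    method: Literal["average", "per_base", "window"] = "average"
    min: Optional[float] = None
    max: Optional[float] = None
    window_length: Optional[int] = Field(default=None, ge=1)
    action: Literal["drop", "trim"] = "drop"

    @model_validator(mode="after")
    def _check(self) -> "QualityFilterParams":
        if self.min is None and self.max is None:
            raise ValueError("at least one of min/max is required")
        if self.min is not None and self.max is not None and self.min > self.max:
            raise ValueError("min must be <= max")
        if self.method == "window" and self.window_length is None:
            raise ValueError("method 'window' requires window_length")
        if self.action == "trim" and self.method == "average":
            raise ValueError("action 'trim' is valid for per_base and window methods only")
        if self.method in ("per_base", "window") and self.min is None:
            raise ValueError(f"method {self.method!r} requires min")
        return self


class LengthFilterParams(_Strict):
    min: Optional[int] = Field(default=None, ge=0)
    max: Optional[int] = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "LengthFilterParams":
        if self.min is None and self.max is None:
            raise ValueError("at least one of min/max is required")
        if self.min is not None and self.max is not None and self.min > self.max:
            raise ValueError("min must be <= max")
        return self


class AmbiguousFilterParams(_Strict):
    max_n: int = Field(ge=0)


class HomopolymerFilterParams(_Strict):
    max_run: int = Field(ge=1)


class ElementModel(_Strict):
    id: str
    sequence: str


class CombinatorialParams(_Strict):
    csv: str
    tag_names: Optional[list[str]] = None
    out_tag: str = "sample"


class MatchParams(_Strict):
    tag_name: str
    elements_fasta: Optional[str] = None
    elements: Optional[list[ElementModel]] = None
    mode: Literal["score", "mismatch"] = "score"
    threshold: float = 0.0
    strand: Literal["forward", "reverse", "both"] = "forward"
    window_start: int = 0
    window_end: Optional[int] = None
    gapped: bool = False
    gap_penalty: float = element_match.DEFAULT_GAP_PENALTY
    trim: Literal["none", "cut_leading", "cut_trailing", "cut_element"] = "none"
    require_match: bool = True
    role: Literal["barcode", "primer5", "primer3", "custom"] = "custom"
    combinatorial: Optional[CombinatorialParams] = None

    @model_validator(mode="after")
    def _check(self) -> "MatchParams":
        if (self.elements_fasta is None) == (self.elements is None):
            raise ValueError("exactly one of elements_fasta / elements is required")
        if self.mode == "mismatch" and self.gapped:
            raise ValueError("mismatch mode is ungapped only")
        return self


class MergeParams(_Strict):
    min_overlap: int = Field(default=10, ge=1)
    max_mismatch_fraction: float = Field(default=0.1, ge=0.0, le=1.0)
    reverse_mate_is_revcomp: bool = True
    unmerged_prefix: Optional[str] = None


class FindDuplicatesParams(_Strict):
    group_tag: Optional[str] = None


class WriteSequencesParams(_Strict):
    prefix: str = ""
    group_tag: Optional[str] = None
    format: Literal["fasta", "fastq"] = "fasta"
    include_tags: bool = True


_PARAM_MODELS = {
    "statistics": StatisticsParams,
    "quality_filter": QualityFilterParams,
    "length_filter": LengthFilterParams,
    "ambiguous_filter": AmbiguousFilterParams,
    "homopolymer_filter": HomopolymerFilterParams,
    "match": MatchParams,
    "merge_paired": MergeParams,
    "find_duplicates": FindDuplicatesParams,
    "write_sequences": WriteSequencesParams,
}


class StepModel(_Strict):
    kind: str
    name: Optional[str] = None
    applies_to: Literal["all", "forward", "reverse", "merged"] = "all"
    params: dict = Field(default_factory=dict)


class ConfigModel(_Strict):
    version: int = CONFIG_VERSION
    inputs: list[InputModel]
    steps: list[StepModel]
    output_dir: str = "out"


@dataclass
class StepSpec:
    name: str
    kind: str
    applies_to: str
    params: BaseModel


@dataclass
class PipelineSpec:
    inputs: list[ReadSource]
    steps: list[StepSpec]
    output_dir: str
    version: int = CONFIG_VERSION

    @property
    def paired(self) -> bool:
        return len(self.inputs) == 2


def parse_config(json_text: str) -> PipelineSpec:
    """Parse and fully validate a JSON pipeline configuration.

    Raises :class:`ConfigError` on JSON syntax errors (with position),
    unknown keys or step kinds, missing or mistyped parameters, and
    violations of the structural invariants (1–2 inputs, unique step names,
    at most one merge step, mate-scoped steps only before the merge).
    """
    try:
        raw = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"configuration is not valid JSON: {exc}") from exc
    try:
        model = ConfigModel.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"configuration invalid: {exc}") from exc

    if model.version != CONFIG_VERSION:
        raise ConfigError(f"unsupported config version {model.version} (expected {CONFIG_VERSION})")
    if not 1 <= len(model.inputs) <= 2:
        raise ConfigError("at least one input is required (two for paired-end)")

    steps: list[StepSpec] = []
    names: set[str] = set()
    merge_seen = False
    paired = len(model.inputs) == 2
    for idx, step in enumerate(model.steps):
        if step.kind not in STEP_KINDS:
            raise ConfigError(f"step {idx}: unknown kind {step.kind!r}")
        name = step.name or f"{step.kind}_{idx + 1}"
        if name in names:
            raise ConfigError(f"step {idx}: duplicate step name {name!r}")
        names.add(name)
        try:
            params = _PARAM_MODELS[step.kind].model_validate(step.params)
        except ValidationError as exc:
            raise ConfigError(f"step {name!r} ({step.kind}): invalid params: {exc}") from exc

        if step.kind == "merge_paired":
            if merge_seen:
                raise ConfigError(
                    f"step {name!r}: at most one merge_paired step is allowed"
                )
            if not paired:
                raise ConfigError(f"step {name!r}: merge_paired requires two inputs")
            merge_seen = True
        if step.applies_to in ("forward", "reverse"):
            if not paired or merge_seen:
                raise ConfigError(
                    f"step {name!r}: applies_to={step.applies_to!r} is only valid "
                    "for paired input before the merge step"
                )
        if step.applies_to == "merged" and paired and not merge_seen:
            raise ConfigError(
                f"step {name!r}: applies_to='merged' requires a preceding merge_paired step"
            )
        if step.kind == "find_duplicates" and paired and not merge_seen:
            raise ConfigError(
                f"step {name!r}: find_duplicates on paired input requires a "
                "preceding merge_paired step"
            )
        steps.append(StepSpec(name=name, kind=step.kind, applies_to=step.applies_to, params=params))

    inputs = [
        ReadSource(path=i.path, format=i.format, qual_path=i.qual_path, compression=i.compression)
        for i in model.inputs
    ]
    return PipelineSpec(inputs=inputs, steps=steps, output_dir=model.output_dir, version=model.version)


def load_config(path: str) -> PipelineSpec:
    with open(path, encoding="utf-8") as fh:
        return parse_config(fh.read())


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class StepReport:
    name: str
    kind: str
    seen: int = 0
    passed: int = 0
    dropped: int = 0
    reasons: dict[str, int] = dc_field(default_factory=dict)

    def drop(self, reason: str) -> None:
        self.dropped += 1
        self.reasons[reason] = self.reasons.get(reason, 0) + 1

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "seen": self.seen,
            "passed": self.passed,
            "dropped": self.dropped,
            "reasons": dict(self.reasons),
        }


@dataclass
class PipelineReport:
    input_units: int = 0
    steps: list[StepReport] = dc_field(default_factory=list)
    outputs: dict[str, dict[str, list[str]]] = dc_field(default_factory=dict)
    stats_files: dict[str, dict[str, str]] = dc_field(default_factory=dict)
    warnings: list[str] = dc_field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "input_units": self.input_units,
            "steps": [s.as_dict() for s in self.steps],
            "outputs": self.outputs,
            "stats_files": self.stats_files,
            "warnings": self.warnings,
        }


# ---------------------------------------------------------------------------
# output routing
# ---------------------------------------------------------------------------

_UNSAFE_TAG_CHARS = re.compile(r"[/\\\0]")


class OutputRouter:
    """Lazily opened per-group output files for one write step.

    Reads sharing the group tag value share ``<prefix><value>.<ext>``;
    reads missing the tag go to ``<prefix>unmatched.<ext>``; with no group
    tag configured everything goes to ``<prefix>sequences.<ext>``.
    Tag values containing path separators are sanitised to '_'.
    """

    def __init__(
        self,
        out_dir: str,
        prefix: str,
        fmt: str,
        group_tag: Optional[str],
        include_tags: bool,
        report: PipelineReport,
    ) -> None:
        self.out_dir = out_dir
        self.prefix = prefix
        self.fmt = fmt
        self.group_tag = group_tag
        self.include_tags = include_tags
        self.report = report
        self._handles: dict[str, "os.PathLike | object"] = {}
        self.paths: dict[str, list[str]] = {}
        self.counts: dict[str, int] = {}

    def _group_for(self, read: SequenceRead) -> str:
        if self.group_tag is None:
            return "sequences"
        value = read.tags.get(self.group_tag)
        if value is None:
            return "unmatched"
        clean = _UNSAFE_TAG_CHARS.sub("_", value)
        if clean != value:
            msg = f"sanitised group tag value {value!r} -> {clean!r}"
            if msg not in self.report.warnings:
                self.report.warnings.append(msg)
        return clean

    def _handle(self, group: str, mate_suffix: str):
        key = group + mate_suffix
        fh = self._handles.get(key)
        if fh is None:
            ext = "fasta" if self.fmt == "fasta" else "fastq"
            path = os.path.join(self.out_dir, f"{self.prefix}{group}{mate_suffix}.{ext}")
            fh = open(path, "w", encoding="ascii")
            self._handles[key] = fh
            self.paths.setdefault(group, []).append(path)
        return fh

    def write_unit(self, unit: ReadUnit) -> None:
        paired = "forward" in unit
        for slot, read in unit.items():
            suffix = {"forward": "_1", "reverse": "_2"}.get(slot, "") if paired else ""
            group = self._group_for(read)
            fh = self._handle(group, suffix)
            if self.fmt == "fasta":
                fh.write(io_formats.format_fasta_record(read, self.include_tags))
            else:
                fh.write(io_formats.format_fastq_record(read))
            self.counts[group] = self.counts.get(group, 0) + 1

    def close(self) -> None:
        for fh in self._handles.values():
            fh.close()
        self._handles.clear()


# ---------------------------------------------------------------------------
# runtime steps
# ---------------------------------------------------------------------------

def _selected_slots(unit: ReadUnit, applies_to: str) -> list[str]:
    if applies_to == "all":
        return list(unit.keys())
    if applies_to in ("forward", "reverse"):
        return [applies_to] if applies_to in unit else []
    # "merged": the single/merged slot
    return ["single"] if "single" in unit else []


class _Runtime:
    """One executable step; transforms the unit stream, counting as it goes."""

    def __init__(self, spec: StepSpec, ctx: "_RunContext") -> None:
        self.spec = spec
        self.ctx = ctx
        self.counter = StepReport(name=spec.name, kind=spec.kind)
        ctx.report.steps.append(self.counter)

    def transform(self, units: Iterator[ReadUnit]) -> Iterator[ReadUnit]:
        raise NotImplementedError

    def finish(self) -> None:  # pragma: no cover - default no-op
        pass


class _FilterRuntime(_Runtime):
    """quality/length/ambiguous/homopolymer filters; a unit is dropped when
    any selected mate is dropped, trims replace the mate in place."""

    def _apply(self, read: SequenceRead) -> read_filters.FilterResult:
        p = self.spec.params
        if self.spec.kind == "length_filter":
            return read_filters.filter_length(read, p.min, p.max)
        if self.spec.kind == "ambiguous_filter":
            return read_filters.filter_ambiguous(read, p.max_n)
        if self.spec.kind == "homopolymer_filter":
            return read_filters.filter_homopolymer(read, p.max_run)
        # quality_filter
        if p.method == "average":
            return read_filters.filter_average_quality(read, p.min, p.max)
        if p.method == "per_base":
            return read_filters.filter_per_base_quality(read, p.min, p.action)
        return read_filters.filter_window_quality(read, p.window_length, p.min, p.action)

    def transform(self, units: Iterator[ReadUnit]) -> Iterator[ReadUnit]:
        for unit in units:
            self.counter.seen += 1
            dropped_reason = None
            out = dict(unit)
            for slot in _selected_slots(unit, self.spec.applies_to):
                try:
                    result = self._apply(unit[slot])
                except RepseqPrepError:
                    if not self.ctx.permissive:
                        raise
                    dropped_reason = "error"
                    break
                if not result.passed:
                    dropped_reason = result.reason or "filtered"
                    break
                out[slot] = result.read
            if dropped_reason is None:
                self.counter.passed += 1
                yield out
            else:
                self.counter.drop(dropped_reason)


class _StatisticsRuntime(_Runtime):
    """Observes the stream where placed; accumulates one StatsAccumulator
    per slot and writes the reports at the end of the run."""

    def __init__(self, spec: StepSpec, ctx: "_RunContext") -> None:
        super().__init__(spec, ctx)
        self.accumulators: dict[str, StatsAccumulator] = {}

    def transform(self, units: Iterator[ReadUnit]) -> Iterator[ReadUnit]:
        for unit in units:
            self.counter.seen += 1
            for slot in _selected_slots(unit, self.spec.applies_to):
                acc = self.accumulators.setdefault(slot, StatsAccumulator())
                acc.update(unit[slot])
            self.counter.passed += 1
            yield unit

    def finish(self) -> None:
        stats_dir = os.path.join(self.ctx.output_dir, "stats")
        for slot, acc in self.accumulators.items():
            label = self.spec.name if slot == "single" else f"{self.spec.name}_{slot}"
            paths = acc.write_reports(stats_dir, label)
            self.ctx.report.stats_files[label] = paths


class _MatchRuntime(_Runtime):
    def __init__(self, spec: StepSpec, ctx: "_RunContext") -> None:
        super().__init__(spec, ctx)
        p = spec.params
        if p.elements_fasta is not None:
            elements = element_match.load_elements_fasta(p.elements_fasta, p.role)
        else:
            elements = [element_match.MatchElement(e.id, e.sequence, p.role) for e in p.elements]
        self.match_spec = element_match.MatchSpec(
            elements=elements,
            tag_name=p.tag_name,
            mode=p.mode,
            threshold=p.threshold,
            strand=p.strand,
            window_start=p.window_start,
            window_end=p.window_end,
            gapped=p.gapped,
            gap_penalty=p.gap_penalty,
            trim=p.trim,
            require_match=p.require_match,
        )
        self.combo = None
        if p.combinatorial is not None:
            self.combo = (
                element_match.load_combinatorial_csv(p.combinatorial.csv),
                p.combinatorial.tag_names,
                p.combinatorial.out_tag,
            )
        self.window_outside = 0

    def transform(self, units: Iterator[ReadUnit]) -> Iterator[ReadUnit]:
        for unit in units:
            self.counter.seen += 1
            out = dict(unit)
            dropped_reason = None
            for slot in _selected_slots(unit, self.spec.applies_to):
                outcome = element_match.best_match(unit[slot], self.match_spec)
                if outcome.window_outside:
                    self.window_outside += 1
                if not outcome.passed:
                    dropped_reason = (
                        "window_outside"
                        if outcome.window_outside
                        else f"no_match:{self.match_spec.tag_name}"
                    )
                    break
                read = outcome.read
                if self.combo is not None:
                    table, tag_names, out_tag = self.combo
                    read = element_match.resolve_combinatorial(read, table, tag_names, out_tag)
                out[slot] = read
            if dropped_reason is None:
                self.counter.passed += 1
                yield out
            else:
                self.counter.drop(dropped_reason)


class _MergeRuntime(_Runtime):
    def __init__(self, spec: StepSpec, ctx: "_RunContext") -> None:
        super().__init__(spec, ctx)
        p = spec.params
        self.merge_spec = MergeSpec(
            min_overlap=p.min_overlap,
            max_mismatch_fraction=p.max_mismatch_fraction,
            reverse_mate_is_revcomp=p.reverse_mate_is_revcomp,
        )
        self._unmerged_handles = None
        if p.unmerged_prefix is not None:
            base = os.path.join(ctx.output_dir, p.unmerged_prefix)
            self._unmerged_paths = (base + "unmerged_1.fastq", base + "unmerged_2.fastq")
        else:
            self._unmerged_paths = None

    def _route_unmerged(self, unit: ReadUnit) -> None:
        if self._unmerged_paths is None:
            return
        if self._unmerged_handles is None:
            self._unmerged_handles = tuple(
                open(p, "w", encoding="ascii") for p in self._unmerged_paths
            )
        self._unmerged_handles[0].write(io_formats.format_fastq_record(unit["forward"]))
        self._unmerged_handles[1].write(io_formats.format_fastq_record(unit["reverse"]))

    def transform(self, units: Iterator[ReadUnit]) -> Iterator[ReadUnit]:
        for unit in units:
            self.counter.seen += 1
            result = merge_pair(unit["forward"], unit["reverse"], self.merge_spec)
            if result.merged:
                self.counter.passed += 1
                yield {"single": result.read}
            else:
                self.counter.drop(result.reason or "no_overlap")
                self._route_unmerged(unit)

    def finish(self) -> None:
        if self._unmerged_handles is not None:
            for fh in self._unmerged_handles:
                fh.close()


class _DedupRuntime(_Runtime):
    """Barrier step: consumes the whole stream into the duplicate store,
    then emits the unique representatives (first-seen order) downstream."""

    def __init__(self, spec: StepSpec, ctx: "_RunContext") -> None:
        super().__init__(spec, ctx)
        self.store = DuplicateStore()

    def transform(self, units: Iterator[ReadUnit]) -> Iterator[ReadUnit]:
        group_tag = self.spec.params.group_tag
        for unit in units:
            self.counter.seen += 1
            self.store.add_read(unit["single"], group_tag)
        for read in self.store.emit_unique():
            self.counter.passed += 1
            yield {"single": read}
        # remaining inputs were collapsed into their representatives
        self.counter.dropped = self.counter.seen - self.counter.passed
        if self.counter.dropped:
            self.counter.reasons["duplicate"] = self.counter.dropped

    def finish(self) -> None:
        path = os.path.join(self.ctx.output_dir, f"{self.spec.name}.duplicates.tsv")
        self.store.write_report(path)
        self.ctx.report.outputs.setdefault(self.spec.name, {})["duplicates_report"] = [path]


class _WriteRuntime(_Runtime):
    def __init__(self, spec: StepSpec, ctx: "_RunContext") -> None:
        super().__init__(spec, ctx)
        p = spec.params
        self.router = OutputRouter(
            out_dir=ctx.output_dir,
            prefix=p.prefix,
            fmt=p.format,
            group_tag=p.group_tag,
            include_tags=p.include_tags,
            report=ctx.report,
        )

    def transform(self, units: Iterator[ReadUnit]) -> Iterator[ReadUnit]:
        for unit in units:
            self.counter.seen += 1
            self.router.write_unit(unit)
            self.counter.passed += 1
            yield unit

    def finish(self) -> None:
        self.router.close()
        self.ctx.report.outputs[self.spec.name] = dict(self.router.paths)


_RUNTIME_CLASSES = {
    "statistics": _StatisticsRuntime,
    "quality_filter": _FilterRuntime,
    "length_filter": _FilterRuntime,
    "ambiguous_filter": _FilterRuntime,
    "homopolymer_filter": _FilterRuntime,
    "match": _MatchRuntime,
    "merge_paired": _MergeRuntime,
    "find_duplicates": _DedupRuntime,
    "write_sequences": _WriteRuntime,
}


@dataclass
class _RunContext:
    output_dir: str
    report: PipelineReport
    permissive: bool = False


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------

def _unit_stream(spec: PipelineSpec, report: PipelineReport) -> Iterator[ReadUnit]:
    if not spec.paired:
        for read in io_formats.open_read_stream(spec.inputs[0]):
            report.input_units += 1
            yield {"single": read}
        return
    fwd_stream = io_formats.open_read_stream(spec.inputs[0])
    rev_stream = io_formats.open_read_stream(spec.inputs[1])
    while True:
        fwd = next(fwd_stream, None)
        rev = next(rev_stream, None)
        if fwd is None and rev is None:
            return
        if fwd is None or rev is None:
            longer = spec.inputs[1].path if fwd is None else spec.inputs[0].path
            raise PairingError(
                f"paired inputs have different record counts ({longer} is longer)"
            )
        fwd.pair_role, rev.pair_role = "forward", "reverse"
        report.input_units += 1
        yield {"forward": fwd, "reverse": rev}


def run_pipeline(
    spec: PipelineSpec,
    output_dir: Optional[str] = None,
    permissive: bool = False,
) -> PipelineReport:
    """Execute the pipeline in one streaming pass and write
    ``<output_dir>/report.json``.

    Deterministic: identical inputs and spec produce byte-identical outputs
    and report.  Each filtering step satisfies seen == passed + dropped.
    """
    out_dir = output_dir or spec.output_dir
    os.makedirs(out_dir, exist_ok=True)
    report = PipelineReport()
    ctx = _RunContext(output_dir=out_dir, report=report, permissive=permissive)

    runtimes = [_RUNTIME_CLASSES[s.kind](s, ctx) for s in spec.steps]
    stream: Iterator[ReadUnit] = _unit_stream(spec, report)
    for rt in runtimes:
        stream = rt.transform(stream)
    for _ in stream:  # drain: pulls each unit through the whole chain
        pass
    for rt in runtimes:
        rt.finish()

    report_path = os.path.join(out_dir, "report.json")
    with open(report_path, "w") as fh:
        json.dump(report.as_dict(), fh, indent=1, sort_keys=True)
    return report
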