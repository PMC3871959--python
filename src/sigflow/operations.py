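"""Operations: YAML-specified jobs mapping a dataset summary to a new one.

The central ``node_chain`` operation expands a parameterized node-chain
template over the Cartesian product of parameter ranges (minus
constraint-filtered combinations) and over seeded repetitions, creating
one independent process per (dataset, parameter binding, run).  After
execution the ``consolidate`` step writes one combined ``results.csv``,
archives the specification files and compresses all but one process
folder.  ``merge`` and ``shuffle`` operations reorganize summaries.
"""

from __future__ import annotations

import ast
import datetime
import itertools
import re
import shutil
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence
from urllib.parse import quote

import numpy as np
import yaml

from . import __version__
from .backends import Backend, SerialBackend, execute_processes
from .data_model import ConfigurationError, Dataset, Summary
from .dataset_io import read_dataset, read_summary, write_dataset, write_summary
from .evaluation import MetricsRecord, aggregate_results, results_to_csv
from .node_framework import (
    NodeChainSpec,
    check_chain,
    parse_node_chain_yaml,
    run_node_chain,
)

__all__ = [
    "OperationSpec",
    "ProcessDescriptor",
    "ProcessOutcome",
    "expand_range_expression",
    "expand_parameter_grid",
    "instantiate_template",
    "create_processes",
    "run_operation",
    "run_operation_chain",
    "consolidate",
    "merge_datasets",
    "shuffle_datasets",
    "load_operation_spec",
    "execute_descriptor",
]

TOKEN_RE = re.compile(r"__[A-Za-z][A-Za-z0-9_]*?__")
RANGE_RE = re.compile(
    r"^\s*range\(\s*(-?\d+)\s*,\s*(-?\d+)\s*(?:,\s*(-?\d+)\s*)?\)\s*$"
)


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------


@dataclass
class OperationSpec:
    """Parsed operation definition.

    ``template`` holds the node-chain YAML text with ``__token__``
    placeholders (node_chain operations only).
    """

    type: str
    input_path: str
    template: str = ""
    parameter_ranges: dict = field(default_factory=dict)
    constraints: list = field(default_factory=list)
    runs: int = 1
    name: str = "operation"
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.type not in ("node_chain", "merge", "shuffle"):
            raise ConfigurationError(f"unknown operation type {self.type!r}")
        if self.runs < 1:
            raise ConfigurationError("runs must be >= 1")
        if self.type == "node_chain":
            tokens = set(TOKEN_RE.findall(self.template)) - _internal_tokens(self.template)
            missing = tokens - set(self.parameter_ranges)
            if missing:
                raise ConfigurationError(
                    f"template tokens missing from parameter_ranges: {sorted(missing)}"
                )


def load_operation_spec(path) -> OperationSpec:
    """Load an operation YAML file; ``template`` may be a relative path."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "type" not in doc:
        raise ConfigurationError(f"{path}: operation spec must be a mapping with 'type'")
    template = doc.get("template_text", "")
    if not template and doc.get("template"):
        template_path = path.parent / doc["template"]
        template = template_path.read_text(encoding="utf-8")
    known = {"type", "input_path", "template", "template_text", "parameter_ranges",
             "constraints", "runs"}
    return OperationSpec(
        type=str(doc["type"]),
        input_path=str(doc.get("input_path", "")),
        template=template,
        parameter_ranges=dict(doc.get("parameter_ranges") or {}),
        constraints=list(doc.get("constraints") or []),
        runs=int(doc.get("runs", 1)),
        name=path.stem,
        options={k: v for k, v in doc.items() if k not in known},
    )


# ---------------------------------------------------------------------------
# grid expansion
# ---------------------------------------------------------------------------


def expand_range_expression(expr: str) -> list[int]:
    """Expand ``range(a, b[, s])`` with the usual exclusive-stop semantics."""
    match = RANGE_RE.match(expr)
    if not match:
        raise ConfigurationError(f"malformed range expression {expr!r}")
    a, b = int(match.group(1)), int(match.group(2))
    s = int(match.group(3)) if match.group(3) is not None else 1
    if s == 0:
        raise ConfigurationError("range step must not be zero")
    values = list(range(a, b, s))
    if not values:
        raise ConfigurationError(f"empty parameter range: {expr!r}")
    return values


def _expand_values(value) -> list:
    if isinstance(value, str) and RANGE_RE.match(value):
        return expand_range_expression(value)
    if isinstance(value, (list, tuple)):
        if not value:
            raise ConfigurationError("empty parameter range")
        return list(value)
    return [value]


_ALLOWED_CONSTRAINT_NODES = (
    ast.Expression,
    ast.BoolOp,
    ast.And,
    ast.Or,
    ast.UnaryOp,
    ast.Not,
    ast.Compare,
    ast.Eq,
    ast.NotEq,
    ast.Lt,
    ast.LtE,
    ast.Gt,
    ast.GtE,
    ast.Name,
    ast.Constant,
    ast.Load,
)


def _eval_constraint(expr: str, binding: dict) -> bool:
    """Evaluate a boolean comparison expression over a parameter binding.

    Only and/or/not, comparisons, token names and literals are allowed —
    no calls, no attribute access, no general code execution.
    """
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as exc:
        raise ConfigurationError(f"malformed constraint {expr!r}: {exc}") from None
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_CONSTRAINT_NODES):
            raise ConfigurationError(
                f"constraint {expr!r}: disallowed syntax {type(node).__name__}"
            )
        if isinstance(node, ast.Name) and node.id not in binding:
            raise ConfigurationError(
                f"constraint {expr!r} references unknown token {node.id!r}"
            )
    return bool(
        eval(compile(tree, "<constraint>", "eval"), {"__builtins__": {}}, dict(binding))
    )


def expand_parameter_grid(
    ranges: dict, constraints: Sequence[str] = ()
) -> list[dict]:
    """Cartesian product of parameter ranges, filtered by constraints.

    Tokens iterate in declaration order with the last token fastest;
    ordering is deterministic.
    """
    tokens = list(ranges)
    if not tokens:
        return [{}]
    expanded = {t: _expand_values(ranges[t]) for t in tokens}
    bindings = []
    for combo in itertools.product(*(expanded[t] for t in tokens)):
        binding = dict(zip(tokens, combo))
        if all(_eval_constraint(c, binding) for c in constraints):
            bindings.append(binding)
    if not bindings:
        raise ConfigurationError("constraints removed every parameter combination")
    return bindings


# ---------------------------------------------------------------------------
# template instantiation
# ---------------------------------------------------------------------------


def _internal_tokens(template: str) -> set[str]:
    """Tokens bound inside the template itself (grid-search ``grid`` keys).

    A meta node's hyper-parameter tokens are resolved by that node during
    training, not by the operation's parameter grid, so they must survive
    template instantiation untouched.
    """
    try:
        doc = yaml.safe_load(template)
    except yaml.YAMLError:
        return set()
    tokens: set[str] = set()

    def walk(node):
        if isinstance(node, dict):
            grid = node.get("grid")
            if isinstance(grid, dict):
                tokens.update(k for k in grid if isinstance(k, str) and TOKEN_RE.fullmatch(k))
            for v in node.values():
                walk(v)
        elif isinstance(node, list):
            for v in node:
                walk(v)

    walk(doc)
    return tokens


def _substitute(value, binding: dict):
    if isinstance(value, str):
        if value in binding:
            return binding[value]  # full-token scalar: preserve the value type
        def repl(match):
            token = match.group(0)
            if token not in binding:
                raise ConfigurationError(f"unbound template token {token!r}")
            return str(binding[token])
        return TOKEN_RE.sub(repl, value)
    if isinstance(value, dict):
        return {k: _substitute(v, binding) for k, v in value.items()}
    if isinstance(value, list):
        return [_substitute(v, binding) for v in value]
    return value


def instantiate_template(template: str, binding: dict) -> NodeChainSpec:
    """Bind every ``__token__`` in a node-chain template and parse it.

    Grid-search-internal tokens (keys of a ``grid:`` mapping) pass through
    unchanged; every other token must be bound.
    """
    internal = _internal_tokens(template)
    full_binding = {**{t: t for t in internal}, **binding}
    for token in TOKEN_RE.findall(template):
        if token not in full_binding:
            raise ConfigurationError(f"unbound template token {token!r}")
    doc = yaml.safe_load(template)
    if not isinstance(doc, dict) or "node_chain" not in doc:
        raise ConfigurationError("template must have a top-level 'node_chain' key")
    resolved = _substitute(doc, full_binding)
    return parse_node_chain_yaml(yaml.safe_dump(resolved, sort_keys=False))


# ---------------------------------------------------------------------------
# processes
# ---------------------------------------------------------------------------


def _token_name(token: str) -> str:
    return token.strip("_")


def _safe_value(value) -> str:
    return quote(str(value), safe="")


@dataclass
class ProcessDescriptor:
    """One fully bound unit of work: dataset x parameter binding x run."""

    dataset_name: str
    dataset_path: Optional[str]
    binding: dict
    run_index: int
    chain: NodeChainSpec
    output_subpath: str
    dataset: Optional[Dataset] = None  # in-memory fallback when no path exists


@dataclass
class ProcessOutcome:
    descriptor: ProcessDescriptor
    success: bool
    train_metrics: Optional[MetricsRecord] = None
    test_metrics: Optional[MetricsRecord] = None
    output: Optional[Dataset] = None
    error: Optional[str] = None


def create_processes(spec: OperationSpec, summary: Summary) -> list[ProcessDescriptor]:
    """One descriptor per (dataset x binding x run), deterministic order."""
    if not summary.datasets:
        raise ConfigurationError("input summary is empty")
    bindings = expand_parameter_grid(spec.parameter_ranges, spec.constraints)
    descriptors = []
    for name in sorted(summary.datasets):
        dataset_path = (
            str(Path(summary.root_path) / name) if summary.root_path else None
        )
        dataset = None if dataset_path else summary.datasets[name]
        for binding in bindings:
            chain = instantiate_template(spec.template, binding)
            params = "_".join(
                f"{_token_name(t)}={_safe_value(v)}" for t, v in binding.items()
            ) or "default"
            for run_index in range(spec.runs):
                descriptors.append(
                    ProcessDescriptor(
                        dataset_name=name,
                        dataset_path=dataset_path,
                        binding=dict(binding),
                        run_index=run_index,
                        chain=chain,
                        output_subpath=f"{name}/{params}/run{run_index}",
                        dataset=dataset,
                    )
                )
    return descriptors


def execute_descriptor(descriptor: ProcessDescriptor) -> ProcessOutcome:
    """Run one process; every exception becomes a failure outcome."""
    try:
        dataset = (
            read_dataset(descriptor.dataset_path)
            if descriptor.dataset_path
            else descriptor.dataset
        )
        result = run_node_chain(descriptor.chain, dataset, descriptor.run_index)
        return ProcessOutcome(
            descriptor=descriptor,
            success=True,
            train_metrics=result.train_metrics,
            test_metrics=result.test_metrics,
            output=result.output,
        )
    except Exception as exc:  # independence contract: never propagate
        return ProcessOutcome(descriptor=descriptor, success=False, error=str(exc))


# ---------------------------------------------------------------------------
# running and consolidation
# ---------------------------------------------------------------------------


def _timestamp() -> str:
    return datetime.datetime.now(datetime.timezone.utc).strftime("%Y%m%d_%H%M%S")


def run_operation(
    spec: OperationSpec,
    output_root,
    backend: Optional[Backend] = None,
    result_dir_name: Optional[str] = None,
) -> Path:
    """Execute one operation and return its timestamped result directory."""
    backend = backend or SerialBackend()
    output_root = Path(output_root)
    result_dir = output_root / (result_dir_name or f"{spec.name}_{_timestamp()}")
    result_dir.mkdir(parents=True, exist_ok=False)

    if spec.type == "merge":
        summary = read_summary(spec.input_path)
        merged = merge_datasets(summary, spec.options.get("group_pattern"))
        write_summary(merged, result_dir)
        return result_dir
    if spec.type == "shuffle":
        summary = read_summary(spec.input_path)
        shuffled = shuffle_datasets(summary, int(spec.options.get("seed", 0)))
        write_summary(shuffled, result_dir)
        return result_dir

    summary = read_summary(spec.input_path)
    processes = create_processes(spec, summary)
    # fail fast on an invalid template before any process is launched
    for descriptor in processes[:1]:
        kind = summary.datasets[descriptor.dataset_name].kind
        report = check_chain(descriptor.chain, kind)
        if not report.ok:
            raise ConfigurationError("invalid chain template: " + "; ".join(report.errors))
    outcomes = execute_processes(processes, execute_descriptor, backend)

    for outcome in outcomes:
        if not outcome.success:
            continue
        process_dir = result_dir / outcome.descriptor.output_subpath
        process_dir.mkdir(parents=True, exist_ok=True)
        if outcome.output is not None:
            output = outcome.output
            output.add_history(
                f"operation {spec.name}, binding {outcome.descriptor.binding}, "
                f"run {outcome.descriptor.run_index}"
            )
            write_dataset(output, process_dir / "output")
        metrics_doc = {}
        for phase, record in (("train", outcome.train_metrics), ("test", outcome.test_metrics)):
            if record is not None:
                metrics_doc[phase] = record.as_dict()
        with open(process_dir / "metrics.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(metrics_doc, fh, sort_keys=False)

    consolidate(result_dir, spec, outcomes)
    return result_dir


def build_result_rows(outcomes: Sequence[ProcessOutcome]) -> list[dict]:
    rows = []
    for outcome in outcomes:
        if not outcome.success:
            continue
        row = {
            "Dataset": outcome.descriptor.dataset_name,
            "Run": outcome.descriptor.run_index,
        }
        for token, value in outcome.descriptor.binding.items():
            row[_token_name(token)] = value
        row["train_metrics"] = outcome.train_metrics
        row["test_metrics"] = outcome.test_metrics
        rows.append(row)
    return rows


def consolidate(result_dir, spec: OperationSpec, outcomes: Sequence[ProcessOutcome]) -> None:
    """Write results.csv, archive the specs, compress process folders.

    All process sub-folders except the first are zipped and removed; one
    stays uncompressed as an example.  Failures are listed in
    ``failures.yaml``.
    """
    result_dir = Path(result_dir)
    table = aggregate_results(build_result_rows(outcomes))
    results_to_csv(table, result_dir / "results.csv")

    with zipfile.ZipFile(result_dir / "specs.zip", "w", zipfile.ZIP_DEFLATED) as archive:
        archive.writestr(
            "operation.yaml",
            yaml.safe_dump(
                {
                    "type": spec.type,
                    "input_path": spec.input_path,
                    "parameter_ranges": spec.parameter_ranges,
                    "constraints": spec.constraints,
                    "runs": spec.runs,
                },
                sort_keys=False,
            ),
        )
        archive.writestr("template.yaml", spec.template)
        archive.writestr("version.txt", f"sigflow {__version__}\n")

    failures = [
        {
            "dataset": o.descriptor.dataset_name,
            "binding": {str(k): v for k, v in o.descriptor.binding.items()},
            "run": o.descriptor.run_index,
            "error": o.error,
        }
        for o in outcomes
        if not o.success
    ]
    with open(result_dir / "failures.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(failures, fh, sort_keys=False)

    kept_example = False
    for outcome in outcomes:
        process_dir = result_dir / outcome.descriptor.output_subpath
        if not process_dir.is_dir():
            continue
        if not kept_example:
            kept_example = True
            continue
        zip_path = process_dir.with_suffix(".zip")
        with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as archive:
            for file in sorted(process_dir.rglob("*")):
                if file.is_file():
                    archive.write(file, file.relative_to(process_dir))
        shutil.rmtree(process_dir)


def run_operation_chain(
    specs: Sequence[OperationSpec],
    output_root,
    backend: Optional[Backend] = None,
) -> Path:
    """Run operations sequentially, each feeding the next one's input."""
    if not specs:
        raise ConfigurationError("operation chain must contain at least one operation")
    result_dir: Optional[Path] = None
    for i, spec in enumerate(specs):
        if i > 0:
            spec = OperationSpec(
                type=spec.type,
                input_path=str(result_dir),
                template=spec.template,
                parameter_ranges=spec.parameter_ranges,
                constraints=spec.constraints,
                runs=spec.runs,
                name=spec.name,
                options=spec.options,
            )
        result_dir = run_operation(spec, output_root, backend)
    return result_dir


# ---------------------------------------------------------------------------
# summary reorganization
# ---------------------------------------------------------------------------


def _group_key(name: str, group_pattern: Optional[str]) -> str:
    if group_pattern is None:
        return "merged"
    match = re.match(group_pattern, name)
    if match and match.groups():
        return match.group(1)
    return name


def merge_datasets(summary: Summary, group_pattern: Optional[str] = None) -> Summary:
    """Concatenate compatible datasets; groups come from a regex capture.

    Without a pattern all datasets merge into one named ``merged``.
    Group members must agree on kind, channel/feature names and sampling
    frequency.
    """
    groups: dict[str, list[str]] = {}
    for name in sorted(summary.datasets):
        groups.setdefault(_group_key(name, group_pattern), []).append(name)

    merged: dict[str, Dataset] = {}
    for group, members in sorted(groups.items()):
        first = summary.datasets[members[0]]
        samples: list = []
        for name in members:
            dataset = summary.datasets[name]
            if dataset.kind != first.kind:
                raise ConfigurationError(
                    f"cannot merge {members[0]!r} and {name!r}: kind mismatch"
                )
            for key in ("channel_names", "feature_names", "sampling_frequency"):
                if dataset.metadata.get(key) != first.metadata.get(key):
                    raise ConfigurationError(
                        f"cannot merge {members[0]!r} and {name!r}: {key} mismatch"
                    )
            samples.extend(dataset.samples)
        metadata = {
            k: v for k, v in first.metadata.items() if k not in ("history", "window_info")
        }
        metadata["history"] = [f"merged from {members}"]
        merged[group] = Dataset(kind=first.kind, samples=samples, metadata=metadata)
    return Summary(root_path=None, datasets=merged)


def shuffle_datasets(summary: Summary, seed: int) -> Summary:
    """Permute sample order within each dataset, deterministically in seed."""
    shuffled: dict[str, Dataset] = {}
    for name in sorted(summary.datasets):
        dataset = summary.datasets[name]
        # per-dataset stream so iteration order cannot matter
        sub_seed = np.random.SeedSequence([seed, *[ord(c) for c in name]])
        rng = np.random.default_rng(sub_seed)
        order = rng.permutation(len(dataset.samples))
        metadata = {k: v for k, v in dataset.metadata.items() if k != "window_info"}
        metadata = dict(metadata)
        metadata["history"] = list(metadata.get("history", [])) + [f"shuffled seed={seed}"]
        shuffled[name] = Dataset(
            kind=dataset.kind,
            samples=[dataset.samples[int(i)] for i in order],
            metadata=metadata,
        )
    return Summary(root_path=None, datasets=shuffled)
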