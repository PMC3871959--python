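"""Node contract, node registry and node-chain execution.

A *node* maps one data sample to another and may be trainable, in which
case it fixes its state from training samples before any sample is
transformed.  Nodes concatenate into a *node chain* whose head is a
source (feeding samples from a dataset) and whose tail is a sink
(gathering outputs and, for performance sinks, computing metrics).

Execution is strictly sequential and deterministic: randomized nodes
derive their seed from the run index, their position in the chain and
their name, so the triple (chain, dataset, run_index) fully determines
the output.
"""

from __future__ import annotations

import difflib
import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

from .data_model import Dataset
from .evaluation import MetricsRecord

__all__ = [
    "Node",
    "NodeSpec",
    "NodeChainSpec",
    "ValidationReport",
    "register_node",
    "resolve_node",
    "registered_node_names",
    "check_chain",
    "run_node_chain",
    "parse_node_chain_yaml",
    "derive_seed",
    "NodeChainResult",
    "UnknownNodeError",
    "ChainExecutionError",
]

KIND_ORDER = ("stream", "time_series", "feature_vector", "prediction")


class UnknownNodeError(KeyError):
    pass


class ChainExecutionError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# node base class and registry
# ---------------------------------------------------------------------------


class Node:
    """Base class for all processing nodes.

    Subclasses declare ``input_kinds`` (accepted sample kinds, or
    ``("any",)``) and ``output_kind`` (``None`` means the input kind is
    preserved).  Trainable nodes set ``trainable = True`` and implement
    :meth:`train`; every node implements :meth:`execute`, which must not
    mutate its input sample.
    """

    input_kinds: tuple[str, ...] = ("any",)
    output_kind: Optional[str] = None
    trainable: bool = False
    is_splitter: bool = False
    is_source: bool = False
    is_sink: bool = False
    #: set for nodes mapping one sample to several (e.g. stream windowers)
    expands: bool = False

    def __init__(self, **parameters):
        if parameters:
            unknown = ", ".join(sorted(parameters))
            raise TypeError(f"{type(self).__name__} got unknown parameters: {unknown}")
        self._seed: Optional[int] = None

    # -- randomness ---------------------------------------------------------
    def set_seed(self, seed: int) -> None:
        self._seed = int(seed)

    # -- training -----------------------------------------------------------
    def train(self, samples: Sequence) -> None:  # pragma: no cover - overridden
        raise NotImplementedError

    # -- execution ----------------------------------------------------------
    def execute(self, sample):
        raise NotImplementedError

    def execute_many(self, sample) -> list:
        return [self.execute(sample)]

    def accepts(self, kind: str) -> bool:
        return "any" in self.input_kinds or kind in self.input_kinds

    def output_kind_for(self, input_kind: str) -> str:
        return self.output_kind if self.output_kind is not None else input_kind


NODE_REGISTRY: dict[str, type] = {}


def register_node(cls: type) -> type:
    """Class decorator adding a node class to the global registry."""
    name = cls.__name__
    if not name.endswith("Node"):
        raise ValueError(f"node class name must end with 'Node': {name}")
    if name in NODE_REGISTRY and NODE_REGISTRY[name] is not cls:
        raise ValueError(f"duplicate node registration: {name}")
    NODE_REGISTRY[name] = cls
    return cls


def registered_node_names() -> list[str]:
    return sorted(NODE_REGISTRY)


def resolve_node(name: str) -> type:
    """Look up a node factory; the 'Node' suffix is optional."""
    _ensure_builtin_nodes()
    for candidate in (name, name + "Node"):
        if candidate in NODE_REGISTRY:
            return NODE_REGISTRY[candidate]
    matches = difflib.get_close_matches(
        name if name.endswith("Node") else name + "Node", NODE_REGISTRY, n=3, cutoff=0.5
    )
    hint = f"; did you mean {', '.join(matches)}?" if matches else ""
    raise UnknownNodeError(f"unknown node {name!r}{hint}")


def _ensure_builtin_nodes() -> None:
    # deferred import: processing_nodes registers itself on import
    from . import processing_nodes  # noqa: F401


def derive_seed(run_index: int, position: int, name: str) -> int:
    """Stable 64-bit per-node seed derived from the run index."""
    digest = hashlib.sha256(f"{run_index}|{position}|{name}".encode()).digest()
    return int.from_bytes(digest[:8], "big")


# ---------------------------------------------------------------------------
# chain specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeSpec:
    node: str
    parameters: dict = field(default_factory=dict)

    def build(self) -> Node:
        factory = resolve_node(self.node)
        return factory(**self.parameters)


@dataclass(frozen=True)
class NodeChainSpec:
    nodes: tuple[NodeSpec, ...]

    def __iter__(self):
        return iter(self.nodes)

    def __len__(self) -> int:
        return len(self.nodes)


def parse_node_chain_yaml(text: str) -> NodeChainSpec:
    """Parse a node-chain YAML document (top-level key ``node_chain``)."""
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "node_chain" not in doc:
        raise ValueError("node chain YAML must have a top-level 'node_chain' key")
    entries = doc["node_chain"]
    if not isinstance(entries, list) or not entries:
        raise ValueError("'node_chain' must be a non-empty list")
    specs = []
    for i, entry in enumerate(entries):
        if not isinstance(entry, dict) or "node" not in entry:
            raise ValueError(f"node chain entry {i} must be a mapping with a 'node' key")
        params = entry.get("parameters") or {}
        if not isinstance(params, dict):
            raise ValueError(f"node chain entry {i}: 'parameters' must be a mapping")
        specs.append(NodeSpec(node=str(entry["node"]), parameters=dict(params)))
    return NodeChainSpec(tuple(specs))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    ok: bool
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _build_nodes(chain: NodeChainSpec) -> list[Node]:
    return [spec.build() for spec in chain]


def check_chain(chain: NodeChainSpec, input_kind: str) -> ValidationReport:
    """Validate kind compatibility along a chain for the given input kind."""
    report = ValidationReport(ok=True)
    try:
        nodes = _build_nodes(chain)
    except (UnknownNodeError, TypeError, ValueError) as exc:
        report.ok = False
        report.errors.append(str(exc))
        return report

    if not nodes[0].is_source:
        report.errors.append("chain must start with a source node")
    if not nodes[-1].is_sink:
        report.errors.append("chain must end with a sink node")
    for i, node in enumerate(nodes[1:-1], start=1):
        if node.is_source or node.is_sink:
            report.errors.append(
                f"edge {i}: source/sink node {chain.nodes[i].node!r} in chain interior"
            )

    kind = input_kind
    seen_splitter = False
    trainable_without_split = []
    for i, node in enumerate(nodes):
        if not node.accepts(kind):
            report.errors.append(
                f"edge {i}: node {chain.nodes[i].node!r} needs "
                f"{' or '.join(node.input_kinds)}, got {kind!r}"
            )
            break
        if node.is_splitter:
            seen_splitter = True
        if node.trainable and not seen_splitter:
            trainable_without_split.append(chain.nodes[i].node)
        kind = node.output_kind_for(kind)
    if trainable_without_split:
        report.warnings.append(
            "trainable node(s) without an upstream splitter: "
            + ", ".join(trainable_without_split)
            + "; all samples default to test"
        )
    report.ok = not report.errors
    return report


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------


@dataclass
class NodeChainResult:
    output: Dataset
    train_metrics: Optional[MetricsRecord] = None
    test_metrics: Optional[MetricsRecord] = None


def run_node_chain(
    chain: NodeChainSpec, dataset: Dataset, run_index: int = 0
) -> NodeChainResult:
    """Execute a node chain on one dataset.

    Trainable nodes are trained strictly in chain order, each on the
    training samples as transformed by all upstream nodes; afterwards
    every sample (train and test, flagged) flows through the remaining
    chain.  ``run_index`` seeds all randomized nodes.
    """
    report = check_chain(chain, dataset.kind)
    if not report.ok:
        raise ChainExecutionError("invalid node chain: " + "; ".join(report.errors))

    nodes = _build_nodes(chain)
    source, middle, sink = nodes[0], nodes[1:-1], nodes[-1]
    if not source.accepts(dataset.kind):
        raise ChainExecutionError(
            f"source expects {' or '.join(source.input_kinds)}, dataset is {dataset.kind!r}"
        )

    samples = list(dataset.samples)
    flags = [False] * len(samples)  # by default, data are processed as testing data

    for pos, node in enumerate(middle, start=1):
        name = chain.nodes[pos].node
        seed = derive_seed(run_index, pos, name)
        if node.is_splitter:
            node.set_seed(seed)
            flags = node.split(samples)
            if len(flags) != len(samples):
                raise ChainExecutionError(f"splitter {name!r} returned wrong flag count")
            continue
        if node.trainable:
            node.set_seed(seed)
            training = [s for s, f in zip(samples, flags) if f]
            if not training:
                raise ChainExecutionError(
                    f"node {name!r} received no training data; insert a splitter"
                )
            node.train(training)
        try:
            if node.expands:
                new_samples, new_flags = [], []
                for s, f in zip(samples, flags):
                    outs = node.execute_many(s)
                    new_samples.extend(outs)
                    new_flags.extend([f] * len(outs))
                samples, flags = new_samples, new_flags
            else:
                samples = [node.execute(s) for s in samples]
        except ChainExecutionError:
            raise
        except Exception as exc:
            raise ChainExecutionError(f"node {name!r} failed: {exc}") from exc

    return sink.gather(samples, flags, dataset)
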