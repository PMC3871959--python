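"""Concrete processing algorithms and their node wrappers.

Pure functions implement the math (standardization, decimation, FIR
lowpass, xDAWN/CSP/PCA spatial filters, time-domain features, feature
normalization, a regularized linear classifier, score mapping, stratified
splitting, grid search); thin ``*Node`` classes adapt them to the chain
contract of :mod:`sigflow.node_framework`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.signal

from .data_model import (
    ConfigurationError,
    CuttingRule,
    Dataset,
    FeatureVector,
    PredictionVector,
    TimeSeriesWindow,
)
from .evaluation import METRIC_NAMES, compute_metrics
from .node_framework import Node, NodeChainResult, NodeSpec, register_node

__all__ = [
    "SpatialFilterModel",
    "LinearModel",
    "NormalizationModel",
    "SplitAssignment",
    "standardize_window",
    "decimate_window",
    "lowpass_filter_window",
    "fit_xdawn",
    "fit_csp",
    "fit_pca",
    "apply_spatial_filter",
    "extract_time_features",
    "fit_normalization",
    "apply_normalization",
    "train_linear_classifier",
    "classify",
    "map_score_sigmoid",
    "split_train_test",
    "kfold_splits",
    "grid_search",
]

RIDGE_SCALE = 1e-6
ZERO_STD = 1e-12


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


@dataclass
class SpatialFilterModel:
    """Linear channel-combination filters (columns, unit norm)."""

    filters: np.ndarray  # (n_channels, k)
    input_channel_names: tuple[str, ...]
    output_channel_names: tuple[str, ...]
    method: str  # xdawn | csp | pca | noop
    eigenvalues: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.method == "noop":
            return
        self.filters = np.asarray(self.filters, dtype=float)
        norms = np.linalg.norm(self.filters, axis=0)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("filter columns must be unit norm")


@dataclass
class LinearModel:
    weights: np.ndarray
    bias: float
    complexity: float
    class_labels: tuple[str, str]  # (negative, positive)
    feature_names: tuple[str, ...]
    name: str = "LinearClassifier"


@dataclass
class NormalizationModel:
    location: np.ndarray
    scale: np.ndarray
    feature_names: tuple[str, ...]


@dataclass
class SplitAssignment:
    """Per-sample train/test flags; ``True`` means training."""

    train_flags: tuple[bool, ...]
    split_index: int = 0

    def __iter__(self):
        return iter(self.train_flags)

    def __len__(self) -> int:
        return len(self.train_flags)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def standardize_window(w: TimeSeriesWindow) -> TimeSeriesWindow:
    """Z-score each channel (population std); flat channels become zeros."""
    values = w.values
    mean = values.mean(axis=0)
    std = values.std(axis=0)
    out = np.where(std > ZERO_STD, (values - mean) / np.where(std > ZERO_STD, std, 1.0), 0.0)
    return w.with_values(out)


def decimate_window(w: TimeSeriesWindow, factor: int) -> TimeSeriesWindow:
    """Replace consecutive blocks of ``factor`` samples by their mean."""
    factor = int(factor)
    if factor < 1:
        raise ConfigurationError("decimation factor must be >= 1")
    if factor > w.n_timepoints:
        raise ConfigurationError("decimation factor exceeds window length")
    if factor == 1:
        return w.with_values(w.values.copy())
    t = (w.n_timepoints // factor) * factor
    blocks = w.values[:t].reshape(-1, factor, w.n_channels)
    return w.with_values(
        blocks.mean(axis=1), sampling_frequency=w.sampling_frequency / factor
    )


def _fir_taps(cutoff_hz: float, fs: float) -> np.ndarray:
    n = int(np.ceil(4.0 * fs / cutoff_hz))
    if n % 2 == 0:
        n += 1
    return scipy.signal.firwin(n, cutoff_hz, fs=fs, window="hamming")


def lowpass_filter_window(w: TimeSeriesWindow, cutoff_hz: float) -> TimeSeriesWindow:
    """Linear-phase windowed-sinc lowpass, length preserving.

    Reflect padding plus centered (odd-tap) kernel compensates the group
    delay; DC gain is exactly unity.
    """
    fs = w.sampling_frequency
    if not 0 < cutoff_hz < fs / 2:
        raise ConfigurationError("cutoff must lie in (0, fs/2)")
    taps = _fir_taps(cutoff_hz, fs)
    half = len(taps) // 2
    out = np.empty_like(w.values)
    for c in range(w.n_channels):
        padded = np.pad(w.values[:, c], half, mode="reflect")
        out[:, c] = np.convolve(padded, taps, mode="valid")
    return w.with_values(out)


# ---------------------------------------------------------------------------
# spatial filters
# ---------------------------------------------------------------------------


def _fix_signs(filters: np.ndarray) -> np.ndarray:
    """Deterministic sign: the largest-magnitude entry of each column is positive."""
    out = filters.copy()
    for j in range(out.shape[1]):
        idx = int(np.argmax(np.abs(out[:, j])))
        if out[idx, j] < 0:
            out[:, j] = -out[:, j]
    return out


def _unit_columns(filters: np.ndarray) -> np.ndarray:
    return filters / np.linalg.norm(filters, axis=0, keepdims=True)


def _ridge(cov: np.ndarray) -> np.ndarray:
    c = cov.shape[0]
    return cov + (RIDGE_SCALE * np.trace(cov) / c) * np.eye(c)


def _check_windows(windows: Sequence[TimeSeriesWindow]) -> tuple[int, int]:
    shapes = {w.values.shape for w in windows}
    if len(shapes) != 1:
        raise ValueError("all training windows must share the same shape")
    return shapes.pop()


def _model(
    filters: np.ndarray,
    windows: Sequence[TimeSeriesWindow],
    method: str,
    eigenvalues: Optional[np.ndarray] = None,
) -> SpatialFilterModel:
    filters = _fix_signs(_unit_columns(filters))
    k = filters.shape[1]
    return SpatialFilterModel(
        filters=filters,
        input_channel_names=windows[0].channel_names,
        output_channel_names=tuple(f"{method}{j:02d}" for j in range(k)),
        method=method,
        eigenvalues=eigenvalues,
    )


def fit_xdawn(
    train: Sequence[TimeSeriesWindow], target_label: str, retained_channels: int
) -> SpatialFilterModel:
    """Evoked-response spatial filters via a generalized eigenproblem.

    Signal covariance comes from the mean target epoch; noise covariance
    is pooled over all training epochs after per-epoch channel mean
    removal.  Filters are the leading generalized eigenvectors.
    """
    t_len, n_ch = _check_windows(train)
    k = int(retained_channels)
    if not 1 <= k <= n_ch:
        raise ConfigurationError(f"retained_channels must be in [1, {n_ch}]")
    targets = [w for w in train if w.label == target_label]
    if len(targets) < 2:
        raise ValueError(f"need at least 2 {target_label!r} windows, got {len(targets)}")

    erp = np.mean([w.values for w in targets], axis=0)  # (T, C)
    r_signal = erp.T @ erp / t_len

    r_noise = np.zeros((n_ch, n_ch))
    for w in train:
        centered = w.values - w.values.mean(axis=0)
        r_noise += centered.T @ centered
    r_noise /= len(train) * t_len
    r_noise = _ridge(r_noise)

    eigvals, eigvecs = scipy.linalg.eigh(r_signal, r_noise)
    order = np.argsort(eigvals)[::-1][:k]
    return _model(eigvecs[:, order], train, "xdawn", eigenvalues=eigvals[order])


def fit_csp(
    train: Sequence[TimeSeriesWindow], retained_channels: int
) -> SpatialFilterModel:
    """Common spatial patterns for exactly two classes.

    Eigenvalues of ``S1 w = lam (S1 + S2) w`` are sorted descending;
    filters are taken alternately from the two ends of the spectrum.
    """
    t_len, n_ch = _check_windows(train)
    if t_len < 2:
        raise ValueError("windows too short for covariance estimation")
    k = int(retained_channels)
    if not 1 <= k <= n_ch:
        raise ConfigurationError(f"retained_channels must be in [1, {n_ch}]")
    classes = sorted({w.label for w in train if w.label is not None})
    if len(classes) != 2:
        raise ValueError(f"CSP requires exactly 2 classes, got {classes}")

    sigma = {}
    for label in classes:
        covs = []
        for w in train:
            if w.label != label:
                continue
            centered = w.values - w.values.mean(axis=0)
            cov = centered.T @ centered
            covs.append(cov / np.trace(cov))
        sigma[label] = _ridge(np.mean(covs, axis=0))

    s1, s2 = sigma[classes[0]], sigma[classes[1]]
    eigvals, eigvecs = scipy.linalg.eigh(s1, s1 + s2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    # alternate the two ends: most class-1 discriminative, most class-2, ...
    picks: list[int] = []
    lo, hi = 0, n_ch - 1
    while len(picks) < k:
        picks.append(lo)
        lo += 1
        if len(picks) < k:
            picks.append(hi)
            hi -= 1
    return _model(eigvecs[:, picks], train, "csp", eigenvalues=eigvals[picks])


def fit_pca(
    train: Sequence[TimeSeriesWindow], retained_channels: int
) -> SpatialFilterModel:
    """Principal channel directions of the pooled (centered) covariance."""
    _, n_ch = _check_windows(train)
    k = int(retained_channels)
    if not 1 <= k <= n_ch:
        raise ConfigurationError(f"retained_channels must be in [1, {n_ch}]")
    pooled = np.concatenate([w.values for w in train], axis=0)
    pooled = pooled - pooled.mean(axis=0)
    cov = pooled.T @ pooled / max(pooled.shape[0] - 1, 1)
    eigvals, eigvecs = scipy.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1][:k]
    return _model(eigvecs[:, order], train, "pca", eigenvalues=eigvals[order])


def noop_filter_model() -> SpatialFilterModel:
    return SpatialFilterModel(
        filters=np.empty((0, 0)),
        input_channel_names=(),
        output_channel_names=(),
        method="noop",
    )


def apply_spatial_filter(
    model: SpatialFilterModel, w: TimeSeriesWindow
) -> TimeSeriesWindow:
    """Project a window onto the filter columns (``values @ filters``)."""
    if model.method == "noop":
        return w
    if w.channel_names != model.input_channel_names:
        raise ValueError(
            f"channel mismatch: window has {w.channel_names}, "
            f"model trained on {model.input_channel_names}"
        )
    return w.with_values(w.values @ model.filters, channel_names=model.output_channel_names)


# ---------------------------------------------------------------------------
# features, normalization, classification
# ---------------------------------------------------------------------------


def _time_label(time_ms: float) -> str:
    return str(round(time_ms, 6))


def extract_time_features(w: TimeSeriesWindow) -> FeatureVector:
    """Flatten a window row-major into named amplitude features."""
    step_ms = 1000.0 / w.sampling_frequency
    names = tuple(
        f"TD_{ch}_{_time_label(t * step_ms)}"
        for t in range(w.n_timepoints)
        for ch in w.channel_names
    )
    return FeatureVector(values=w.values.ravel().copy(), feature_names=names, label=w.label)


def fit_normalization(train: Sequence[FeatureVector]) -> NormalizationModel:
    if len(train) < 2:
        raise ValueError("feature normalization needs at least 2 training vectors")
    names = train[0].feature_names
    for fv in train:
        if fv.feature_names != names:
            raise ValueError("training vectors disagree on feature names")
    matrix = np.stack([fv.values for fv in train])
    return NormalizationModel(
        location=matrix.mean(axis=0), scale=matrix.std(axis=0), feature_names=names
    )


def apply_normalization(model: NormalizationModel, fv: FeatureVector) -> FeatureVector:
    if fv.feature_names != model.feature_names:
        raise ValueError("feature names do not match the normalization model")
    ok = model.scale > ZERO_STD
    values = np.where(ok, (fv.values - model.location) / np.where(ok, model.scale, 1.0), 0.0)
    return FeatureVector(values=values, feature_names=fv.feature_names, label=fv.label)


def _logistic_objective(params, x, y, inv_c):
    w, b = params[:-1], params[-1]
    z = y * (x @ w + b)
    loss = np.logaddexp(0.0, -z).sum() + 0.5 * inv_c * w @ w
    s = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))  # = sigmoid(-z)
    grad_w = -(x.T @ (y * s)) + inv_c * w
    grad_b = -(y * s).sum()
    return loss, np.append(grad_w, grad_b)


def train_linear_classifier(
    train: Sequence[FeatureVector],
    complexity: float,
    class_labels: Optional[tuple[str, str]] = None,
) -> LinearModel:
    """L2-regularized logistic regression with inverse regularization C.

    Minimizes ``sum log(1 + exp(-y (w.x + b))) + ||w||^2 / (2 C)`` with a
    deterministic quasi-Newton solver from zero initialization; the bias
    is not penalized.
    """
    if complexity <= 0:
        raise ConfigurationError("complexity must be positive")
    if class_labels is None:
        present = sorted({fv.label for fv in train if fv.label is not None})
        if len(present) != 2:
            raise ValueError(f"need exactly 2 classes in training data, got {present}")
        class_labels = (present[0], present[1])
    names = train[0].feature_names
    x = np.stack([fv.values for fv in train])
    y = np.array([1.0 if fv.label == class_labels[1] else -1.0 for fv in train])
    if len(set(y)) < 2:
        raise ValueError("training data contains a single class")

    result = scipy.optimize.minimize(
        _logistic_objective,
        x0=np.zeros(x.shape[1] + 1),
        args=(x, y, 1.0 / complexity),
        method="L-BFGS-B",
        jac=True,
        options={"ftol": 1e-14, "gtol": 1e-8, "maxiter": 2000},
    )
    params = result.x
    return LinearModel(
        weights=params[:-1],
        bias=float(params[-1]),
        complexity=float(complexity),
        class_labels=tuple(class_labels),
        feature_names=names,
    )


def classify(model: LinearModel, fv: FeatureVector) -> PredictionVector:
    """Score a feature vector; ties (score 0) go to the positive class."""
    if fv.feature_names != model.feature_names:
        raise ValueError("feature names do not match the classifier model")
    score = float(model.weights @ fv.values + model.bias)
    label = model.class_labels[1] if score >= 0 else model.class_labels[0]
    return PredictionVector(
        score=score, assigned_label=label, true_label=fv.label, classifier_name=model.name
    )


def map_score_sigmoid(p: PredictionVector, scale: float = 1.0) -> PredictionVector:
    if scale <= 0:
        raise ConfigurationError("sigmoid scale must be positive")
    score = 1.0 / (1.0 + np.exp(-scale * p.score))
    return PredictionVector(
        score=float(score),
        assigned_label=p.assigned_label,
        true_label=p.true_label,
        classifier_name=p.classifier_name,
    )


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def _labels_of(samples: Sequence) -> list[str]:
    labels = [getattr(s, "label", None) for s in samples]
    if any(lab is None for lab in labels):
        raise ValueError("stratified splitting requires every sample to be labeled")
    return labels


def split_train_test(
    samples: Sequence, train_fraction: float, seed: int
) -> SplitAssignment:
    """Stratified single split; each class keeps >= 1 sample on both sides."""
    if not 0 < train_fraction < 1:
        raise ConfigurationError("train_fraction must lie in (0, 1)")
    labels = _labels_of(samples)
    classes = sorted(set(labels))
    per_class = {lab: [i for i, l in enumerate(labels) if l == lab] for lab in classes}
    for lab, idx in per_class.items():
        if len(idx) < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 samples; cannot split")

    # largest-remainder apportionment of the overall train count across
    # classes, so an equal split of a balanced set is exactly half/half
    target = int(np.floor(len(samples) * train_fraction + 0.5))
    base = {lab: int(np.floor(len(idx) * train_fraction)) for lab, idx in per_class.items()}
    remainder = {
        lab: len(idx) * train_fraction - base[lab] for lab, idx in per_class.items()
    }
    n_train = dict(base)
    leftover = target - sum(base.values())
    for lab in sorted(classes, key=lambda l: (-remainder[l], l))[:max(leftover, 0)]:
        n_train[lab] += 1
    for lab, idx in per_class.items():
        n_train[lab] = min(max(n_train[lab], 1), len(idx) - 1)

    rng = np.random.default_rng(seed)
    flags = [False] * len(samples)
    for lab in classes:
        idx = np.array(per_class[lab])
        rng.shuffle(idx)
        for i in idx[: n_train[lab]]:
            flags[int(i)] = True
    return SplitAssignment(train_flags=tuple(flags))


def kfold_splits(samples: Sequence, k: int, seed: int) -> list[SplitAssignment]:
    """Stratified k folds, dealt round-robin after a seeded shuffle.

    Split ``i`` marks fold ``i`` as validation (test flag); per-class
    fold sizes differ by at most one.
    """
    labels = _labels_of(samples)
    counts = {label: labels.count(label) for label in set(labels)}
    smallest = min(counts.values())
    if not 2 <= k <= smallest:
        raise ConfigurationError(
            f"k must lie in [2, {smallest}] (smallest class size), got {k}"
        )
    rng = np.random.default_rng(seed)
    fold_of = [0] * len(samples)
    for label in sorted(counts):
        idx = np.array([i for i, lab in enumerate(labels) if lab == label])
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            fold_of[int(i)] = j % k
    return [
        SplitAssignment(
            train_flags=tuple(fold_of[i] != fold for i in range(len(samples))),
            split_index=fold,
        )
        for fold in range(k)
    ]


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------


def _bind_specs(specs: Sequence[NodeSpec], binding: dict) -> list[NodeSpec]:
    bound = []
    for spec in specs:
        params = {
            key: binding[val] if isinstance(val, str) and val in binding else val
            for key, val in spec.parameters.items()
        }
        bound.append(NodeSpec(node=spec.node, parameters=params))
    return bound


def _train_tail(specs: Sequence[NodeSpec], samples: list) -> list[Node]:
    nodes = []
    current = list(samples)
    for spec in specs:
        node = spec.build()
        if node.trainable:
            node.train(current)
        current = [node.execute(s) for s in current]
        nodes.append(node)
    return nodes


def _apply_tail(nodes: Sequence[Node], samples: Sequence) -> list:
    out = list(samples)
    for node in nodes:
        out = [node.execute(s) for s in out]
    return out


def grid_search(
    inner_chain_tail: Sequence[NodeSpec],
    grid: dict,
    k: int,
    metric: str,
    train: Sequence,
    seed: int,
    positive_class: str = "Target",
) -> tuple[dict, list[Node], dict]:
    """Exhaustive hyper-parameter search with stratified k-fold CV.

    Returns the winning binding (ties broken by listed order), the tail
    retrained on all training samples, and the per-binding mean scores.
    """
    if not grid:
        raise ConfigurationError("parameter grid must not be empty")
    if metric not in METRIC_NAMES:
        raise ConfigurationError(f"unknown metric {metric!r}; choose from {METRIC_NAMES}")
    tokens = list(grid)
    bindings = [
        dict(zip(tokens, combo)) for combo in itertools.product(*(grid[t] for t in tokens))
    ]
    folds = kfold_splits(train, k, seed) if len(bindings) > 1 else []

    scores: dict[tuple, float] = {}
    best_binding, best_score = bindings[0], -np.inf
    for binding in bindings:
        if folds:
            fold_scores = []
            for assignment in folds:
                tr = [s for s, f in zip(train, assignment.train_flags) if f]
                va = [s for s, f in zip(train, assignment.train_flags) if not f]
                nodes = _train_tail(_bind_specs(inner_chain_tail, binding), tr)
                predictions = _apply_tail(nodes, va)
                record = compute_metrics(predictions, positive_class)
                fold_scores.append(getattr(record, metric))
            mean_score = float(np.mean(fold_scores))
        else:
            mean_score = 0.0
        scores[tuple(binding.values())] = mean_score
        if mean_score > best_score:  # strict: earliest listed binding wins ties
            best_binding, best_score = binding, mean_score

    retrained = _train_tail(_bind_specs(inner_chain_tail, best_binding), list(train))
    return best_binding, retrained, scores


# ---------------------------------------------------------------------------
# node wrappers
# ---------------------------------------------------------------------------


@register_node
class NoopNode(Node):
    """Identity node; baseline for algorithm comparisons.

    Accepts and ignores ``retained_channels`` so it is interchangeable
    with the spatial-filter nodes in parameterized templates.
    """

    input_kinds = ("any",)

    def __init__(self, retained_channels: Optional[int] = None):
        super().__init__()
        self.retained_channels = retained_channels

    def execute(self, sample):
        return sample


@register_node
class StandardizationNode(Node):
    input_kinds = ("time_series",)

    def execute(self, sample):
        return standardize_window(sample)


@register_node
class DecimationNode(Node):
    input_kinds = ("time_series",)

    def __init__(self, factor: int = 1):
        super().__init__()
        self.factor = int(factor)
        if self.factor < 1:
            raise ConfigurationError("decimation factor must be >= 1")

    def execute(self, sample):
        return decimate_window(sample, self.factor)


@register_node
class LowpassFilterNode(Node):
    input_kinds = ("time_series",)

    def __init__(self, cutoff_hz: float):
        super().__init__()
        self.cutoff_hz = float(cutoff_hz)

    def execute(self, sample):
        return lowpass_filter_window(sample, self.cutoff_hz)


@register_node
class MarkerWindowerNode(Node):
    """Stream-to-windows segmentation inside a chain (one rule per mapping)."""

    input_kinds = ("stream",)
    output_kind = "time_series"
    expands = True

    def __init__(self, rules: Sequence[dict] = ()):
        super().__init__()
        if not rules:
            raise ConfigurationError("MarkerWindower needs at least one cutting rule")
        self.rules = [
            CuttingRule(
                marker_name=str(r["marker_name"]),
                window_start_ms=float(r["window_start_ms"]),
                window_end_ms=float(r["window_end_ms"]),
                class_label=str(r["class_label"]),
            )
            for r in rules
        ]

    def execute_many(self, sample):
        from .data_model import segment_by_markers

        return segment_by_markers(sample, self.rules).windows

    def execute(self, sample):  # pragma: no cover - expands is used instead
        raise NotImplementedError


class _SpatialFilterNode(Node):
    input_kinds = ("time_series",)
    trainable = True
    method = ""

    def __init__(self, retained_channels: int):
        super().__init__()
        self.retained_channels = int(retained_channels)
        self.model: Optional[SpatialFilterModel] = None

    def execute(self, sample):
        if self.model is None:
            raise RuntimeError(f"{type(self).__name__} used before training")
        return apply_spatial_filter(self.model, sample)


@register_node
class XDAWNNode(_SpatialFilterNode):
    method = "xdawn"

    def __init__(self, retained_channels: int, target_label: str = "Target"):
        super().__init__(retained_channels)
        self.target_label = target_label

    def train(self, samples):
        self.model = fit_xdawn(samples, self.target_label, self.retained_channels)


@register_node
class CSPNode(_SpatialFilterNode):
    method = "csp"

    def train(self, samples):
        self.model = fit_csp(samples, self.retained_channels)


@register_node
class PCANode(_SpatialFilterNode):
    method = "pca"

    def train(self, samples):
        self.model = fit_pca(samples, self.retained_channels)


@register_node
class TimeDomainFeaturesNode(Node):
    input_kinds = ("time_series",)
    output_kind = "feature_vector"

    def execute(self, sample):
        return extract_time_features(sample)


@register_node
class FeatureNormalizationNode(Node):
    input_kinds = ("feature_vector",)
    trainable = True

    def __init__(self):
        super().__init__()
        self.model: Optional[NormalizationModel] = None

    def train(self, samples):
        self.model = fit_normalization(samples)

    def execute(self, sample):
        if self.model is None:
            raise RuntimeError("FeatureNormalizationNode used before training")
        return apply_normalization(self.model, sample)


@register_node
class LinearClassifierNode(Node):
    input_kinds = ("feature_vector",)
    output_kind = "prediction"
    trainable = True

    def __init__(self, complexity: float = 1.0, class_labels: Optional[Sequence[str]] = None):
        super().__init__()
        self.complexity = float(complexity)
        self.class_labels = tuple(class_labels) if class_labels else None
        self.model: Optional[LinearModel] = None

    def train(self, samples):
        self.model = train_linear_classifier(samples, self.complexity, self.class_labels)

    def execute(self, sample):
        if self.model is None:
            raise RuntimeError("LinearClassifierNode used before training")
        return classify(self.model, sample)


@register_node
class SigmoidScoreMappingNode(Node):
    input_kinds = ("prediction",)

    def __init__(self, scale: float = 1.0):
        super().__init__()
        self.scale = float(scale)

    def execute(self, sample):
        return map_score_sigmoid(sample, self.scale)


@register_node
class TrainTestSplitterNode(Node):
    """Stratified random split; seeded by the run index via the framework."""

    input_kinds = ("any",)
    is_splitter = True

    def __init__(self, train_fraction: float = 0.5):
        super().__init__()
        self.train_fraction = float(train_fraction)

    def split(self, samples) -> list[bool]:
        if self._seed is None:
            raise RuntimeError("splitter seed was not set")
        return list(split_train_test(samples, self.train_fraction, self._seed).train_flags)


@register_node
class GridSearchNode(Node):
    """Meta node: k-fold grid search over the parameters of an inner tail.

    ``nodes`` is the inner node list (same YAML shape as a chain) whose
    parameter values may name grid tokens; ``grid`` maps each token to
    its candidate values.
    """

    trainable = True

    def __init__(
        self,
        nodes: Sequence[dict],
        grid: dict,
        folds: int = 5,
        metric: str = "balanced_accuracy",
        positive_class: str = "Target",
    ):
        super().__init__()
        if not nodes:
            raise ConfigurationError("GridSearch needs a non-empty inner node list")
        self.inner_specs = [
            NodeSpec(node=str(e["node"]), parameters=dict(e.get("parameters") or {}))
            for e in nodes
        ]
        self.grid = {str(k): list(v) for k, v in grid.items()}
        for token, values in self.grid.items():
            if not values:
                raise ConfigurationError(f"empty grid for token {token!r}")
        self.folds = int(folds)
        self.metric = str(metric)
        self.positive_class = str(positive_class)
        self.best_binding: Optional[dict] = None
        self.scores: Optional[dict] = None
        self._tail: Optional[list[Node]] = None
        # kind bookkeeping from a representative instantiation
        probe_binding = {t: v[0] for t, v in self.grid.items()}
        self._probe = [s.build() for s in _bind_specs(self.inner_specs, probe_binding)]

    @property
    def input_kinds(self):  # type: ignore[override]
        return self._probe[0].input_kinds

    def output_kind_for(self, input_kind: str) -> str:
        kind = input_kind
        for node in self._probe:
            kind = node.output_kind_for(kind)
        return kind

    def train(self, samples):
        if self._seed is None:
            raise RuntimeError("grid-search seed was not set")
        self.best_binding, self._tail, self.scores = grid_search(
            self.inner_specs,
            self.grid,
            self.folds,
            self.metric,
            samples,
            self._seed,
            self.positive_class,
        )

    def execute(self, sample):
        if self._tail is None:
            raise RuntimeError("GridSearchNode used before training")
        for node in self._tail:
            sample = node.execute(sample)
        return sample


# ---------------------------------------------------------------------------
# sources and sinks
# ---------------------------------------------------------------------------


class _SourceNode(Node):
    is_source = True

    def execute(self, sample):
        return sample


@register_node
class StreamSourceNode(_SourceNode):
    input_kinds = ("stream",)


@register_node
class TimeSeriesSourceNode(_SourceNode):
    input_kinds = ("time_series",)


@register_node
class FeatureVectorSourceNode(_SourceNode):
    input_kinds = ("feature_vector",)


class _CollectingSinkNode(Node):
    is_sink = True
    collected_kind = ""

    def gather(self, samples, flags, input_dataset) -> NodeChainResult:
        metadata = {
            "kind": self.collected_kind,
            "history": list(input_dataset.metadata.get("history", []))
            + [f"collected by {type(self).__name__}"],
        }
        return NodeChainResult(
            output=Dataset(kind=self.collected_kind, samples=list(samples), metadata=metadata)
        )

    def execute(self, sample):  # pragma: no cover - sinks only gather
        return sample


@register_node
class TimeSeriesSinkNode(_CollectingSinkNode):
    input_kinds = ("time_series",)
    collected_kind = "time_series"


@register_node
class FeatureVectorSinkNode(_CollectingSinkNode):
    input_kinds = ("feature_vector",)
    collected_kind = "feature_vector"


@register_node
class PerformanceSinkNode(Node):
    """Gathers predictions and computes metrics separately per phase."""

    input_kinds = ("prediction",)
    is_sink = True

    def __init__(self, positive_class: str = "Target"):
        super().__init__()
        self.positive_class = positive_class

    def gather(self, samples, flags, input_dataset) -> NodeChainResult:
        train = [s for s, f in zip(samples, flags) if f]
        test = [s for s, f in zip(samples, flags) if not f]
        metadata = {
            "kind": "prediction",
            "history": list(input_dataset.metadata.get("history", []))
            + ["collected by PerformanceSinkNode"],
        }
        return NodeChainResult(
            output=Dataset(kind="prediction", samples=list(samples), metadata=metadata),
            train_metrics=(
                compute_metrics(train, self.positive_class, phase="train") if train else None
            ),
            test_metrics=(
                compute_metrics(test, self.positive_class, phase="test") if test else None
            ),
        )

    def execute(self, sample):  # pragma: no cover - sinks only gather
        return sample
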