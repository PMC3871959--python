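"""Core in-memory data types and stream segmentation.

Data samples come in four granularities: a continuous :class:`RawStream`,
fixed-length :class:`TimeSeriesWindow` epochs cut from it, flat
:class:`FeatureVector` samples and classifier :class:`PredictionVector`
outputs.  A :class:`Dataset` bundles the samples of one experimental run
together with metadata; a :class:`Summary` is a named collection of
datasets backed by a directory tree.

Array orientation is fixed throughout the package: rows are time points,
columns are channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Optional, Sequence

import numpy as np

__all__ = [
    "Marker",
    "RawStream",
    "TimeSeriesWindow",
    "FeatureVector",
    "PredictionVector",
    "CuttingRule",
    "Dataset",
    "Summary",
    "SegmentationResult",
    "segment_by_markers",
    "segment_equidistant",
    "ConfigurationError",
]

KINDS = ("stream", "time_series", "feature_vector", "prediction")


class ConfigurationError(ValueError):
    """Raised for invalid user-supplied configuration values."""


def _check_unique(names: Sequence[str], what: str) -> None:
    if len(set(names)) != len(names):
        seen, dups = set(), []
        for n in names:
            if n in seen:
                dups.append(n)
            seen.add(n)
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass(frozen=True)
class Marker:
    """Event marker: a named position (sample index) in a stream."""

    sample_index: int
    name: str


@dataclass
class RawStream:
    """Continuous multichannel recording with event markers.

    ``samples`` has shape (n_samples, n_channels); markers are kept sorted
    by sample index (stable for ties).
    """

    samples: np.ndarray
    channel_names: tuple[str, ...]
    sampling_frequency: float
    markers: tuple[Marker, ...] = ()

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("stream samples must be a 2-D array")
        self.channel_names = tuple(self.channel_names)
        _check_unique(self.channel_names, "channel names")
        if len(self.channel_names) != self.samples.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[1]} data columns"
            )
        if not self.sampling_frequency > 0:
            raise ValueError("sampling_frequency must be positive")
        markers = tuple(Marker(int(m.sample_index), str(m.name)) for m in self.markers)
        n = self.samples.shape[0]
        for m in markers:
            if not 0 <= m.sample_index < n:
                raise ValueError(
                    f"marker {m.name!r} at sample {m.sample_index} outside [0, {n})"
                )
        # stable sort preserves the order of ties
        self.markers = tuple(sorted(markers, key=lambda m: m.sample_index))

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


@dataclass
class TimeSeriesWindow:
    """One segmented epoch: (n_timepoints, n_channels) amplitudes."""

    values: np.ndarray
    channel_names: tuple[str, ...]
    sampling_frequency: float
    start_time_ms: float = 0.0
    label: Optional[str] = None
    tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("window values must be a 2-D array")
        self.channel_names = tuple(self.channel_names)
        _check_unique(self.channel_names, "channel names")
        if len(self.channel_names) != self.values.shape[1]:
            raise ValueError("channel_names length must match value columns")
        if not self.sampling_frequency > 0:
            raise ValueError("sampling_frequency must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("window values must be finite")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def with_values(
        self,
        values: np.ndarray,
        channel_names: Optional[Sequence[str]] = None,
        sampling_frequency: Optional[float] = None,
    ) -> "TimeSeriesWindow":
        """Copy carrying over timing/label metadata."""
        return TimeSeriesWindow(
            values=np.asarray(values, dtype=float),
            channel_names=tuple(channel_names) if channel_names is not None else self.channel_names,
            sampling_frequency=sampling_frequency if sampling_frequency is not None else self.sampling_frequency,
            start_time_ms=self.start_time_ms,
            label=self.label,
            tag=self.tag,
        )


@dataclass
class FeatureVector:
    """Named 1-D feature values with an optional class label."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.feature_names = tuple(self.feature_names)
        _check_unique(self.feature_names, "feature names")
        if len(self.values) != len(self.feature_names):
            raise ValueError("values and feature_names length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


@dataclass
class PredictionVector:
    """Classifier decision value plus assigned (and true) label."""

    score: float
    assigned_label: str
    true_label: Optional[str] = None
    classifier_name: str = ""


@dataclass(frozen=True)
class CuttingRule:
    """Window extraction rule: offsets in ms relative to a named marker."""

    marker_name: str
    window_start_ms: float
    window_end_ms: float
    class_label: str

    def __post_init__(self) -> None:
        if not self.window_end_ms > self.window_start_ms:
            raise ConfigurationError("window_end_ms must exceed window_start_ms")


@dataclass
class Dataset:
    """All samples of one experimental run plus metadata.

    ``metadata`` is a plain dict so that io code can round-trip arbitrary
    keys; the ``history`` entry records prior processing steps.
    """

    kind: str
    samples: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown dataset kind {self.kind!r}; expected one of {KINDS}")
        self.metadata.setdefault("kind", self.kind)
        self.metadata.setdefault("history", [])

    def __len__(self) -> int:
        return len(self.samples)

    def add_history(self, entry: str) -> None:
        self.metadata.setdefault("history", []).append(str(entry))


@dataclass
class Summary:
    """Named collection of datasets, usually mirroring a directory tree."""

    root_path: Optional[str] = None
    datasets: dict[str, Dataset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.datasets = dict(self.datasets)

    def __len__(self) -> int:
        return len(self.datasets)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


@dataclass
class SegmentationResult:
    """Windows plus a tally of windows dropped at stream boundaries."""

    windows: list[TimeSeriesWindow]
    n_dropped: int = 0

    def __iter__(self):
        return iter(self.windows)

    def __len__(self) -> int:
        return len(self.windows)


def _offset_to_samples(offset_ms: float, fs: float) -> int:
    """Convert a millisecond offset to a whole sample count.

    Rounds to the nearest sample; an offset that is not representable
    within floating tolerance is accepted (rounding is the contract).
    """
    return int(round(offset_ms * fs / 1000.0))


def segment_by_markers(
    stream: RawStream, rules: Sequence[CuttingRule]
) -> SegmentationResult:
    """Cut labeled windows around event markers.

    A window for marker position ``m`` and rule offsets ``(start, end)``
    spans samples ``[m + start, m + end)`` (half-open, 0-based).  Windows
    extending beyond the stream are dropped silently and counted.  A
    marker may match several rules; each match emits a window.
    """
    if not rules:
        raise ConfigurationError("at least one cutting rule is required")
    fs = stream.sampling_frequency
    resolved = []
    for rule in rules:
        start = _offset_to_samples(rule.window_start_ms, fs)
        end = _offset_to_samples(rule.window_end_ms, fs)
        if end - start < 1:
            raise ConfigurationError(
                f"rule for marker {rule.marker_name!r} yields a zero-length window"
            )
        resolved.append((rule, start, end))

    windows: list[tuple[int, TimeSeriesWindow]] = []
    n_dropped = 0
    n = stream.n_samples
    for marker in stream.markers:
        for rule, start, end in resolved:
            if marker.name != rule.marker_name:
                continue
            lo = marker.sample_index + start
            hi = marker.sample_index + end
            if lo < 0 or hi > n:
                n_dropped += 1
                continue
            window = TimeSeriesWindow(
                values=stream.samples[lo:hi].copy(),
                channel_names=stream.channel_names,
                sampling_frequency=fs,
                start_time_ms=lo * 1000.0 / fs,
                label=rule.class_label,
                tag=f"marker={marker.name}@{marker.sample_index}",
            )
            windows.append((lo, window))
    windows.sort(key=lambda item: item[0])
    return SegmentationResult([w for _, w in windows], n_dropped)


def segment_equidistant(
    stream: RawStream,
    window_ms: float,
    step_ms: float,
    label: Optional[str] = None,
) -> SegmentationResult:
    """Cut equally spaced windows starting at sample 0.

    Only fully contained windows are returned; for ``n_samples >= w`` the
    count is ``floor((n_samples - w) / step) + 1``.
    """
    if window_ms <= 0 or step_ms <= 0:
        raise ConfigurationError("window_ms and step_ms must be positive")
    fs = stream.sampling_frequency
    w = _offset_to_samples(window_ms, fs)
    step = _offset_to_samples(step_ms, fs)
    if w < 1 or step < 1:
        raise ConfigurationError("window and step must be at least one sample")
    windows = []
    n = stream.n_samples
    for lo in range(0, n - w + 1, step):
        windows.append(
            TimeSeriesWindow(
                values=stream.samples[lo : lo + w].copy(),
                channel_names=stream.channel_names,
                sampling_frequency=fs,
                start_time_ms=lo * 1000.0 / fs,
                label=label,
                tag=f"equidistant@{lo}",
            )
        )
    return SegmentationResult(windows, 0)
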