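"""Synthetic fixtures: an oddball recording with a planted spatial pattern.

The generator emulates a rare-target / frequent-standard stimulation
experiment.  Each target stimulus adds a half-sine deflection (default
latency 300 ms, width 200 ms) times a fixed unit-norm spatial pattern on
top of white Gaussian channel noise, so spatial-filter and classifier
stages have a known ground truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import Dataset, FeatureVector, Marker, RawStream

__all__ = [
    "SyntheticGroundTruth",
    "generate_oddball_stream",
    "generate_gaussian_features",
]


@dataclass
class SyntheticGroundTruth:
    """Planted signal parameters of a generated oddball stream."""

    spatial_pattern: np.ndarray
    erp_amplitude: float
    erp_latency_ms: float
    erp_width_ms: float
    noise_sigma: float
    marker_schedule: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spatial_pattern = np.asarray(self.spatial_pattern, dtype=float)
        norm = float(np.linalg.norm(self.spatial_pattern))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("spatial pattern must be unit norm")
        if self.erp_amplitude < 0:
            raise ValueError("amplitude must be non-negative")


def _half_sine(n: int) -> np.ndarray:
    # positive half wave over n samples
    return np.sin(np.pi * (np.arange(n) + 0.5) / n)


def generate_oddball_stream(
    n_channels: int = 8,
    sampling_frequency: float = 100.0,
    n_targets: int = 50,
    n_standards: int = 200,
    isi_ms: float = 1000.0,
    amplitude: float = 2.0,
    noise_sigma: float = 1.0,
    seed: int = 0,
    erp_latency_ms: float = 300.0,
    erp_width_ms: float = 200.0,
) -> tuple[RawStream, SyntheticGroundTruth]:
    """Generate a continuous oddball recording with markers.

    Stimuli are presented in seeded random order at a fixed inter-stimulus
    interval.  Targets add ``amplitude * half_sine * pattern`` starting
    ``erp_latency_ms`` after their onset.  Deterministic in ``seed``.
    """
    if n_channels < 1:
        raise ValueError("need at least one channel")
    if n_targets < 1 or n_standards < 1:
        raise ValueError("stimulus counts must be positive")
    fs = sampling_frequency
    isi = int(round(isi_ms * fs / 1000.0))
    latency = int(round(erp_latency_ms * fs / 1000.0))
    width = int(round(erp_width_ms * fs / 1000.0))
    if latency + width > isi:
        raise ValueError("ERP would overlap the next epoch; increase isi_ms")

    rng = np.random.default_rng(seed)
    pattern = rng.normal(size=n_channels)
    pattern /= np.linalg.norm(pattern)

    n_stimuli = n_targets + n_standards
    order = np.array(["Target"] * n_targets + ["Standard"] * n_standards)
    rng.shuffle(order)

    # one trailing ISI so the last window fits entirely in the stream
    n_samples = (n_stimuli + 1) * isi
    data = rng.normal(scale=noise_sigma, size=(n_samples, n_channels))

    erp = amplitude * _half_sine(width)
    markers = []
    schedule = []
    for i, name in enumerate(order):
        onset = i * isi
        markers.append(Marker(onset, str(name)))
        schedule.append((onset, str(name)))
        if name == "Target":
            lo = onset + latency
            data[lo : lo + width] += np.outer(erp, pattern)

    stream = RawStream(
        samples=data,
        channel_names=tuple(f"ch{i + 1}" for i in range(n_channels)),
        sampling_frequency=fs,
        markers=tuple(markers),
    )
    truth = SyntheticGroundTruth(
        spatial_pattern=pattern,
        erp_amplitude=amplitude,
        erp_latency_ms=erp_latency_ms,
        erp_width_ms=erp_width_ms,
        noise_sigma=noise_sigma,
        marker_schedule=schedule,
    )
    return stream, truth


def generate_gaussian_features(
    n_per_class: int,
    n_features: int,
    separation: float,
    seed: int = 0,
) -> Dataset:
    """Two spherical Gaussian classes with means ``±(separation/2)·u``.

    ``u`` is a seeded random unit direction; labels are ``Standard`` and
    ``Target``.  With identity covariance the Bayes accuracy is
    ``Phi(separation / 2)``.
    """
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    u = rng.normal(size=n_features)
    u /= np.linalg.norm(u)
    names = tuple(f"f{i}" for i in range(n_features))
    samples = []
    for label, sign in (("Standard", -1.0), ("Target", 1.0)):
        mean = sign * (separation / 2.0) * u
        points = rng.normal(size=(n_per_class, n_features)) + mean
        for row in points:
            samples.append(FeatureVector(row, names, label=label))
    return Dataset(
        kind="feature_vector",
        samples=samples,
        metadata={"kind": "feature_vector", "classes": ["Standard", "Target"], "history": []},
    )
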