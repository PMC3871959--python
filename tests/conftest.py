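import numpy as np
import pytest

from sigflow.data_model import CuttingRule, Dataset, TimeSeriesWindow, segment_by_markers
from sigflow.synthetic import generate_gaussian_features, generate_oddball_stream

ODDBALL_RULES = [
    CuttingRule("Target", 0.0, 1000.0, "Target"),
    CuttingRule("Standard", 0.0, 1000.0, "Standard"),
]


def make_window(values, fs=100.0, label=None, channel_names=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1:
        values = values.T
    if channel_names is None:
        channel_names = tuple(f"ch{i + 1}" for i in range(values.shape[1]))
    return TimeSeriesWindow(
        values=values, channel_names=channel_names, sampling_frequency=fs, label=label
    )


def oddball_dataset(seed=0, amplitude=2.0, n_targets=50, n_standards=200, n_channels=8):
    stream, truth = generate_oddball_stream(
        n_channels=n_channels,
        n_targets=n_targets,
        n_standards=n_standards,
        amplitude=amplitude,
        seed=seed,
    )
    windows = segment_by_markers(stream, ODDBALL_RULES).windows
    dataset = Dataset(
        kind="time_series",
        samples=windows,
        metadata={"kind": "time_series", "history": []},
    )
    return dataset, truth


@pytest.fixture(scope="session")
def oddball():
    """Medium oddball dataset with a clearly recoverable pattern."""
    return oddball_dataset(seed=0)


@pytest.fixture(scope="session")
def gaussian_features():
    return generate_gaussian_features(n_per_class=50, n_features=4, separation=6.0, seed=0)


@pytest.fixture()
def example_chain_text():
    return """
node_chain:
  - node: TimeSeriesSource
  - node: Standardization
  - node: Decimation
    parameters: {factor: 4}
  - node: LowpassFilter
    parameters: {cutoff_hz: 10}
  - node: TrainTestSplitter
    parameters: {train_fraction: 0.5}
  - node: XDAWN
    parameters: {retained_channels: 4}
  - node: TimeDomainFeatures
  - node: FeatureNormalization
  - node: GridSearch
    parameters:
      nodes:
        - node: LinearClassifier
          parameters: {complexity: __C__}
      grid: {__C__: [0.01, 0.1, 1.0]}
      folds: 5
      metric: balanced_accuracy
  - node: PerformanceSink
"""
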