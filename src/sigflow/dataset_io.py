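"""On-disk storage: CSV streams and datasets, ARFF feature vectors, YAML metadata.

Each dataset lives in its own directory holding ``metadata.yaml`` plus the
data files.  Layouts:

* stream          — ``data.csv`` (header = channel names, one row per
                    sample) and ``markers.csv`` (``sample_index,name``)
* time_series     — ``data.csv`` with columns
                    ``window_id,label,time_index,<channel...>``
* feature_vector  — ``data.csv`` with columns ``<feature...>,label``
                    or an ARFF file (``data.arff``)
* prediction      — ``data.csv`` with columns
                    ``score,assigned_label,true_label,classifier``

CSV dialect is fixed: comma separator, ``.`` decimal point, mandatory
header row, UTF-8, floats printed with 17 significant digits so round
trips are bit exact for doubles.
"""

from __future__ import annotations

import csv
import os
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .data_model import (
    Dataset,
    FeatureVector,
    Marker,
    PredictionVector,
    RawStream,
    Summary,
    TimeSeriesWindow,
)

__all__ = [
    "FormatError",
    "read_stream_csv",
    "write_stream_csv",
    "write_dataset",
    "read_dataset",
    "write_arff",
    "read_arff",
    "read_summary",
    "write_summary",
    "METADATA_FILENAME",
]

METADATA_FILENAME = "metadata.yaml"
FLOAT_FORMAT = "%.17g"


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


def _fmt(x: float) -> str:
    return FLOAT_FORMAT % float(x)


def _parse_float(cell: str, path, line_no: int) -> float:
    try:
        value = float(cell)
    except ValueError:
        raise FormatError(f"{path}: non-numeric cell {cell!r}, line {line_no}") from None
    if not np.isfinite(value):
        raise FormatError(f"{path}: non-finite value {cell!r}, line {line_no}")
    return value


def _read_rows(path) -> list[list[str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        return [row for row in csv.reader(fh)]


# ---------------------------------------------------------------------------
# streams
# ---------------------------------------------------------------------------


def read_stream_csv(data_path, marker_path, sampling_frequency: float) -> RawStream:
    """Read a continuous recording from a sample table plus a marker file."""
    rows = _read_rows(data_path)
    if not rows:
        raise FormatError(f"{data_path}: empty file, missing header, line 1")
    header = rows[0]
    n_cols = len(header)
    data = np.empty((len(rows) - 1, n_cols), dtype=float)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != n_cols:
            raise FormatError(
                f"{data_path}: ragged row ({len(row)} cells, expected {n_cols}), line {i}"
            )
        for j, cell in enumerate(row):
            data[i - 2, j] = _parse_float(cell, data_path, i)

    markers = []
    mrows = _read_rows(marker_path)
    if not mrows or [c.strip() for c in mrows[0][:2]] != ["sample_index", "name"]:
        raise FormatError(f"{marker_path}: expected header 'sample_index,name', line 1")
    for i, row in enumerate(mrows[1:], start=2):
        if len(row) != 2:
            raise FormatError(f"{marker_path}: ragged marker row, line {i}")
        try:
            idx = int(row[0])
        except ValueError:
            raise FormatError(f"{marker_path}: non-integer sample index, line {i}") from None
        if not 0 <= idx < data.shape[0]:
            raise FormatError(f"{marker_path}: marker out of range, line {i}")
        markers.append(Marker(idx, row[1]))

    return RawStream(
        samples=data,
        channel_names=tuple(header),
        sampling_frequency=sampling_frequency,
        markers=tuple(markers),
    )


def write_stream_csv(stream: RawStream, data_path, marker_path) -> None:
    with open(data_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(stream.channel_names)
        for row in stream.samples:
            writer.writerow([_fmt(x) for x in row])
    with open(marker_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_index", "name"])
        for m in stream.markers:
            writer.writerow([m.sample_index, m.name])


# ---------------------------------------------------------------------------
# dataset directories
# ---------------------------------------------------------------------------


def _write_metadata(directory: Path, metadata: dict) -> None:
    with open(directory / METADATA_FILENAME, "w", encoding="utf-8") as fh:
        yaml.safe_dump(metadata, fh, sort_keys=False)


def _read_metadata(directory: Path) -> dict:
    path = directory / METADATA_FILENAME
    if not path.exists():
        raise FormatError(f"{directory}: missing {METADATA_FILENAME}")
    with open(path, encoding="utf-8") as fh:
        metadata = yaml.safe_load(fh)
    if not isinstance(metadata, dict) or "kind" not in metadata:
        raise FormatError(f"{path}: metadata must be a mapping with a 'kind' key")
    return metadata


def write_dataset(dataset: Dataset, directory) -> Path:
    """Write a dataset directory (``metadata.yaml`` + data files)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    metadata = dict(dataset.metadata)
    metadata["kind"] = dataset.kind
    metadata.setdefault("storage_format", "csv")

    if dataset.kind == "stream":
        if len(dataset.samples) != 1:
            raise ValueError("stream dataset must hold exactly one RawStream")
        stream: RawStream = dataset.samples[0]
        metadata["sampling_frequency"] = float(stream.sampling_frequency)
        metadata["channel_names"] = list(stream.channel_names)
        write_stream_csv(stream, directory / "data.csv", directory / "markers.csv")
    elif dataset.kind == "time_series":
        _write_time_series_csv(dataset, directory, metadata)
    elif dataset.kind == "feature_vector":
        if metadata.get("storage_format") == "arff":
            names = _feature_names(dataset)
            metadata["feature_names"] = list(names)
            write_arff(dataset, directory / "data.arff", relation=directory.name)
        else:
            _write_feature_csv(dataset, directory, metadata)
    elif dataset.kind == "prediction":
        _write_prediction_csv(dataset, directory, metadata)
    else:  # pragma: no cover - guarded by Dataset
        raise ValueError(f"unsupported dataset kind {dataset.kind!r}")

    _write_metadata(directory, metadata)
    return directory


def _feature_names(dataset: Dataset) -> tuple[str, ...]:
    if not dataset.samples:
        names = dataset.metadata.get("feature_names")
        return tuple(names) if names else ()
    return dataset.samples[0].feature_names


def _write_time_series_csv(dataset: Dataset, directory: Path, metadata: dict) -> None:
    windows: Sequence[TimeSeriesWindow] = dataset.samples
    if windows:
        channels = windows[0].channel_names
        fs = windows[0].sampling_frequency
        for w in windows:
            if w.channel_names != channels:
                raise ValueError("all windows must share channel names")
            if w.sampling_frequency != fs:
                raise ValueError("all windows must share the sampling frequency")
        metadata["channel_names"] = list(channels)
        metadata["sampling_frequency"] = float(fs)
        metadata["window_info"] = [
            {"start_time_ms": float(w.start_time_ms), "tag": w.tag} for w in windows
        ]
    else:
        channels = tuple(metadata.get("channel_names") or ())
    with open(directory / "data.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["window_id", "label", "time_index", *channels])
        for wid, w in enumerate(windows):
            label = "" if w.label is None else w.label
            for t, row in enumerate(w.values):
                writer.writerow([wid, label, t, *[_fmt(x) for x in row]])


def _write_feature_csv(dataset: Dataset, directory: Path, metadata: dict) -> None:
    names = _feature_names(dataset)
    for fv in dataset.samples:
        if fv.feature_names != names:
            raise ValueError("all feature vectors must share feature names")
    metadata["feature_names"] = list(names)
    with open(directory / "data.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([*names, "label"])
        for fv in dataset.samples:
            label = "" if fv.label is None else fv.label
            writer.writerow([*[_fmt(x) for x in fv.values], label])


def _write_prediction_csv(dataset: Dataset, directory: Path, metadata: dict) -> None:
    with open(directory / "data.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["score", "assigned_label", "true_label", "classifier"])
        for p in dataset.samples:
            writer.writerow(
                [
                    _fmt(p.score),
                    p.assigned_label,
                    "" if p.true_label is None else p.true_label,
                    p.classifier_name,
                ]
            )


def read_dataset(directory) -> Dataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    directory = Path(directory)
    metadata = _read_metadata(directory)
    kind = metadata["kind"]

    if kind == "stream":
        stream = read_stream_csv(
            directory / "data.csv",
            directory / "markers.csv",
            float(metadata["sampling_frequency"]),
        )
        declared = metadata.get("channel_names")
        if declared is not None and tuple(declared) != stream.channel_names:
            raise FormatError(f"{directory}: metadata channel names disagree with data.csv")
        return Dataset(kind="stream", samples=[stream], metadata=metadata)
    if kind == "time_series":
        return _read_time_series_csv(directory, metadata)
    if kind == "feature_vector":
        if metadata.get("storage_format") == "arff":
            dataset = read_arff(directory / "data.arff")
            dataset.metadata.update(metadata)
            return dataset
        return _read_feature_csv(directory, metadata)
    if kind == "prediction":
        return _read_prediction_csv(directory, metadata)
    raise FormatError(f"{directory}: unknown dataset kind {kind!r}")


def _read_time_series_csv(directory: Path, metadata: dict) -> Dataset:
    path = directory / "data.csv"
    rows = _read_rows(path)
    if not rows:
        raise FormatError(f"{path}: empty file, line 1")
    header = rows[0]
    if header[:3] != ["window_id", "label", "time_index"]:
        raise FormatError(f"{path}: expected columns window_id,label,time_index, line 1")
    channels = tuple(header[3:])
    declared = metadata.get("channel_names")
    if declared is not None and tuple(declared) != channels:
        raise FormatError(f"{path}: metadata channel names disagree with header")
    fs = float(metadata["sampling_frequency"])
    window_info = metadata.get("window_info") or []

    groups: dict[int, dict] = {}
    order: list[int] = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise FormatError(f"{path}: ragged row, line {i}")
        wid = int(row[0])
        label = row[1] or None
        values = [_parse_float(c, path, i) for c in row[3:]]
        if wid not in groups:
            groups[wid] = {"label": label, "rows": []}
            order.append(wid)
        groups[wid]["rows"].append(values)

    windows = []
    for pos, wid in enumerate(order):
        info = window_info[pos] if pos < len(window_info) else {}
        windows.append(
            TimeSeriesWindow(
                values=np.asarray(groups[wid]["rows"], dtype=float),
                channel_names=channels,
                sampling_frequency=fs,
                start_time_ms=float(info.get("start_time_ms", 0.0)),
                label=groups[wid]["label"],
                tag=str(info.get("tag", "")),
            )
        )
    return Dataset(kind="time_series", samples=windows, metadata=metadata)


def _read_feature_csv(directory: Path, metadata: dict) -> Dataset:
    path = directory / "data.csv"
    rows = _read_rows(path)
    if not rows:
        raise FormatError(f"{path}: empty file, line 1")
    header = rows[0]
    if not header or header[-1] != "label":
        raise FormatError(f"{path}: last column must be 'label', line 1")
    names = tuple(header[:-1])
    declared = metadata.get("feature_names")
    if declared is not None and tuple(declared) != names:
        raise FormatError(f"{path}: metadata feature names disagree with header")
    samples = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise FormatError(f"{path}: ragged row, line {i}")
        values = [_parse_float(c, path, i) for c in row[:-1]]
        samples.append(FeatureVector(np.asarray(values), names, label=row[-1] or None))
    return Dataset(kind="feature_vector", samples=samples, metadata=metadata)


def _read_prediction_csv(directory: Path, metadata: dict) -> Dataset:
    path = directory / "data.csv"
    rows = _read_rows(path)
    if not rows or rows[0] != ["score", "assigned_label", "true_label", "classifier"]:
        raise FormatError(f"{path}: bad prediction header, line 1")
    samples = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != 4:
            raise FormatError(f"{path}: ragged row, line {i}")
        samples.append(
            PredictionVector(
                score=_parse_float(row[0], path, i),
                assigned_label=row[1],
                true_label=row[2] or None,
                classifier_name=row[3],
            )
        )
    return Dataset(kind="prediction", samples=samples, metadata=metadata)


# ---------------------------------------------------------------------------
# ARFF
# ---------------------------------------------------------------------------


def write_arff(dataset: Dataset, path, relation: Optional[str] = None) -> None:
    """Write a feature-vector dataset as ARFF.

    One numeric attribute per feature; the nominal ``class`` attribute is
    last.  Labels must come from a finite class set (every sample labeled).
    """
    if dataset.kind != "feature_vector":
        raise ValueError("ARFF storage supports feature_vector datasets only")
    names = _feature_names(dataset)
    labels = []
    for fv in dataset.samples:
        if fv.label is None:
            raise ValueError("ARFF requires every sample to carry a class label")
        labels.append(fv.label)
    classes = sorted(set(labels)) or list(dataset.metadata.get("classes", []))
    if relation is None:
        relation = str(dataset.metadata.get("relation", "sigflow"))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"@RELATION {relation}\n\n")
        for name in names:
            fh.write(f"@ATTRIBUTE {name} NUMERIC\n")
        fh.write("@ATTRIBUTE class {" + ",".join(classes) + "}\n\n")
        fh.write("@DATA\n")
        for fv in dataset.samples:
            fh.write(",".join([_fmt(x) for x in fv.values] + [fv.label]) + "\n")


def read_arff(path) -> Dataset:
    """Read an ARFF file holding numeric features and a nominal class."""
    names: list[str] = []
    classes: list[str] = []
    samples: list[FeatureVector] = []
    relation = ""
    in_data = False
    saw_class = False
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            lower = line.lower()
            if not in_data:
                if lower.startswith("@relation"):
                    relation = line.split(None, 1)[1] if " " in line else ""
                elif lower.startswith("@attribute"):
                    parts = line.split(None, 2)
                    if len(parts) < 3:
                        raise FormatError(f"{path}: malformed attribute, line {line_no}")
                    _, name, spec = parts
                    if spec.strip().startswith("{"):
                        if saw_class:
                            raise FormatError(
                                f"{path}: multiple nominal attributes, line {line_no}"
                            )
                        saw_class = True
                        classes = [c.strip() for c in spec.strip().strip("{}").split(",") if c.strip()]
                    else:
                        if spec.strip().lower() not in ("numeric", "real", "integer"):
                            raise FormatError(
                                f"{path}: non-numeric feature attribute {name!r}, line {line_no}"
                            )
                        if saw_class:
                            raise FormatError(
                                f"{path}: class attribute must be last, line {line_no}"
                            )
                        if name in names:
                            raise FormatError(
                                f"{path}: duplicate attribute name {name!r}, line {line_no}"
                            )
                        names.append(name)
                elif lower.startswith("@data"):
                    if not saw_class:
                        raise FormatError(f"{path}: missing nominal class attribute")
                    in_data = True
                continue
            cells = [c.strip() for c in line.split(",")]
            if len(cells) != len(names) + 1:
                raise FormatError(f"{path}: ragged data row, line {line_no}")
            values = [_parse_float(c, path, line_no) for c in cells[:-1]]
            label = cells[-1]
            if label not in classes:
                raise FormatError(f"{path}: unknown class {label!r}, line {line_no}")
            samples.append(FeatureVector(np.asarray(values), tuple(names), label=label))
    if not in_data:
        raise FormatError(f"{path}: missing @DATA section")
    return Dataset(
        kind="feature_vector",
        samples=samples,
        metadata={
            "kind": "feature_vector",
            "storage_format": "arff",
            "feature_names": list(names),
            "classes": classes,
            "relation": relation,
            "history": [],
        },
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def read_summary(root) -> Summary:
    """Load every dataset sub-directory (one level deep) under ``root``."""
    root = Path(root)
    if not root.is_dir():
        raise FormatError(f"summary directory {root} does not exist")
    datasets = {}
    for entry in sorted(os.listdir(root)):
        sub = root / entry
        if sub.is_dir() and (sub / METADATA_FILENAME).exists():
            datasets[entry] = read_dataset(sub)
    return Summary(root_path=str(root), datasets=datasets)


def write_summary(summary: Summary, root) -> Path:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for name, dataset in summary.datasets.items():
        write_dataset(dataset, root / name)
    return root
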