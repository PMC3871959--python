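"""Binary classification metrics and consolidated result tables."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import pandas as pd

from .data_model import PredictionVector

__all__ = [
    "MetricsRecord",
    "METRIC_NAMES",
    "compute_metrics",
    "aggregate_results",
    "query_results",
    "results_to_csv",
    "read_results_csv",
]

METRIC_NAMES = ("accuracy", "balanced_accuracy", "precision", "recall", "f_measure")
COUNT_NAMES = ("TP", "FP", "TN", "FN")


@dataclass(frozen=True)
class MetricsRecord:
    """Confusion counts and derived rates for one evaluation phase.

    Zero denominators yield 0 by convention so that result tables remain
    purely numeric.
    """

    TP: int
    FP: int
    TN: int
    FN: int
    accuracy: float
    balanced_accuracy: float
    precision: float
    recall: float
    f_measure: float
    n_samples: int
    phase: str = "test"

    def as_dict(self) -> dict:
        return asdict(self)


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def compute_metrics(
    predictions: Sequence[PredictionVector],
    positive_class: str,
    phase: str = "test",
) -> MetricsRecord:
    """Confusion counts of ``predictions`` against ``positive_class``."""
    if not predictions:
        raise ValueError("cannot compute metrics on an empty prediction set")
    tp = fp = tn = fn = 0
    for p in predictions:
        if p.true_label is None:
            raise ValueError("every prediction needs a true_label for evaluation")
        predicted_pos = p.assigned_label == positive_class
        actual_pos = p.true_label == positive_class
        if predicted_pos and actual_pos:
            tp += 1
        elif predicted_pos and not actual_pos:
            fp += 1
        elif not predicted_pos and actual_pos:
            fn += 1
        else:
            tn += 1
    n = len(predictions)
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    return MetricsRecord(
        TP=tp,
        FP=fp,
        TN=tn,
        FN=fn,
        accuracy=_safe_div(tp + tn, n),
        balanced_accuracy=(recall + specificity) / 2.0,
        precision=precision,
        recall=recall,
        f_measure=_safe_div(2.0 * precision * recall, precision + recall),
        n_samples=n,
        phase=phase,
    )


def _metric_columns(prefix: str) -> list[str]:
    return [f"{prefix}_{name}" for name in COUNT_NAMES + METRIC_NAMES + ("n_samples",)]


def aggregate_results(rows: Sequence[dict]) -> pd.DataFrame:
    """Combine per-process result rows into one sorted table.

    Each row dict must carry ``Dataset``, ``Run``, the varied parameter
    columns, and ``train``/``test`` :class:`MetricsRecord` objects under
    the keys ``train_metrics`` / ``test_metrics`` (either may be None).
    """
    if not rows:
        return pd.DataFrame(columns=["Dataset", "Run"])
    param_cols: list[str] = []
    for row in rows:
        for key in row:
            if key in ("Dataset", "Run", "train_metrics", "test_metrics"):
                continue
            if key not in param_cols:
                param_cols.append(key)
    records = []
    for row in rows:
        rec = {"Dataset": row["Dataset"], "Run": row["Run"]}
        for col in param_cols:
            rec[col] = row.get(col)
        for phase in ("Train", "Test"):
            metrics: Optional[MetricsRecord] = row.get(f"{phase.lower()}_metrics")
            for col in _metric_columns(phase):
                name = col[len(phase) + 1 :]
                rec[col] = getattr(metrics, name) if metrics is not None else 0
        records.append(rec)
    table = pd.DataFrame.from_records(records)
    sort_cols = ["Dataset", *param_cols, "Run"]
    table = table.sort_values(sort_cols, kind="stable").reset_index(drop=True)
    return table


def results_to_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.17g")


def read_results_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def query_results(
    table: pd.DataFrame,
    filters: Optional[dict] = None,
    group_by: Optional[Sequence[str]] = None,
    metric: str = "Test_balanced_accuracy",
) -> pd.DataFrame:
    """Mean ``metric`` per group after filtering rows by exact match."""
    for col in list((filters or {}).keys()) + list(group_by or []):
        if col not in table.columns:
            raise KeyError(f"unknown column {col!r}")
    if metric not in table.columns:
        raise KeyError(f"unknown metric column {metric!r}")
    view = table
    for col, value in (filters or {}).items():
        view = view[view[col] == value]
    if not group_by:
        return view.reset_index(drop=True)
    if view.empty:
        return pd.DataFrame(columns=[*group_by, metric])
    grouped = view.groupby(list(group_by), sort=True)[metric].mean().reset_index()
    return grouped
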