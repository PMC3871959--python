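"""Execution back-ends: serial and local multicore.

Both back-ends satisfy the same contract: every process descriptor is
executed exactly once, per-process exceptions are captured in the
outcome instead of propagating, and the outcome list order matches the
input order regardless of completion order — so results are identical
across back-ends.
"""

from __future__ import annotations

import os
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

__all__ = ["Backend", "SerialBackend", "MulticoreBackend", "get_backend", "execute_processes"]


@dataclass(frozen=True)
class Backend:
    name: str
    worker_count: int = 1

    def __post_init__(self) -> None:
        if self.worker_count < 1:
            raise ValueError("worker_count must be >= 1")


def SerialBackend() -> Backend:
    return Backend(name="serial", worker_count=1)


def MulticoreBackend(worker_count: Optional[int] = None) -> Backend:
    if worker_count is None:
        worker_count = os.cpu_count() or 1
    return Backend(name="mcore", worker_count=worker_count)


def get_backend(name: str, worker_count: Optional[int] = None) -> Backend:
    if name == "serial":
        return SerialBackend()
    if name == "mcore":
        return MulticoreBackend(worker_count)
    raise ValueError(f"unknown backend {name!r}; choose 'serial' or 'mcore'")


def execute_processes(
    processes: Sequence, runner: Callable, backend: Backend
) -> list:
    """Run ``runner`` over all process descriptors via the chosen back-end.

    ``runner`` must be a picklable top-level callable returning a
    per-process outcome and must itself capture per-process errors (the
    independence contract: one failing process never aborts siblings).
    """
    processes = list(processes)
    if not processes:
        return []
    if backend.name == "serial" or backend.worker_count == 1 or len(processes) == 1:
        return [runner(p) for p in processes]
    with ProcessPoolExecutor(max_workers=backend.worker_count) as pool:
        return list(pool.map(runner, processes))
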