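"""Degeneracy-weighted worst-fit job partitioning and local execution.

Screening every expansion of every candidate probe dominates the cost of a
design, and a probe's cost is proportional to its degeneracy, so the probes
are distributed over N jobs by weight: sort descending by weight, then
worst-fit — each probe goes to the job with the most remaining room
relative to the mean load per job, i.e. the currently lightest job (ties:
lowest job index).  The resulting jobs have almost the same total weight:
max load - min load never exceeds the largest single weight.

Jobs run on a local worker pool with bounded retries; results are merged
into a single canonically ordered list, so the merged output is identical
whatever N or the execution order — parallelization never changes the
science.
"""

from __future__ import annotations

import logging
import math
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from heapq import heappop, heappush
from typing import Callable, Literal, Sequence, TypeVar

from .consensus_design import DegenerateProbe

logger = logging.getLogger(__name__)

__all__ = [
    "JobPartition",
    "LoadStats",
    "JobRecord",
    "JobFailure",
    "worst_fit_partition",
    "load_stats",
    "run_jobs_local",
]

T = TypeVar("T")


@dataclass
class JobPartition:
    """Assignment of probes to N jobs with per-job loads."""

    jobs: list[list[DegenerateProbe]]
    loads: list[float]
    mean_load: float


@dataclass(frozen=True)
class LoadStats:
    mean: float
    sample_std: float


@dataclass
class JobRecord:
    """Lifecycle of one job in the local executor."""

    job_id: int
    state: Literal["pending", "submitted", "failed", "done"] = "pending"
    attempts: int = 0
    error: str | None = None


class JobFailure(RuntimeError):
    """A job exhausted its retries; carries the partial-results manifest."""

    def __init__(self, records: list[JobRecord]):
        self.records = records
        failed = [r.job_id for r in records if r.state == "failed"]
        super().__init__(f"jobs failed after retries: {failed}")


def worst_fit_partition(
    probes: Sequence[DegenerateProbe], n_jobs: int
) -> JobPartition:
    """Distribute probes over ``n_jobs`` jobs of almost equal total weight.

    Probes are placed in descending weight order (ties: input order) into
    the currently lightest job (ties: lowest job index) — worst-fit with
    all bins sized to the mean load.  Deterministic.
    """
    if n_jobs < 1:
        raise ValueError("n_jobs must be >= 1")
    order = sorted(range(len(probes)), key=lambda i: (-probes[i].weight, i))
    jobs: list[list[DegenerateProbe]] = [[] for _ in range(n_jobs)]
    loads = [0.0] * n_jobs
    heap: list[tuple[float, int]] = [(0.0, j) for j in range(n_jobs)]
    for i in order:
        load, j = heappop(heap)
        jobs[j].append(probes[i])
        load += probes[i].weight
        loads[j] = load
        heappush(heap, (load, j))
    total = sum(loads)
    return JobPartition(jobs=jobs, loads=loads, mean_load=total / n_jobs)


def load_stats(loads: Sequence[float]) -> LoadStats:
    """Mean and sample standard deviation (n-1 denominator) of job loads.

    A single load has standard deviation 0 by convention.
    """
    if len(loads) == 0:
        raise ValueError("no loads")
    n = len(loads)
    mean = sum(loads) / n
    if n == 1:
        return LoadStats(mean=mean, sample_std=0.0)
    var = sum((x - mean) ** 2 for x in loads) / (n - 1)
    return LoadStats(mean=mean, sample_std=math.sqrt(var))


def run_jobs_local(
    partition: JobPartition,
    worker: Callable[[int, list[DegenerateProbe], int], list[T]],
    max_retries: int = 2,
    max_workers: int = 1,
    merge_key: Callable[[T], tuple] | None = None,
) -> tuple[list[T], list[JobRecord]]:
    """Run each job's worker locally with retry, then merge results.

    ``worker(job_id, probes, attempt)`` must be a pure function of the
    job's probe list (``attempt`` starts at 0 and only supports
    fault-injection testing and logging).  A failing job is retried up to
    ``max_retries`` times; if any job still fails, :class:`JobFailure` is
    raised carrying the manifest.  Results of all jobs are concatenated and
    sorted by ``merge_key`` (default: taxon then probe start then sequence),
    which makes the merged output independent of N and scheduling.
    """
    records = [JobRecord(job_id=j) for j in range(len(partition.jobs))]
    results: dict[int, list[T]] = {}

    def submit_round(pending: list[int], pool: ProcessPoolExecutor | None):
        futures = {}
        for j in pending:
            records[j].state = "submitted"
            records[j].attempts += 1
            attempt = records[j].attempts - 1
            if pool is None:
                try:
                    results[j] = worker(j, partition.jobs[j], attempt)
                    records[j].state = "done"
                except Exception as exc:  # noqa: BLE001 - worker is user code
                    records[j].state = "failed"
                    records[j].error = repr(exc)
                    logger.warning("job %d attempt %d failed: %r", j, attempt, exc)
            else:
                futures[pool.submit(worker, j, partition.jobs[j], attempt)] = j
        for fut, j in futures.items():
            try:
                results[j] = fut.result()
                records[j].state = "done"
            except Exception as exc:  # noqa: BLE001
                records[j].state = "failed"
                records[j].error = repr(exc)
                logger.warning("job %d failed: %r", j, exc)

    pending = list(range(len(partition.jobs)))
    pool = ProcessPoolExecutor(max_workers=max_workers) if max_workers > 1 else None
    try:
        for _round in range(max_retries + 1):
            if not pending:
                break
            submit_round(pending, pool)
            pending = [j for j in pending if records[j].state == "failed"]
    finally:
        if pool is not None:
            pool.shutdown()
    if pending:
        raise JobFailure(records)

    merged: list[T] = [r for j in range(len(partition.jobs)) for r in results[j]]
    if merge_key is None:
        def merge_key(item):  # type: ignore[misc]
            probe = getattr(item, "probe", item)
            return (probe.taxon, probe.start, probe.sequence)
    merged.sort(key=merge_key)
    return merged, records
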