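"""Map stage: task records, submission validation, cost and worker stats.

Each B-scan becomes one paid micro-task (HIT) duplicated across independent
workers.  Submissions are gated on the interface rules: a required line
count and a minimum mean drawing time per line.  Cost is exact integer-cent
arithmetic over every collected assignment, rejected or not.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .synth_retina import BScanImage, SegmentationSet

__all__ = [
    "TaskRecord",
    "AssignmentResult",
    "CostReport",
    "create_tasks",
    "validate_submission",
    "cost_summary",
    "project_cost",
    "worker_stats",
]

STATUSES = ("accepted", "rejected_lines", "rejected_timing", "rejected_crossing")


def _to_cents(usd: float) -> int:
    cents = round(usd * 100)
    if abs(cents - usd * 100) > 1e-6:
        raise ValueError(f"reward {usd!r} is not a whole number of cents")
    return int(cents)


@dataclass(frozen=True)
class TaskRecord:
    """One unit of crowd work: segment one B-scan."""

    task_id: str
    image_ref: int  # slice index
    reward_usd: float = 0.01
    assignments_requested: int = 2
    min_approval_rate: float = 0.80
    required_lines: int = 5
    min_mean_line_seconds: float = 15.0

    def __post_init__(self) -> None:
        if self.reward_usd < 0:
            raise ValueError("reward_usd must be >= 0")
        if self.assignments_requested < 1:
            raise ValueError("assignments_requested must be >= 1")
        if self.required_lines < 1:
            raise ValueError("required_lines must be >= 1")
        _to_cents(self.reward_usd)  # validate exact cents


@dataclass(frozen=True)
class AssignmentResult:
    """One collected submission for a task."""

    task_id: str
    worker_id: str
    segset: SegmentationSet
    per_line_seconds: tuple[float, ...]
    submitted_at: float  # seconds on the simulated clock
    status: str = "accepted"

    def __post_init__(self) -> None:
        if len(self.per_line_seconds) != self.segset.n_lines:
            raise ValueError("per_line_seconds must have one entry per trace")
        if any(t < 0 for t in self.per_line_seconds):
            raise ValueError("per-line times must be nonnegative")
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


@dataclass(frozen=True)
class CostReport:
    n_tasks: int
    n_assignments: int
    reward_usd: float
    total_cents: int

    @property
    def total_usd(self) -> float:
        return self.total_cents / 100.0


def create_tasks(
    volume: Sequence[BScanImage],
    duplication: int = 2,
    reward_usd: float = 0.01,
) -> list[TaskRecord]:
    """One TaskRecord per slice, each requesting ``duplication`` assignments."""
    if len(volume) == 0:
        raise ValueError("cannot create tasks from an empty volume")
    if duplication < 1:
        raise ValueError("duplication must be >= 1")
    n = len(volume)
    pad = max(len(str(n - 1)), 3)
    return [
        TaskRecord(
            task_id=f"task-{img.slice_index:0{pad}d}",
            image_ref=img.slice_index,
            reward_usd=reward_usd,
            assignments_requested=duplication,
        )
        for img in volume
    ]


def validate_submission(
    assignment: AssignmentResult, task: TaskRecord
) -> AssignmentResult:
    """Apply the interface gates: line count, then mean per-line time.

    Crossing QC is applied separately, later.  Idempotent: an already
    rejected assignment keeps its status.
    """
    if assignment.task_id != task.task_id:
        raise ValueError(
            f"assignment {assignment.task_id!r} does not reference task "
            f"{task.task_id!r}")
    if assignment.status != "accepted":
        return assignment
    if assignment.segset.n_lines < task.required_lines:
        return replace(assignment, status="rejected_lines")
    if float(np.mean(assignment.per_line_seconds)) < task.min_mean_line_seconds:
        return replace(assignment, status="rejected_timing")
    return assignment


def cost_summary(
    tasks: Sequence[TaskRecord], assignments: Sequence[AssignmentResult]
) -> CostReport:
    """Total spend over all collected assignments (rejected ones included:
    workers were paid per HIT regardless of downstream QC)."""
    rewards = {t.task_id: _to_cents(t.reward_usd) for t in tasks}
    total = sum(rewards[a.task_id] for a in assignments)
    reward_usd = tasks[0].reward_usd if tasks else 0.0
    return CostReport(
        n_tasks=len(tasks),
        n_assignments=len(assignments),
        reward_usd=reward_usd,
        total_cents=total,
    )


def project_cost(
    n_subjects: int,
    slices_per_scan: int,
    duplication: int,
    reward_usd: float,
) -> float:
    """Projected campaign cost in dollars, exact to the cent."""
    for name, v in (("n_subjects", n_subjects),
                    ("slices_per_scan", slices_per_scan),
                    ("duplication", duplication)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    cents = n_subjects * slices_per_scan * duplication * _to_cents(reward_usd)
    return cents / 100.0


def worker_stats(assignments: Sequence[AssignmentResult]) -> dict:
    """Campaign-level worker statistics.

    Returns per-worker task counts, mean tasks per worker (1 decimal),
    mean lines per collected task (2 decimals), per-line and per-task time
    summaries, and — for workers with >= 4 tasks — the mean completion time
    by task ordinal (the learning-curve table).
    """
    if not assignments:
        return {
            "n_assignments": 0, "n_workers": 0, "tasks_per_worker": {},
            "mean_tasks_per_worker": None, "total_lines": 0,
            "mean_lines_per_task": None, "line_seconds": {},
            "task_minutes": {}, "learning_curve_minutes": [],
        }

    rows = pd.DataFrame({
        "worker": [a.worker_id for a in assignments],
        "submitted_at": [a.submitted_at for a in assignments],
        "n_lines": [a.segset.n_lines for a in assignments],
        "task_seconds": [float(sum(a.per_line_seconds)) for a in assignments],
    })
    per_worker = rows.groupby("worker").size()
    line_secs = np.concatenate(
        [np.asarray(a.per_line_seconds, dtype=float) for a in assignments])

    n_tasks = len(rows)
    total_lines = int(rows["n_lines"].sum())
    stats = {
        "n_assignments": n_tasks,
        "n_workers": int(per_worker.size),
        "tasks_per_worker": per_worker.to_dict(),
        "mean_tasks_per_worker": round(n_tasks / per_worker.size, 1),
        "total_lines": total_lines,
        "mean_lines_per_task": round(total_lines / n_tasks, 2),
        "line_seconds": {
            "mean": float(line_secs.mean()),
            "min": float(line_secs.min()),
            "max": float(line_secs.max()),
        },
        "task_minutes": {
            "mean": float(rows["task_seconds"].mean() / 60.0),
            "min": float(rows["task_seconds"].min() / 60.0),
            "max": float(rows["task_seconds"].max() / 60.0),
        },
    }

    # learning curve: workers with >= 4 tasks, task ordinal by submission time
    rows = rows.sort_values("submitted_at", kind="stable")
    rows["ordinal"] = rows.groupby("worker").cumcount()
    frequent = per_worker[per_worker >= 4].index
    sub = rows[rows["worker"].isin(frequent)]
    curve = (sub.groupby("ordinal")["task_seconds"].mean() / 60.0)
    stats["learning_curve_minutes"] = [float(v) for v in curve.tolist()]
    stats["n_frequent_workers"] = int(frequent.size)
    return stats
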