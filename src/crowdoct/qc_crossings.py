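"""Crossing quality control: no two lines of one submission may cross.

For every pair of resampled traces the dominant vertical order over the
shared column domain is established (majority sign of the per-column
difference); maximal intervals where the order inverts are reported as
crossings.  Exact touching without inversion is not a crossing.  Offending
submissions are rejected, not repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .synth_retina import SegmentationSet
from .task_map import AssignmentResult
from .trace_refine import BoundaryTrace

__all__ = ["CrossingReport", "detect_crossings", "apply_qc"]


@dataclass(frozen=True)
class CrossingReport:
    """Intervals of inverted vertical order for each offending line pair."""

    pairs: tuple[tuple[int, int, int, int], ...]  # (i, j, x_start, x_end)
    has_crossing: bool
    skipped_pairs: tuple[tuple[int, int], ...] = ()  # empty shared domain


def _dominant_sign(diff: np.ndarray) -> int:
    """Majority vertical order of a per-column difference array."""
    s = np.sign(diff)
    vote = s.sum()
    if vote != 0:
        return 1 if vote > 0 else -1
    total = diff.sum()
    if total != 0:
        return 1 if total > 0 else -1
    return 1


def _inversion_intervals(xs: np.ndarray, diff: np.ndarray) -> list[tuple[int, int]]:
    """Maximal column intervals where sign(diff) opposes the dominant sign."""
    dom = _dominant_sign(diff)
    bad = np.sign(diff) == -dom
    if not bad.any():
        return []
    intervals = []
    i = 0
    n = bad.size
    while i < n:
        if bad[i]:
            j = i
            while j + 1 < n and bad[j + 1]:
                j += 1
            intervals.append((int(xs[i]), int(xs[j])))
            i = j + 1
        else:
            i += 1
    return intervals


def detect_crossings(
    segset: SegmentationSet | Sequence[BoundaryTrace],
) -> CrossingReport:
    """Find all pairwise order inversions among a submission's traces.

    Traces are resampled to per-column form if needed.  A pair with empty
    shared domain is skipped and recorded.
    """
    traces = segset.traces if isinstance(segset, SegmentationSet) else segset
    traces = [t.resampled() for t in traces]
    pairs: list[tuple[int, int, int, int]] = []
    skipped: list[tuple[int, int]] = []
    for i in range(len(traces)):
        for j in range(i + 1, len(traces)):
            ti, tj = traces[i], traces[j]
            lo = max(ti.x[0], tj.x[0])
            hi = min(ti.x[-1], tj.x[-1])
            if hi < lo:
                skipped.append((i, j))
                continue
            yi = ti.y[lo - ti.x[0]: hi - ti.x[0] + 1]
            yj = tj.y[lo - tj.x[0]: hi - tj.x[0] + 1]
            xs = np.arange(lo, hi + 1)
            for x0, x1 in _inversion_intervals(xs, yi - yj):
                pairs.append((i, j, x0, x1))
    return CrossingReport(
        pairs=tuple(pairs),
        has_crossing=bool(pairs),
        skipped_pairs=tuple(skipped),
    )


def apply_qc(assignment: AssignmentResult) -> AssignmentResult:
    """Reject an assignment whose traces cross; otherwise pass it through.

    Only currently accepted assignments are examined; earlier rejections
    are preserved.
    """
    if assignment.status != "accepted":
        return assignment
    report = detect_crossings(assignment.segset)
    if report.has_crossing:
        return replace(assignment, status="rejected_crossing")
    return assignment
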