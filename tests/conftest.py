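import numpy as np
import pytest

from crowdoct.synth_retina import (BScanImage, GroundTruthBoundaries,
                                   PhantomConfig, RaterModel, SegmentationSet)
from crowdoct.task_map import AssignmentResult
from crowdoct.trace_refine import BoundaryTrace


@pytest.fixture
def small_phantom() -> PhantomConfig:
    """A fast, small phantom with all deformations active."""
    return PhantomConfig(
        width=96, height=200, n_slices=3,
        base_depths=(60.0, 85.0, 110.0, 135.0, 160.0),
        pit_depth=15.0, pit_width=15.0,
        ped_amplitude=8.0, ped_center=70.0, ped_width=10.0,
        dropout_prob=0.0, interslice_drift_sd=1.0,
    )


@pytest.fixture
def clean_phantom(small_phantom) -> PhantomConfig:
    """Noise-free variant: no speckle, no blur, no dropout."""
    from dataclasses import replace
    return replace(small_phantom, speckle_shape=np.inf, blur_sigma=0.0,
                   dropout_prob=0.0)


@pytest.fixture
def flat_truth() -> GroundTruthBoundaries:
    """Five flat boundaries, 256 columns wide."""
    curves = np.repeat(
        np.array([50.0, 90.0, 130.0, 170.0, 210.0])[:, None], 256, axis=1)
    return GroundTruthBoundaries(slice_index=0, curves=curves)


def make_trace(y_values, x0=0):
    """Per-column BoundaryTrace from an array of y values."""
    y = np.asarray(y_values, dtype=float)
    x = np.arange(x0, x0 + y.size)
    verts = np.column_stack([x.astype(float), y])
    return BoundaryTrace(vertices=verts, x=x, y=y)


def make_assignment(task_id="task-000", worker_id="w0", n_lines=5,
                    line_seconds=None, submitted_at=0.0, status="accepted",
                    slice_index=0, width=16):
    """A minimal AssignmentResult for accounting-level tests."""
    if line_seconds is None:
        line_seconds = tuple(20.0 for _ in range(n_lines))
    traces = tuple(
        make_trace(np.full(width, 10.0 + 20.0 * k)) for k in range(n_lines))
    segset = SegmentationSet(worker_id=worker_id, slice_index=slice_index,
                             traces=traces, line_seconds=tuple(line_seconds))
    return AssignmentResult(
        task_id=task_id, worker_id=worker_id, segset=segset,
        per_line_seconds=tuple(line_seconds), submitted_at=submitted_at,
        status=status)


@pytest.fixture
def assignment_factory():
    return make_assignment
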