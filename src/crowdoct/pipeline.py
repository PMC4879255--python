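"""End-to-end orchestration: simulate -> map -> collect -> refine -> QC ->
reduce -> stats -> reconstruct, from one config and one seed.

The run is single-process and fully deterministic: every random stream is
derived from the master seed with fixed spawn keys, the submission clock is
simulated, and reports are canonical JSON, so identical config+seed gives
byte-identical output.

The drawing interface's timing gate is modelled at collection time: a
worker whose mean per-line time falls below the floor is held back until
the floor is met (times scaled up), mirroring an interface that refuses
early submission.  Offline-validated data can still be rejected for timing
via ``validate_submission``.  Assignments rejected by QC are resubmitted to
a fresh simulated worker (bounded retries); every collected assignment is
paid, rejected or not.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from . import io as coio
from .qc_crossings import apply_qc, detect_crossings
from .reduce_consensus import interrater_stats, reduce_task
from .synth_retina import (PhantomConfig, RaterModel, SegmentationSet,
                           simulate_rater, generate_volume, _rng)
from .task_map import (AssignmentResult, cost_summary, create_tasks,
                       validate_submission, worker_stats)
from .trace_refine import RefineConfig, snap_to_contrast
from .volume_reconstruct import Scales, export_model, stack_surfaces

__all__ = ["PipelineConfig", "default_rater_pool", "run_pipeline"]


def default_rater_pool(
    n_workers: int = 22,
    seed: int = 0,
    bias_sd_px: float = 1.0,
    **overrides,
) -> tuple[RaterModel, ...]:
    """A pool of simulated annotators with per-worker systematic biases.

    Defaults mirror an anonymous micro-task crowd: 22 workers, axial error
    SD 2 px with 15 px lateral correlation, ~22 s median per line with a
    5%/task practice effect, and a 15% chance per extra-line draw of a
    spurious duplicate line (two draws per task, so 5-7 lines).
    """
    rng = _rng(seed, 3)
    biases = rng.normal(0.0, bias_sd_px, size=n_workers)
    params = {"extra_line_prob": 0.15, "learning_rate": 0.05}
    params.update(overrides)
    return tuple(
        RaterModel(worker_id=f"worker-{k:02d}", bias_px=float(biases[k]),
                   **params)
        for k in range(n_workers)
    )


@dataclass(frozen=True)
class PipelineConfig:
    """One self-contained run description.  ``seed`` is mandatory: the
    pipeline refuses silent nondeterminism."""

    seed: int
    phantom: PhantomConfig = PhantomConfig()
    raters: tuple[RaterModel, ...] = ()
    duplication: int = 2
    reward_usd: float = 0.01
    refine: RefineConfig = RefineConfig()
    refine_enabled: bool = True
    scales: Scales = Scales()
    max_resubmits: int = 8
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not self.raters:
            object.__setattr__(
                self, "raters", default_rater_pool(seed=self.seed))

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs = {}
        if "phantom" in raw:
            kwargs["phantom"] = PhantomConfig(**raw["phantom"])
        if "raters" in raw:
            kwargs["raters"] = tuple(RaterModel(**r) for r in raw["raters"])
        if "refine" in raw:
            kwargs["refine"] = RefineConfig(**raw["refine"])
        if "scales" in raw:
            kwargs["scales"] = Scales(**raw["scales"])
        for key in ("seed", "duplication", "reward_usd", "refine_enabled",
                    "max_resubmits", "output_dir"):
            if key in raw:
                kwargs[key] = raw[key]
        if "seed" not in kwargs:
            raise ValueError("config must set an explicit seed")
        return cls(**kwargs)


def _gate_times(segset: SegmentationSet, floor: float) -> SegmentationSet:
    """Model the interface's minimum-time gate: the worker waits until the
    mean per-line time reaches the floor before submitting."""
    mean = float(np.mean(segset.line_seconds))
    if mean >= floor or mean == 0:
        return segset
    scale = 1.001 * floor / mean  # hold just past the gate
    return replace(segset, line_seconds=tuple(
        t * scale for t in segset.line_seconds))


def _refine_assignment(assignment, image, config):
    """Snap every trace of an accepted assignment to the image contrast,
    then revert any pair whose refinement introduced an order inversion."""
    raw = [t.resampled() for t in assignment.segset.traces]
    refined = [snap_to_contrast(image.pixels, t, config) for t in raw]
    report = detect_crossings(refined)
    if report.has_crossing:
        bad = {i for i, j, *_ in report.pairs} | {j for i, j, *_ in report.pairs}
        refined = [raw[k] if k in bad else refined[k]
                   for k in range(len(refined))]
    segset = replace(assignment.segset, traces=tuple(refined))
    return replace(assignment, segset=segset)


def _surface_rmse(model, truths, consensus_slices):
    """Per-boundary RMSE of the stacked consensus surfaces against the
    phantom ground truth (phantom runs only; truth is known)."""
    n_b = model.n_boundaries
    errs = [[] for _ in range(n_b)]
    slice_to_row = {c.image_ref: s for s, c in
                    enumerate(sorted(consensus_slices, key=lambda c: c.image_ref))}
    for c in consensus_slices:
        s = slice_to_row[c.image_ref]
        truth = truths[c.image_ref].curves
        for b in range(min(n_b, truth.shape[0])):
            row = model.surfaces_px[b, s]
            mask = ~np.isnan(row)
            if mask.any():
                errs[b].append(row[mask] - truth[b, mask])
    per_b = []
    for b in range(n_b):
        if errs[b]:
            e = np.concatenate(errs[b])
            per_b.append(float(np.sqrt(np.mean(e ** 2))))
        else:
            per_b.append(None)
    pooled = np.concatenate([np.concatenate(e) for e in errs if e])
    return per_b, float(np.sqrt(np.mean(pooled ** 2)))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full map/reduce run; returns the report dict.

    If ``config.output_dir`` is set, all artifacts (slice PNGs, truth CSV,
    manifest, traces, consensus, surface exports, report.json) are written
    beneath it.
    """
    seed = config.seed

    # --- simulate the volume ------------------------------------------------
    images, truths = generate_volume(config.phantom, seed)

    # --- map: tasks ---------------------------------------------------------
    tasks = create_tasks(images, config.duplication, config.reward_usd)

    # --- collect ------------------------------------------------------------
    order_rng = _rng(seed, 4)
    n_pool = len(config.raters)
    if n_pool < config.duplication:
        raise ValueError(
            f"rater pool of {n_pool} cannot satisfy duplication "
            f"{config.duplication}")
    worker_task_count: dict[str, int] = {}
    clock = 0.0
    collected: list[AssignmentResult] = []

    for task in tasks:
        perm = order_rng.permutation(n_pool)
        accepted_here = 0
        for attempt, widx in enumerate(perm):
            if accepted_here >= config.duplication:
                break
            if attempt >= config.duplication + config.max_resubmits:
                break
            model = config.raters[widx]
            t_idx = worker_task_count.get(model.worker_id, 0)
            sub_seed = int(_rng(seed, 5, task.image_ref, attempt)
                           .integers(2 ** 31))
            segset = simulate_rater(truths[task.image_ref], model, t_idx,
                                    sub_seed)
            segset = _gate_times(segset, task.min_mean_line_seconds)
            worker_task_count[model.worker_id] = t_idx + 1
            clock += float(sum(segset.line_seconds)) + 5.0
            a = AssignmentResult(
                task_id=task.task_id, worker_id=model.worker_id,
                segset=segset, per_line_seconds=segset.line_seconds,
                submitted_at=clock)
            a = validate_submission(a, task)
            a = apply_qc(a)
            collected.append(a)
            if a.status == "accepted":
                accepted_here += 1

    # --- refine -------------------------------------------------------------
    by_task: dict[str, list[AssignmentResult]] = {t.task_id: [] for t in tasks}
    for a in collected:
        if a.status != "accepted":
            continue
        if config.refine_enabled:
            img = images[a.segset.slice_index]
            a = _refine_assignment(a, img, config.refine)
        by_task[a.task_id].append(a)

    # --- reduce -------------------------------------------------------------
    consensus_slices = []
    paired_all = []
    unreduced = []
    for task in tasks:
        accepted = sorted(by_task[task.task_id], key=lambda a: a.submitted_at)
        if len(accepted) < 2:
            unreduced.append(task.task_id)
            continue
        # the first two submissions form the interrater pair; within the
        # pair, roles are ordered by worker id so the sign of the
        # Bland-Altman difference is consistent across tasks
        pair = sorted(accepted[:2], key=lambda a: a.worker_id)
        ordered = pair + accepted[2:]
        cons, paired = reduce_task(
            [a.segset for a in ordered],
            height=config.phantom.height, image_ref=task.image_ref)
        consensus_slices.append(cons)
        paired_all.extend(paired)

    agreement = None
    if paired_all:
        agreement = interrater_stats(
            paired_all, config.phantom.axial_um_per_px)

    # --- reconstruct --------------------------------------------------------
    model = None
    rmse_per_b: list | None = None
    rmse_all = None
    if consensus_slices:
        model = stack_surfaces(consensus_slices, config.scales,
                               width=config.phantom.width)
        rmse_per_b, rmse_all = _surface_rmse(model, truths, consensus_slices)

    # --- accounting ---------------------------------------------------------
    cost = cost_summary(tasks, collected)
    wstats = worker_stats(collected)
    status_counts = {s: 0 for s in
                     ("accepted", "rejected_lines", "rejected_timing",
                      "rejected_crossing")}
    for a in collected:
        status_counts[a.status] += 1

    report = {
        "schema_version": 1,
        "seed": seed,
        "config": {
            "n_slices": config.phantom.n_slices,
            "width": config.phantom.width,
            "height": config.phantom.height,
            "duplication": config.duplication,
            "reward_usd": config.reward_usd,
            "n_workers_in_pool": n_pool,
            "refine_enabled": config.refine_enabled,
            "axial_um_per_px": config.phantom.axial_um_per_px,
        },
        "counts": {
            "n_tasks": len(tasks),
            "n_assignments_collected": len(collected),
            "by_status": status_counts,
            "tasks_reduced": len(consensus_slices),
            "tasks_unreduced": len(unreduced),
            "unreduced_task_ids": unreduced,
        },
        "cost": {
            "n_assignments": cost.n_assignments,
            "reward_usd": cost.reward_usd,
            "total_usd": cost.total_usd,
        },
        "worker_stats": wstats,
        "agreement": None if agreement is None else {
            "pearson_r": agreement.pearson_r,
            "r_squared": agreement.r_squared,
            "p_value": agreement.p_value,
            "n_samples": agreement.n_samples,
            "bias_um": agreement.bias_um,
            "loa_um": list(agreement.loa_um),
        },
        "surface_rmse_px": {
            "per_boundary": rmse_per_b,
            "overall": rmse_all,
        },
        "artifacts": {},
    }

    # --- artifacts ----------------------------------------------------------
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        coio.write_volume_pngs(images, out / "volume")
        coio.write_truth_csv(truths, out / "truth.csv")
        coio.write_manifest_csv(tasks, out / "manifest.csv")
        coio.write_assignments(collected, out / "traces.csv",
                               out / "assignments.json")
        if consensus_slices:
            coio.write_consensus_csv(consensus_slices, out / "consensus.csv",
                                     config.phantom.axial_um_per_px)
            export_model(model, out / "model")
        report["artifacts"] = {
            "volume": str(out / "volume"),
            "truth": str(out / "truth.csv"),
            "manifest": str(out / "manifest.csv"),
            "traces": str(out / "traces.csv"),
            "consensus": str(out / "consensus.csv") if consensus_slices else None,
            "model": str(out / "model") if consensus_slices else None,
        }
        coio.canonical_json(report, out / "report.json")

    return report
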