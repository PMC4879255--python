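"""Readers and writers for the pipeline's on-disk formats.

Images: 8-bit grayscale PNG, one per slice, zero-padded index in the name.
Ground truth: CSV (slice, boundary, x, y_px).  Task manifest: CSV.  Traces:
CSV (task_id, worker_id, line_index, vertex_index, x_px, y_px) plus a JSON
sidecar with per-line seconds, submission clock, and status.  Consensus:
CSV (slice, boundary, x, y_px, y_um, n_contributors).  Reports: canonical
JSON (sorted keys) so identical runs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .reduce_consensus import ConsensusLine, ConsensusSegmentation
from .synth_retina import BScanImage, GroundTruthBoundaries, SegmentationSet
from .task_map import AssignmentResult, TaskRecord
from .trace_refine import BoundaryTrace

__all__ = [
    "write_volume_pngs", "read_volume_pngs",
    "write_truth_csv", "read_truth_csv",
    "write_manifest_csv", "read_manifest_csv",
    "write_assignments", "read_assignments",
    "write_consensus_csv", "read_consensus_csv",
    "canonical_json",
]


def canonical_json(obj, path: Path | None = None) -> str:
    text = json.dumps(obj, sort_keys=True, indent=2, allow_nan=False)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# volume

def write_volume_pngs(images: Sequence[BScanImage], out_dir: Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pad = max(len(str(len(images) - 1)), 3)
    paths = []
    for img in images:
        p = out_dir / f"slice_{img.slice_index:0{pad}d}.png"
        iio.imwrite(p, (np.clip(img.pixels, 0, 1) * 255).astype(np.uint8))
        paths.append(p)
    return paths


def read_volume_pngs(
    in_dir: Path, axial_um_per_px: float = 3.87,
    lateral_um_per_px: float = 11.3,
) -> list[BScanImage]:
    paths = sorted(Path(in_dir).glob("*.png"))
    if not paths:
        raise FileNotFoundError(f"no PNG slices found in {in_dir}")
    return [
        BScanImage(
            pixels=np.asarray(iio.imread(p), dtype=float) / 255.0,
            slice_index=i,
            axial_um_per_px=axial_um_per_px,
            lateral_um_per_px=lateral_um_per_px,
        )
        for i, p in enumerate(paths)
    ]


def write_truth_csv(truths: Sequence[GroundTruthBoundaries], path: Path) -> None:
    frames = []
    for t in truths:
        n_b, width = t.curves.shape
        b_idx, x_idx = np.meshgrid(np.arange(n_b), np.arange(width),
                                   indexing="ij")
        frames.append(pd.DataFrame({
            "slice": t.slice_index,
            "boundary": b_idx.ravel(),
            "x": x_idx.ravel(),
            "y_px": t.curves.ravel(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.17g")


def read_truth_csv(path: Path) -> list[GroundTruthBoundaries]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for s, grp in df.groupby("slice", sort=True):
        n_b = int(grp["boundary"].max()) + 1
        width = int(grp["x"].max()) + 1
        curves = np.full((n_b, width), np.nan)
        curves[grp["boundary"].to_numpy(), grp["x"].to_numpy()] = \
            grp["y_px"].to_numpy()
        out.append(GroundTruthBoundaries(slice_index=int(s), curves=curves))
    return out


# ---------------------------------------------------------------------------
# tasks and assignments

def write_manifest_csv(tasks: Sequence[TaskRecord], path: Path,
                       image_paths: dict[int, str] | None = None) -> None:
    pd.DataFrame([{
        "task_id": t.task_id,
        "image_path": (image_paths or {}).get(t.image_ref, str(t.image_ref)),
        "image_ref": t.image_ref,
        "reward_usd": t.reward_usd,
        "assignments_requested": t.assignments_requested,
        "min_approval_rate": t.min_approval_rate,
        "required_lines": t.required_lines,
        "min_mean_line_seconds": t.min_mean_line_seconds,
    } for t in tasks]).to_csv(path, index=False)


def read_manifest_csv(path: Path) -> list[TaskRecord]:
    df = pd.read_csv(path)
    return [
        TaskRecord(
            task_id=str(r.task_id), image_ref=int(r.image_ref),
            reward_usd=float(r.reward_usd),
            assignments_requested=int(r.assignments_requested),
            min_approval_rate=float(r.min_approval_rate),
            required_lines=int(r.required_lines),
            min_mean_line_seconds=float(r.min_mean_line_seconds),
        )
        for r in df.itertuples(index=False)
    ]


def write_assignments(
    assignments: Sequence[AssignmentResult], traces_csv: Path, sidecar_json: Path
) -> None:
    rows = []
    meta = {}
    for a in assignments:
        key = f"{a.task_id}/{a.worker_id}"
        meta[key] = {
            "task_id": a.task_id,
            "worker_id": a.worker_id,
            "slice_index": a.segset.slice_index,
            "per_line_seconds": list(a.per_line_seconds),
            "submitted_at": a.submitted_at,
            "status": a.status,
            "sources": [t.source for t in a.segset.traces],
        }
        for li, tr in enumerate(a.segset.traces):
            for vi, (x, y) in enumerate(np.asarray(tr.vertices)):
                rows.append((a.task_id, a.worker_id, li, vi, x, y))
    pd.DataFrame(rows, columns=[
        "task_id", "worker_id", "line_index", "vertex_index", "x_px", "y_px",
    ]).to_csv(traces_csv, index=False)
    canonical_json(meta, sidecar_json)


def read_assignments(traces_csv: Path, sidecar_json: Path) -> list[AssignmentResult]:
    df = pd.read_csv(traces_csv, float_precision="round_trip")
    meta = json.loads(Path(sidecar_json).read_text())
    out = []
    for key, m in sorted(meta.items()):
        grp = df[(df["task_id"] == m["task_id"])
                 & (df["worker_id"] == m["worker_id"])]
        traces = []
        for li, lines in grp.groupby("line_index", sort=True):
            lines = lines.sort_values("vertex_index")
            verts = np.column_stack([lines["x_px"], lines["y_px"]])
            src = m["sources"][int(li)] if "sources" in m else "raw"
            traces.append(BoundaryTrace(vertices=verts, source=src))
        segset = SegmentationSet(
            worker_id=m["worker_id"], slice_index=int(m["slice_index"]),
            traces=tuple(traces),
            line_seconds=tuple(m["per_line_seconds"]))
        out.append(AssignmentResult(
            task_id=m["task_id"], worker_id=m["worker_id"], segset=segset,
            per_line_seconds=tuple(m["per_line_seconds"]),
            submitted_at=float(m["submitted_at"]), status=m["status"]))
    return out


# ---------------------------------------------------------------------------
# consensus

def write_consensus_csv(
    consensus: Sequence[ConsensusSegmentation], path: Path,
    axial_um_per_px: float,
) -> None:
    frames = []
    for c in consensus:
        for b, ln in enumerate(c.lines):
            frames.append(pd.DataFrame({
                "slice": c.image_ref,
                "boundary": b,
                "x": ln.x,
                "y_px": ln.y_px,
                "y_um": ln.y_px * axial_um_per_px,
                "n_contributors": ln.n_contributors,
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.17g")


def read_consensus_csv(path: Path) -> list[ConsensusSegmentation]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for s, grp in df.groupby("slice", sort=True):
        lines = []
        for _, lg in grp.groupby("boundary", sort=True):
            lg = lg.sort_values("x")
            n = int(lg["n_contributors"].iloc[0])
            lines.append(ConsensusLine(
                x=lg["x"].to_numpy(dtype=int),
                y_px=lg["y_px"].to_numpy(dtype=float),
                contributors=tuple(f"rater{k}" for k in range(n))))
        out.append(ConsensusSegmentation(
            image_ref=int(s), lines=tuple(lines), n_raters=max(
                ln.n_contributors for ln in lines)))
    return out
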