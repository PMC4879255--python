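# crowdoct

Crowdsourced layer segmentation of macular SD-OCT volumes, reimplemented
as a fully offline, testable map/reduce pipeline.

Automated retinal-layer segmenters fail on exactly the scans that matter
clinically — pigment-epithelial detachments, subretinal fibrosis, poor
signal — while expert manual grading is too slow for trial-scale volumes.
A third option is to crowdsource the drawing: split a volume into
one-B-scan micro-tasks, pay untrained annotators a cent per image to trace
the layer boundaries, and recover accuracy in the *reduce* step — snap each
freehand line to the strongest nearby image edge, reject submissions whose
lines cross, match lines across duplicate annotations, and average them
into consensus boundaries.  `crowdoct` implements that whole campaign with
the crowd and the scanner replaced by simulation, so every stage can be
tested against known ground truth: a phantom generator produces 61-slice
macular volumes (foveal pit, PED dome, speckle, signal dropout) and a
stochastic rater model produces human-like annotations (correlated drawing
error, per-worker bias, 5–7 lines, lognormal timing with a practice
effect).

## The model

For a task duplicated across two workers, each drawn line is resampled to
one axial position per column, then refined by a dynamic programme that
maximises, over offsets within ±5 px of the drawing,

    Σ_x |∂I/∂y|(x, y_x)  −  λ Σ_x |y_{x+1} − y_x|

(the "consistently highest contrast" path: axial gradient subject to
lateral continuity), falling back to the original trace when no strict
improvement exists.  Lines are matched across workers by optimal assignment
on the cost `(1 − r) + 6·gap/height` (Pearson correlation of the
per-column positions plus a vertical-gap term at the scale of one retinal
band), averaged per column into consensus lines, and scored by a pooled
Pearson r / R² and a Bland-Altman analysis (bias ± 1.96 SD limits of
agreement, in microns) of per-line mean positions.  Consensus slices stack
into per-boundary 3D surfaces with thickness maps; campaign accounting
(integer-cent cost, tasks per worker, lines per task, learning curves) is
computed alongside.  Details and all parameter defaults are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
from crowdoct import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=1))
print(report["counts"]["n_assignments_collected"],
      report["cost"]["total_usd"])
print(report["worker_stats"]["mean_tasks_per_worker"],
      report["worker_stats"]["mean_lines_per_task"])
print(round(report["agreement"]["pearson_r"], 6),
      round(report["surface_rmse_px"]["overall"], 3))
```

prints

```
122 1.22
5.5 5.29
0.999988 0.501
```

Reading: the default campaign (61 slices × 2 assignments at $0.01) collected
122 annotations for $1.22 from a 22-worker pool (5.5 tasks each, 5.29 lines
per task — workers occasionally draw a 6th or 7th line).  The two duplicate
annotations of each slice agree at pooled r = 0.999988, and the fused
consensus surfaces sit 0.50 px RMS from the phantom's true boundaries —
better than any single annotator (noise SD 2 px), thanks to contrast
snapping plus two-rater averaging.

The same run from a shell, with all artifacts (slice PNGs, trace CSVs,
consensus, OBJ surface meshes, thickness maps, report.json) written to
disk:

```sh
crowdoct run --seed 1 --out run1/
```

Individual stages (`crowdoct simulate / map / qc / refine / reduce /
reconstruct / stats`) operate on the same CSV/JSON files for piecemeal use.

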