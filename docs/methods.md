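# Methods

`crowdoct` is an offline embodiment of a crowdsourced segmentation campaign
for macular SD-OCT volumes, organised as a map/reduce data flow: each
B-scan becomes a small paid annotation task duplicated across independent
workers (map), and the collected freehand traces are refined, quality
controlled, fused into consensus boundaries, scored for interrater
agreement, and stacked into a 3D retinal surface model (reduce).  Because
no crowd platform or clinical images are involved, both sides of the
campaign are simulated: a phantom generator plays the role of the scanner
and a stochastic rater model plays the role of the human workers.  The
phantom's noise-free boundaries are retained, so every downstream claim
(consensus accuracy, refinement benefit, agreement statistics) is measured
against known truth.

## Phantom generator

A volume is `n_slices` (default 61) B-scans of `width x height` (default
512 x 496) pixels.  Five strictly ordered boundary curves partition each
scan into six bands of constant reflectivity.  Geometry:

- **Foveal pit** — an inverted Gaussian (depth 45 px, width 60 px) added to
  all boundaries, attenuated linearly with boundary depth, so the inner
  retina dips most, as in a real macula.
- **Pigment-epithelial detachment** — an upward Gaussian dome (amplitude
  25 px, width 50 px, off-centre) applied to the two deepest boundaries;
  this is the pathology that defeats automated segmenters and motivates
  manual annotation.
- **Inter-slice drift** — a per-boundary Gaussian random walk along the
  slice axis, smoothed (sigma 2 slices), centred, and rescaled so
  `interslice_drift_sd` (default 1.5 px) is the standard deviation of the
  offsets over the volume.  Rescaling matters: an unnormalised walk
  accumulates excursions that squeeze the PED-narrowed gap between the
  mid-retina boundaries shut by the last slices.
- **Lateral undulation** — smooth per-slice noise (SD 1.5 px, correlation
  `min(40, width/4)` px) so no two slices are congruent.

Rendering multiplies the band reflectivities by gamma-distributed speckle
(shape 10, i.e. multiplicative contrast ~0.32, emulating frame-averaged
Spectralis output rather than raw single-frame speckle), blurs with a
Gaussian PSF (sigma 1 px), and optionally zeroes a random signal-dropout
band (probability 0.10 per slice, width 40 px).  Configurations whose
deformations push any boundary out of frame or out of order are rejected
with a diagnostic — never silently clamped.  Scales default to 3.87 µm/px
axial and 11.3 µm/px lateral.

What the phantom does **not** emulate: A-scan point-spread physics,
depth-dependent attenuation, vitreous floaters, motion artefacts, curved
(non-flattened) scan geometry, and pathology other than a single PED.
Passing tests therefore demonstrate the pipeline's correctness and its
statistical behaviour under controlled noise, not clinical-grade accuracy.

## Rater model

A simulated worker draws each boundary as the truth curve plus a
systematic axial bias plus laterally correlated Gaussian noise (white
noise convolved with a Gaussian kernel of width `noise_corr_len_px`,
rescaled to exact SD `noise_sd_px`; generated per column and subsampled at
`click_spacing_px`, so the zero-noise rater reproduces truth exactly at
its vertices).  Per-line drawing times are lognormal with median
`line_time_median_s * (1 - learning_rate)^task_index` — a geometric
practice effect.  With probability `extra_line_prob` (two independent
draws) the worker appends a spurious extra line: a noisy near-duplicate of
a boundary drawn parallel at ±12 px.  The offset is deliberate — an extra
line drawn *on top of* its source would cross it almost surely and the
submission would be voided by QC, whereas observed 6–7-line submissions
passed; the two draws use distinct source boundaries and a random side for
the same reason.  With probability `crossing_violation_prob` one adjacent
pair is perturbed to cross, for QC testing.

Default pool: 22 workers, biases ~ N(0, 1 px), noise SD 2 px, correlation
15 px, clicks every 8 px, extra-line probability 0.15 per draw, median
22 s/line with sigma 0.35 and a 5 %/task practice effect.  Under these
defaults a 61-slice, duplication-2 campaign collects 122 assignments with
~646 lines (~5.3 per task) at ~20.4 s per line — the regime the package
is designed to account for.

## Map stage

Each slice is one task at `reward_usd` (default $0.01) duplicated
`duplication` (default 2) times.  The drawing interface's gates are a
required line count (5) and a minimum mean time per line (15 s).  In the
pipeline the timing gate acts at collection time — a too-fast worker is
held until the floor is met, as an interface that refuses early submission
would — while `validate_submission` applies both gates to offline data.
The recorded 80 % prior-approval requirement is task metadata; the
simulator has no approval history to enforce it against.  All currency is
integer cents internally; every collected assignment is paid, including
ones later rejected by QC.

## Trace refinement

Freehand polylines are resampled to one axial value per integer column
(duplicate x collapsed to mean, linear interpolation, no extrapolation).
"Contrast" is the absolute axial central difference
`|I(x, y+1) − I(x, y−1)|/2` (one-sided at frame edges): retinal boundaries
are axial reflectivity transitions.  The refined trace is the path over
per-column offsets in [−5, +5] px maximising summed contrast minus
`jump_penalty x |Δy|` between neighbouring columns, solved exactly by
dynamic programming — "consistently highest contrast" is read as contrast
maximal *subject to lateral continuity*, because an independent per-column
argmax chases speckle.  Equal-cost paths are broken by smaller cumulative
|offset|, then smaller cumulative y (the brute-force enumeration oracle in
the tests applies the identical rule).  The default jump penalty is
`0.5 x intensity_range / window`.  If the refined path's total contrast
does not strictly exceed the original trace's (tolerance
`improvement_tol`, default 0), the original is returned unchanged — on a
featureless image refinement is a no-op, and a zero-noise trace on a sharp
phantom is already optimal and survives exactly.  Scoring rounds positions
to integer rows; no sub-pixel edge fitting is attempted.

## Crossing QC

For every pair of lines in one submission, the dominant vertical order is
the majority sign of the per-column difference over the shared domain;
maximal intervals of inverted sign are crossings (touching without
inversion is not).  Offending submissions are rejected and resubmitted to
a fresh simulated worker — repair by re-sorting would fabricate data.
QC runs on raw traces before refinement and again after: refinement can
itself invert a pair, in which case both involved traces revert to raw.

## Consensus and agreement

Lines are paired across submissions by optimal assignment
(`scipy.optimize.linear_sum_assignment`) on the cost
`(1 − r) + 6 x gap / height`, where `r` is the Pearson correlation of the
per-column positions over the shared domain and `gap` the mean absolute
vertical separation.  Correlation alone cannot separate parallel retinal
layers (all pairs are near r = 1), so the gap term carries the layer
identity; it is normalised by a typical layer separation (height/6 ≈ one
band) rather than the frame height, because at frame scale a one-layer
confusion (~12 px ≈ 0.024) would drown in the sampling noise of r between
laterally correlated traces.  Degenerate constant lines get r = 1 against
constants and r = 0 against varying lines.  At most five pairs are kept
(best cost first); leftovers are reported unmatched.

The consensus line is the per-column arithmetic mean of all matched
contributors over the intersection of their domains, at sub-pixel
precision.  The first two accepted submissions of a task (by submission
time) form the interrater pair; within the pair, roles are ordered by
worker id so the sign of per-task differences is consistent across the
volume.  The headline Pearson r is pooled over all matched per-column
samples of the volume (one r for the whole campaign); R² = r², and the
p-value is the standard t transform with n − 2 degrees of freedom.
Bland-Altman agreement works per consensus line on the two raters' mean
axial positions converted to microns: mean on the x-axis, difference
(A − B) on the y-axis, with bias and bias ± 1.96 SD limits of agreement.

## Reconstruction

Per-slice consensus lines are stacked into per-boundary grids
(slices x columns) in px and µm; columns without consensus stay missing
(NaN) — dropout bands must not masquerade as thin retina, so no
interpolation or inter-slice smoothing is applied by default.  Thickness
maps are adjacent-surface separations in µm.  Exports: per-boundary CSV
grids (round-trip exact), OBJ triangle meshes (two triangles per fully
observed grid cell), thickness CSV and 16-bit PNG heatmaps.  Inter-slice
spacing is configurable (default 120 µm) — scan protocols differ and no
single value is privileged.

## Numerical and design choices

- One master seed; all streams (volume, per-slice rendering, per-rater
  noise, worker-to-task allocation) derive from it via fixed spawn keys,
  so adding a rater never perturbs existing data and identical
  configurations are byte-identical, including the JSON reports (sorted
  keys, simulated submission clock rather than wall time).
- Matching tie-breaks (smaller gap, then lower index) are implemented as
  infinitesimal cost epsilons; the DP tie-break is exact lexicographic.
- Cents arithmetic is integer throughout; dollar outputs are exact
  multiples of $0.01.
- Statistical tests pin seeds and use tolerances derived from the
  statistic's own sampling variability (binomial confidence bands for
  rates, Monte-Carlo tolerance ~10 % for RMSE ratios).

## Problem sizes

The test suite exercises the full 61 x 512 x 496 default campaign for the
end-to-end and agreement checks and reduced phantoms (3–5 slices, 96–128
columns) for unit-level properties; brute-force oracles (exhaustive path
enumeration, permutation search) run on toys small enough to enumerate
completely (≤12 columns, ≤3 lines).

## Known limitations

- If two raters both draw a spurious extra line on the same side of the
  same boundary, the extra–extra pair can cost less than a genuine pair
  and displace it from the five kept matches; the consensus for that slice
  then carries a duplicated boundary.  Rare under the defaults (distinct
  sources and random sides make the coincidence ~1 % of tasks) but not
  impossible; it surfaces as an isolated RMSE spike.
- The refinement improvement check is per whole trace, so a snap that
  improves most columns but worsens a few is still accepted.
- Consensus ordering is asserted, not enforced; a pathological matching
  that produces crossing consensus lines raises an error rather than
  repairing it.
- Pearson r pooled over columns treats laterally correlated samples as
  independent; its p-value is therefore anti-conservative.  The r itself
  is unaffected.
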