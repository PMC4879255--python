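"""Synthetic macular OCT phantoms and simulated human raters.

The phantom is a stack of B-scans built from five ordered layer boundaries:
piecewise-constant layer reflectivities deformed by a foveal pit (inverted
Gaussian, attenuating with depth) and an optional pigment-epithelial-
detachment dome on the two deepest boundaries, multiplied by gamma speckle,
Gaussian-blurred, with optional signal-dropout columns.  Simulated raters
draw each boundary as a polyline: truth plus a systematic bias plus
laterally correlated noise, subsampled at a click spacing, with lognormal
per-line drawing times, occasional extra (duplicated) lines, and optional
deliberate crossing violations for QC testing.

All outputs are pure functions of (config, model, seed).  Per-slice and
per-rater random streams are derived from the master seed with fixed spawn
keys so that adding a rater never perturbs previously generated data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .trace_refine import BoundaryTrace

__all__ = [
    "PhantomConfig",
    "GroundTruthBoundaries",
    "RaterModel",
    "BScanImage",
    "SegmentationSet",
    "generate_volume",
    "simulate_rater",
]


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic substream: fixed spawn key off one master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass(frozen=True)
class BScanImage:
    """One grayscale B-scan with pixel-to-micron scaling."""

    pixels: np.ndarray  # (height, width) float in [0, 1]
    slice_index: int
    axial_um_per_px: float
    lateral_um_per_px: float

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GroundTruthBoundaries:
    """Noise-free boundary curves of one slice, one axial value per column."""

    slice_index: int
    curves: np.ndarray  # (n_boundaries, width) float px

    def __post_init__(self) -> None:
        c = np.asarray(self.curves, dtype=float)
        if np.any(np.diff(c, axis=0) <= 0):
            raise ValueError("ground-truth curves must be strictly ordered")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, reflectivity and noise model of the synthetic volume.

    Defaults emulate a 61-slice Spectralis-like macular cube: 512 lateral
    by 496 axial pixels, five boundaries, a central foveal pit, moderate
    multiplicative speckle, and an off-centre PED dome.
    """

    width: int = 512
    height: int = 496
    n_boundaries: int = 5
    base_depths: tuple[float, ...] = (160.0, 210.0, 260.0, 310.0, 360.0)
    pit_depth: float = 45.0
    pit_width: float = 60.0
    layer_intensities: tuple[float, ...] = (0.05, 0.40, 0.20, 0.45, 0.85, 0.30)
    speckle_shape: float = 10.0  # gamma shape; inf disables speckle
    blur_sigma: float = 1.0
    dropout_prob: float = 0.10
    dropout_width: int = 40
    ped_amplitude: float = 25.0
    ped_center: float = 360.0
    ped_width: float = 50.0
    interslice_drift_sd: float = 1.5
    n_slices: int = 61
    axial_um_per_px: float = 3.87
    lateral_um_per_px: float = 11.3

    def __post_init__(self) -> None:
        depths = np.asarray(self.base_depths, dtype=float)
        if len(depths) != self.n_boundaries:
            raise ValueError("base_depths must have n_boundaries entries")
        if np.any(np.diff(depths) <= 0):
            raise ValueError("base_depths must be strictly increasing")
        ints = np.asarray(self.layer_intensities, dtype=float)
        if len(ints) != self.n_boundaries + 1:
            raise ValueError(
                "layer_intensities needs n_boundaries+1 entries "
                f"(got {len(ints)}, need {self.n_boundaries + 1})")
        if np.any(ints < 0) or np.any(ints > 1):
            raise ValueError("layer_intensities must lie in [0, 1]")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must be in [0, 1]")


@dataclass(frozen=True)
class RaterModel:
    """Stochastic model of one annotator.

    Error is laterally correlated Gaussian noise of SD ``noise_sd_px`` and
    correlation length ``noise_corr_len_px`` added on top of a systematic
    axial ``bias_px``.  Per-line drawing times are lognormal with median
    ``line_time_median_s * (1 - learning_rate)**task_index``.
    """

    worker_id: str
    bias_px: float = 0.0
    noise_sd_px: float = 2.0
    noise_corr_len_px: float = 15.0
    click_spacing_px: int = 8
    extra_line_prob: float = 0.0
    extra_line_offset_px: float = 12.0
    crossing_violation_prob: float = 0.0
    line_time_median_s: float = 22.0
    line_time_sigma: float = 0.35
    learning_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd_px < 0:
            raise ValueError("noise_sd_px must be >= 0")
        if self.click_spacing_px < 1:
            raise ValueError("click_spacing_px must be >= 1")
        for name in ("extra_line_prob", "crossing_violation_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.learning_rate < 1:
            raise ValueError("learning_rate must be in [0, 1)")


@dataclass(frozen=True)
class SegmentationSet:
    """One worker's full annotation of one slice, with per-line timing."""

    worker_id: str
    slice_index: int
    traces: tuple[BoundaryTrace, ...]
    line_seconds: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.traces) != len(self.line_seconds):
            raise ValueError("one duration per trace required")

    @property
    def n_lines(self) -> int:
        return len(self.traces)


# ---------------------------------------------------------------------------
# phantom geometry

def _base_curves(config: PhantomConfig) -> np.ndarray:
    """Deformed boundary curves shared by all slices, shape (n_b, width)."""
    x = np.arange(config.width, dtype=float)
    depths = np.asarray(config.base_depths, dtype=float)
    curves = np.repeat(depths[:, None], config.width, axis=1)

    # foveal pit: inverted Gaussian, depth attenuating for deeper layers
    cx = (config.width - 1) / 2.0
    pit = np.exp(-0.5 * ((x - cx) / max(config.pit_width, 1e-9)) ** 2)
    atten = 1.0 - np.arange(config.n_boundaries) / config.n_boundaries
    curves += config.pit_depth * atten[:, None] * pit[None, :]

    # PED: upward dome on the two deepest boundaries
    if config.ped_amplitude > 0 and config.n_boundaries >= 2:
        dome = config.ped_amplitude * np.exp(
            -0.5 * ((x - config.ped_center) / max(config.ped_width, 1e-9)) ** 2)
        curves[-2:] -= dome[None, :]
    return curves


def _check_curves(curves: np.ndarray, height: int, slice_index: int) -> None:
    if np.any(curves < 0) or np.any(curves >= height):
        raise ValueError(
            f"slice {slice_index}: boundary deformation leaves the frame "
            f"[0, {height}); adjust pit/PED/drift amplitudes")
    if np.any(np.diff(curves, axis=0) <= 0):
        raise ValueError(
            f"slice {slice_index}: boundary deformation breaks the strict "
            "vertical ordering; adjust pit/PED/drift amplitudes")


def _render_slice(curves: np.ndarray, config: PhantomConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Layer-constant reflectivity x speckle, blurred, with dropout."""
    rows = np.arange(config.height, dtype=float)[:, None]
    region = (curves[:, None, :] <= rows[None, :, :]).sum(axis=0)
    img = np.asarray(config.layer_intensities, dtype=float)[region]

    if np.isfinite(config.speckle_shape):
        k = float(config.speckle_shape)
        img = img * rng.gamma(k, 1.0 / k, size=img.shape)
    if config.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, config.blur_sigma)
    if config.dropout_prob > 0:
        if rng.random() < config.dropout_prob:
            x0 = int(rng.integers(0, max(config.width - config.dropout_width, 1)))
            img[:, x0:x0 + config.dropout_width] = 0.0
    return np.clip(img, 0.0, 1.0)


def generate_volume(
    config: PhantomConfig, seed: int
) -> tuple[list[BScanImage], list[GroundTruthBoundaries]]:
    """Generate ``config.n_slices`` B-scans with their ground truth.

    Boundaries drift smoothly across slices (per-boundary Gaussian random
    walk of step SD ``interslice_drift_sd``, re-smoothed along the slice
    axis) and carry a small smooth lateral undulation per slice.  Identical
    seeds give bit-identical output; a configuration whose deformations
    push any boundary out of frame (or out of order) is rejected.
    """
    base = _base_curves(config)

    # smooth random-walk drift across slices, centred and rescaled so that
    # interslice_drift_sd is the SD of the offsets over the whole volume
    # (an unnormalised walk would accumulate excursions that squeeze the
    # PED-narrowed layer gap shut by the last slices)
    drift_rng = _rng(seed, 0)
    steps = drift_rng.normal(
        0.0, 1.0, size=(config.n_boundaries, config.n_slices))
    drift = np.cumsum(steps, axis=1)
    if config.n_slices > 1 and config.interslice_drift_sd > 0:
        drift = ndimage.gaussian_filter1d(drift, sigma=2.0, axis=1,
                                          mode="nearest")
        drift -= drift.mean(axis=1, keepdims=True)
        sd = drift.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        drift = config.interslice_drift_sd * drift / sd
    else:
        drift[:] = 0.0

    images: list[BScanImage] = []
    truths: list[GroundTruthBoundaries] = []
    for s in range(config.n_slices):
        rng = _rng(seed, 1, s)
        sigma_u = min(40.0, config.width / 4.0)
        undul = ndimage.gaussian_filter1d(
            rng.standard_normal((config.n_boundaries, config.width)),
            sigma=sigma_u, axis=1, mode="wrap")
        undul -= undul.mean(axis=1, keepdims=True)
        sd = undul.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        undul = 1.5 * undul / sd
        curves = base + drift[:, s:s + 1] + undul
        _check_curves(curves, config.height, s)
        img = _render_slice(curves, config, rng)
        images.append(BScanImage(
            pixels=img, slice_index=s,
            axial_um_per_px=config.axial_um_per_px,
            lateral_um_per_px=config.lateral_um_per_px))
        truths.append(GroundTruthBoundaries(slice_index=s, curves=curves))
    return images, truths


# ---------------------------------------------------------------------------
# rater simulation

def _correlated_noise(width: int, sd: float, corr_len: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Stationary Gaussian noise of exact SD ``sd``, correlation length
    ``corr_len`` px (Gaussian kernel), generated with wrap-around so the
    variance is uniform across columns."""
    if sd == 0:
        return np.zeros(width)
    white = rng.standard_normal(width)
    if corr_len <= 0:
        return sd * white
    smooth = ndimage.gaussian_filter1d(white, corr_len, mode="wrap")
    impulse = np.zeros(width)
    impulse[0] = 1.0
    h = ndimage.gaussian_filter1d(impulse, corr_len, mode="wrap")
    norm = np.sqrt(np.sum(h ** 2))
    return sd * smooth / norm


def _trace_from_curve(curve: np.ndarray, spacing: int) -> BoundaryTrace:
    width = curve.size
    xs = np.arange(0, width, spacing)
    if xs[-1] != width - 1:
        xs = np.append(xs, width - 1)
    vertices = np.column_stack([xs.astype(float), curve[xs]])
    return BoundaryTrace(vertices=vertices)


def simulate_rater(
    truth: GroundTruthBoundaries,
    model: RaterModel,
    task_index: int,
    seed: int,
) -> SegmentationSet:
    """Simulate one worker annotating one slice.

    For each boundary the drawn line is truth + bias + correlated noise,
    recorded at ``click_spacing_px`` vertices.  With probability
    ``extra_line_prob`` (two independent draws) a noisy duplicate of a
    random boundary is appended, yielding 6 or 7 lines.  With probability
    ``crossing_violation_prob`` one adjacent pair is perturbed to cross.
    Per-line times are lognormal with a median shrinking geometrically in
    ``task_index`` (practice effect).
    """
    rng = _rng(seed, 2)
    curves = np.asarray(truth.curves, dtype=float)
    n_b, width = curves.shape

    drawn = []
    for b in range(n_b):
        err = _correlated_noise(width, model.noise_sd_px,
                                model.noise_corr_len_px, rng)
        drawn.append(curves[b] + model.bias_px + err)

    # occasional extra lines: a noisy near-duplicate drawn parallel to a
    # real boundary, offset to one side (an overlapping duplicate would
    # cross its source and be caught by QC; observed extras were accepted).
    # The two draws use distinct source boundaries and a random side.
    extra_srcs = rng.choice(n_b, size=min(2, n_b), replace=False)
    for k in range(2):
        if rng.random() < model.extra_line_prob:
            src = int(extra_srcs[k % len(extra_srcs)])
            side = 1.0 if rng.random() < 0.5 else -1.0
            err = _correlated_noise(width, model.noise_sd_px,
                                    model.noise_corr_len_px, rng)
            drawn.append(curves[src] + model.bias_px
                         + side * model.extra_line_offset_px + err)

    if model.crossing_violation_prob > 0 and rng.random() < model.crossing_violation_prob:
        i = int(rng.integers(0, n_b - 1))
        x0 = int(rng.integers(0, width - width // 4))
        x1 = x0 + width // 4
        gap = drawn[i + 1][x0:x1] - drawn[i][x0:x1]
        drawn[i] = drawn[i].copy()
        drawn[i][x0:x1] += np.maximum(gap, 0) + 3.0  # push line i below i+1

    traces = tuple(
        _trace_from_curve(c, model.click_spacing_px) for c in drawn)

    median = model.line_time_median_s * (1.0 - model.learning_rate) ** task_index
    times = tuple(
        float(t) for t in
        rng.lognormal(np.log(max(median, 1e-6)), model.line_time_sigma,
                      size=len(traces)))
    return SegmentationSet(
        worker_id=model.worker_id, slice_index=truth.slice_index,
        traces=traces, line_seconds=times)
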