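"""Contrast-based refinement of hand-drawn layer traces.

A freehand polyline is first resampled to one axial position per integer
lateral column.  It is then snapped to the consistently highest-contrast
axial edge within a small search window: a dynamic programme finds, over
candidate offsets in ``[-window_px, +window_px]`` per column, the path that
maximises summed axial-gradient magnitude minus a lateral-continuity
penalty.  If the refined path does not strictly improve the total contrast
score of the original trace, the original is kept unchanged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "BoundaryTrace",
    "RefineConfig",
    "resample_trace",
    "contrast_score",
    "snap_to_contrast",
]


@dataclass(frozen=True)
class BoundaryTrace:
    """One annotated layer boundary.

    ``vertices`` are the raw (x, y) click points in pixels.  After
    :func:`resample_trace`, ``x`` holds every integer column of the drawn
    extent and ``y`` the interpolated axial position at each column.
    ``source`` records whether the per-column values come from the raw
    drawing or from contrast refinement.
    """

    vertices: np.ndarray  # (n, 2) float
    x: np.ndarray | None = None  # (m,) int columns, contiguous
    y: np.ndarray | None = None  # (m,) float axial px
    source: str = "raw"

    @property
    def is_resampled(self) -> bool:
        return self.x is not None

    def resampled(self) -> "BoundaryTrace":
        """Return a copy with per-column ``x``/``y`` filled in."""
        if self.is_resampled:
            return self
        x, y = resample_trace(self.vertices)
        return replace(self, x=x, y=y)


@dataclass(frozen=True)
class RefineConfig:
    """Parameters of the contrast-snapping search.

    window_px
        Axial search half-width around the drawn trace (px).
    jump_penalty
        Cost per pixel of column-to-column jump of the refined path.
        ``None`` selects ``0.5 * intensity_range / window_px`` at run time.
    improvement_tol
        Minimum fractional gain in total contrast score required to accept
        the refined path; 0 accepts any strict gain.
    """

    window_px: int = 5
    jump_penalty: float | None = None
    improvement_tol: float = 0.0

    def __post_init__(self) -> None:
        if self.window_px < 0:
            raise ValueError("window_px must be >= 0")
        if self.jump_penalty is not None and self.jump_penalty < 0:
            raise ValueError("jump_penalty must be >= 0")
        if self.improvement_tol < 0:
            raise ValueError("improvement_tol must be >= 0")


def resample_trace(vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline to one y value per integer column.

    Vertices are sorted by x; vertices sharing the same x are collapsed to
    their mean y.  Linear interpolation is evaluated at every integer column
    between the first and last distinct x; no extrapolation occurs.

    Returns ``(x, y)`` with ``x`` the integer columns and ``y`` the axial
    positions.  Raises ``ValueError`` for fewer than 2 distinct x values.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ValueError("vertices must be an (n, 2) array")
    order = np.argsort(v[:, 0], kind="stable")
    v = v[order]
    xs, inverse = np.unique(v[:, 0], return_inverse=True)
    if xs.size < 2:
        raise ValueError("need at least 2 distinct x values to resample")
    ys = np.zeros_like(xs)
    counts = np.zeros_like(xs)
    np.add.at(ys, inverse, v[:, 1])
    np.add.at(counts, inverse, 1.0)
    ys /= counts
    x_lo = int(np.ceil(xs[0]))
    x_hi = int(np.floor(xs[-1]))
    if x_hi < x_lo:
        raise ValueError("polyline spans no integer column")
    cols = np.arange(x_lo, x_hi + 1)
    return cols, np.interp(cols, xs, ys)


def contrast_score(image: np.ndarray, x, y) -> np.ndarray | float:
    """Axial contrast at (x, y): |I(x, y+1) - I(x, y-1)| / 2.

    One-sided differences are used at the top and bottom rows.  ``x`` and
    ``y`` may be scalars or equal-shaped integer arrays.  Out-of-range
    coordinates raise ``IndexError``.
    """
    img = np.asarray(image, dtype=float)
    xa = np.asarray(x, dtype=int)
    ya = np.asarray(y, dtype=int)
    h, w = img.shape
    if np.any(xa < 0) or np.any(xa >= w) or np.any(ya < 0) or np.any(ya >= h):
        raise IndexError("coordinates outside the image")
    up = np.maximum(ya - 1, 0)
    down = np.minimum(ya + 1, h - 1)
    span = np.where(down == up, 1.0, (down - up).astype(float))
    score = np.abs(img[down, xa] - img[up, xa]) / span
    if np.isscalar(x) and np.isscalar(y):
        return float(score)
    return score


def _default_jump_penalty(image: np.ndarray, window_px: int) -> float:
    rng = float(np.ptp(image))
    return 0.5 * rng / max(window_px, 1)


def _path_keys(image, cols, base_rows, offsets, jump_penalty):
    """Per-candidate score matrix for the DP / oracle.

    Returns ``scores[c, k]``: contrast at column ``cols[c]``, row
    ``base_rows[c] + offsets[k]`` (rows clipped to the image).
    """
    h = image.shape[0]
    rows = np.clip(base_rows[:, None] + offsets[None, :], 0, h - 1)
    xs = np.broadcast_to(cols[:, None], rows.shape)
    return contrast_score(image, xs, rows), rows


def _dp_best_path(image, cols, base_rows, offsets, jump_penalty):
    """Maximise sum(score) - jump_penalty * sum(|dy|) over offset paths.

    Ties between equal-score paths are broken by smaller cumulative
    sum(|offset|), then by smaller cumulative sum(y).
    """
    scores, rows = _path_keys(image, cols, base_rows, offsets, jump_penalty)
    n_cols, n_off = scores.shape
    abs_off = np.abs(offsets).astype(float)

    best = scores[0].copy()
    cum_abs = np.broadcast_to(abs_off, (n_off,)).astype(float).copy()
    cum_y = rows[0].astype(float).copy()
    back = np.zeros((n_cols, n_off), dtype=int)

    for c in range(1, n_cols):
        dy = np.abs(rows[c][None, :] - rows[c - 1][:, None]).astype(float)
        cand = best[:, None] - jump_penalty * dy  # (prev, cur)
        top = cand.max(axis=0)
        tie = cand >= top[None, :] - 1e-12
        key1 = np.where(tie, cum_abs[:, None], np.inf)
        best1 = key1.min(axis=0)
        tie &= key1 <= best1[None, :] + 1e-12
        key2 = np.where(tie, cum_y[:, None], np.inf)
        prev = np.argmin(key2, axis=0)
        back[c] = prev
        best = cand[prev, np.arange(n_off)] + scores[c]
        cum_abs = cum_abs[prev] + abs_off
        cum_y = cum_y[prev] + rows[c]

    # final candidate selection with the same tie-break
    top = best.max()
    tie = best >= top - 1e-12
    key1 = np.where(tie, cum_abs, np.inf)
    tie &= key1 <= key1.min() + 1e-12
    key2 = np.where(tie, cum_y, np.inf)
    k = int(np.argmin(key2))

    path = np.empty(n_cols, dtype=int)
    path[-1] = k
    for c in range(n_cols - 1, 0, -1):
        path[c - 1] = back[c, path[c]]
    chosen_rows = rows[np.arange(n_cols), path]
    total = float(scores[np.arange(n_cols), path].sum()
                  - jump_penalty * np.abs(np.diff(chosen_rows)).sum())
    return chosen_rows.astype(float), total


def _brute_force_best_path(image, cols, base_rows, offsets, jump_penalty):
    """Exhaustive enumeration of all offset paths (oracle; tiny images only)."""
    scores, rows = _path_keys(image, cols, base_rows, offsets, jump_penalty)
    n_cols, n_off = scores.shape
    abs_off = np.abs(offsets).astype(float)
    best_key = None
    best_rows = None
    for combo in itertools.product(range(n_off), repeat=n_cols):
        idx = np.asarray(combo)
        r = rows[np.arange(n_cols), idx]
        total = scores[np.arange(n_cols), idx].sum()
        total -= jump_penalty * np.abs(np.diff(r)).sum()
        key = (-total, abs_off[idx].sum(), r.sum())
        if best_key is None or key < best_key:
            best_key = key
            best_rows = r.astype(float)
    return best_rows, float(-best_key[0])


def snap_to_contrast(
    image: np.ndarray,
    trace: BoundaryTrace,
    config: RefineConfig = RefineConfig(),
) -> BoundaryTrace:
    """Snap a resampled trace to the consistently highest-contrast edge.

    The refined path never deviates from the input by more than
    ``window_px`` at any column.  If the refined path's total contrast score
    does not exceed the original's by at least ``improvement_tol``
    (relative), the original trace is returned with ``source='raw'``.
    """
    trace = trace.resampled()
    img = np.asarray(image, dtype=float)
    h = img.shape[0]
    cols = trace.x
    base_rows = np.clip(np.rint(trace.y).astype(int), 0, h - 1)

    if config.window_px == 0:
        return replace(trace, source="raw")

    jump = config.jump_penalty
    if jump is None:
        jump = _default_jump_penalty(img, config.window_px)

    offsets = np.arange(-config.window_px, config.window_px + 1)
    refined_rows, _ = _dp_best_path(img, cols, base_rows, offsets, jump)

    orig_total = float(contrast_score(img, cols, base_rows).sum())
    refined_total = float(contrast_score(
        img, cols, refined_rows.astype(int)).sum())

    if refined_total <= orig_total * (1.0 + config.improvement_tol):
        return replace(trace, source="raw")
    return replace(trace, y=refined_rows, source="refined")
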