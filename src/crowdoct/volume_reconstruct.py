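"""Final reduction: stack per-slice consensus lines into 3D surfaces.

Surfaces are (n_slices x width) grids of axial positions, one per boundary,
with explicit NaN for columns outside a slice's consensus domain (dropout
bands must not masquerade as thin retina).  Thickness maps are axial
separations of adjacent surfaces in microns.  Exports: per-boundary CSV
grids (round-trip exact), OBJ triangle meshes, thickness CSV and 16-bit
PNG heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .reduce_consensus import ConsensusSegmentation

__all__ = [
    "Scales",
    "RetinaSurfaceModel",
    "stack_surfaces",
    "export_model",
    "read_surface_csv",
]

EXPORT_FORMATS = ("csv", "obj", "thickness")


@dataclass(frozen=True)
class Scales:
    """Physical scaling of the reconstruction grid (microns per unit)."""

    axial_um_per_px: float = 3.87
    lateral_um_per_px: float = 11.3
    slice_um: float = 120.0  # inter-slice spacing; protocol dependent


@dataclass(frozen=True)
class RetinaSurfaceModel:
    """Stacked boundary surfaces with thickness maps.

    ``surfaces_px[b, s, x]`` is the axial position of boundary ``b`` on
    slice ``s`` at column ``x`` (NaN where no consensus exists);
    ``thickness_um[b]`` separates boundaries ``b`` and ``b+1``.
    """

    surfaces_px: np.ndarray  # (n_boundaries, n_slices, width), NaN = missing
    thickness_um: np.ndarray  # (n_boundaries - 1, n_slices, width)
    scales: Scales

    @property
    def n_boundaries(self) -> int:
        return self.surfaces_px.shape[0]

    @property
    def surfaces_um(self) -> np.ndarray:
        return self.surfaces_px * self.scales.axial_um_per_px


def stack_surfaces(
    consensus: Sequence[ConsensusSegmentation],
    scales: Scales = Scales(),
    width: int | None = None,
) -> RetinaSurfaceModel:
    """Assemble per-slice consensus lines into boundary surface grids.

    Slices are placed in ``image_ref`` order.  Columns outside a slice's
    consensus domain stay NaN — no interpolation is applied.  Inconsistent
    widths across slices are an error.
    """
    if not consensus:
        raise ValueError("no consensus slices to stack")
    ordered = sorted(consensus, key=lambda c: c.image_ref)
    n_b = max(len(c.lines) for c in ordered)
    if width is None:
        width = max(int(ln.x[-1]) + 1 for c in ordered for ln in c.lines)
    for c in ordered:
        for ln in c.lines:
            if int(ln.x[-1]) >= width:
                raise ValueError(
                    f"slice {c.image_ref} extends to column {int(ln.x[-1])}, "
                    f"beyond the declared width {width}")

    n_s = len(ordered)
    grid = np.full((n_b, n_s, width), np.nan)
    for s, c in enumerate(ordered):
        if len(c.lines) != n_b:
            raise ValueError(
                f"slice {c.image_ref} has {len(c.lines)} consensus lines, "
                f"expected {n_b}")
        for b, ln in enumerate(c.lines):
            grid[b, s, ln.x] = ln.y_px

    sep = np.diff(grid, axis=0)
    both = ~np.isnan(sep)
    if np.any(sep[both] < 0):
        raise ValueError("stacked surfaces violate the vertical ordering")
    thickness = sep * scales.axial_um_per_px
    return RetinaSurfaceModel(
        surfaces_px=grid, thickness_um=thickness, scales=scales)


# ---------------------------------------------------------------------------
# export

def _surface_frame(model: RetinaSurfaceModel, b: int) -> pd.DataFrame:
    g = model.surfaces_px[b]
    s_idx, x_idx = np.nonzero(~np.isnan(g))
    return pd.DataFrame({
        "slice": s_idx,
        "x": x_idx,
        "y_px": g[s_idx, x_idx],
        "y_um": g[s_idx, x_idx] * model.scales.axial_um_per_px,
    })


def read_surface_csv(path: Path, n_slices: int, width: int) -> np.ndarray:
    """Read one boundary grid back; missing nodes stay NaN (round-trip
    exact against :func:`export_model`'s CSV writer)."""
    df = pd.read_csv(path, dtype={"slice": int, "x": int, "y_px": float},
                     float_precision="round_trip")
    grid = np.full((n_slices, width), np.nan)
    grid[df["slice"].to_numpy(), df["x"].to_numpy()] = df["y_px"].to_numpy()
    return grid


def _write_obj(path: Path, grid: np.ndarray, scales: Scales) -> tuple[int, int]:
    """Triangulated surface mesh: two triangles per fully observed grid
    cell; NaN nodes are skipped.  Returns (n_vertices, n_triangles)."""
    n_s, n_x = grid.shape
    idx = np.full((n_s, n_x), -1, dtype=int)
    lines = ["# crowdoct boundary surface mesh"]
    v = 0
    for s in range(n_s):
        for x in range(n_x):
            y = grid[s, x]
            if np.isnan(y):
                continue
            v += 1
            idx[s, x] = v  # OBJ is 1-based
            lines.append(
                f"v {x * scales.lateral_um_per_px:.6f} "
                f"{s * scales.slice_um:.6f} "
                f"{y * scales.axial_um_per_px:.6f}")
    n_tri = 0
    for s in range(n_s - 1):
        for x in range(n_x - 1):
            a, b_, c, d = idx[s, x], idx[s, x + 1], idx[s + 1, x], idx[s + 1, x + 1]
            if min(a, b_, c, d) < 0:
                continue
            lines.append(f"f {a} {b_} {c}")
            lines.append(f"f {b_} {d} {c}")
            n_tri += 2
    path.write_text("\n".join(lines) + "\n")
    return v, n_tri


def export_model(
    model: RetinaSurfaceModel,
    out_dir: Path,
    formats: Sequence[str] = ("csv", "obj", "thickness"),
) -> dict[str, list[str]]:
    """Write the model to disk; returns the paths written per format."""
    unknown = [f for f in formats if f not in EXPORT_FORMATS]
    if unknown:
        raise ValueError(
            f"unsupported format(s) {unknown}; supported: {list(EXPORT_FORMATS)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, list[str]] = {f: [] for f in formats}

    for b in range(model.n_boundaries):
        if "csv" in formats:
            p = out_dir / f"boundary_{b}.csv"
            _surface_frame(model, b).to_csv(p, index=False,
                                             float_format="%.17g")
            written["csv"].append(str(p))
        if "obj" in formats:
            p = out_dir / f"boundary_{b}.obj"
            _write_obj(p, model.surfaces_px[b], model.scales)
            written["obj"].append(str(p))

    if "thickness" in formats:
        for b in range(model.n_boundaries - 1):
            t = model.thickness_um[b]
            p = out_dir / f"thickness_{b}_{b + 1}.csv"
            s_idx, x_idx = np.nonzero(~np.isnan(t))
            pd.DataFrame({
                "slice": s_idx, "x": x_idx,
                "thickness_um": t[s_idx, x_idx],
            }).to_csv(p, index=False, float_format="%.17g")
            written["thickness"].append(str(p))

            png = out_dir / f"thickness_{b}_{b + 1}.png"
            finite = t[~np.isnan(t)]
            hi = float(finite.max()) if finite.size else 1.0
            hi = hi if hi > 0 else 1.0
            img = np.where(np.isnan(t), 0.0, t) / hi
            iio.imwrite(png, (img * 65535).astype(np.uint16))
            written["thickness"].append(str(png))
    return written
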