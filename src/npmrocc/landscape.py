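"""Landscape-scale habitat availability analysis.

Quantifies how much potentially suitable breeding habitat a landscape
offers and where: perennial-shoreline line density in a fixed-radius
moving window (default 5 km, the species' maximum dispersal distance) on
a regular grid (default 270-m pixels), masked to climatically suitable
areas, summarised as contiguous habitat patches, land-ownership shares
and kernel-smoothed density distributions of the availability values.

Coordinates are planar and expressed in km; rasters are plain NumPy
arrays on a :class:`GridConfig` with row 0 at the grid origin (south).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage, stats

logger = logging.getLogger(__name__)

__all__ = [
    "GridConfig",
    "Raster",
    "PatchTable",
    "DensityCurve",
    "rasterize_line_length",
    "moving_window_density",
    "mask_by_suitability",
    "patch_statistics",
    "value_density_distribution",
    "ownership_shares",
]


@dataclasses.dataclass(frozen=True)
class GridConfig:
    """Regular analysis grid: origin (x0, y0) km, (nrows, ncols) cells of
    ``cell_size`` km, and the moving-window radius in km."""

    origin: tuple[float, float] = (0.0, 0.0)
    shape: tuple[int, int] = (200, 200)
    cell_size: float = 0.27
    window_radius: float = 5.0

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell size must be > 0")
        if self.window_radius < self.cell_size:
            raise ValueError("window radius must be at least one cell")

    @property
    def cell_area(self) -> float:
        """Cell area in km^2."""
        return self.cell_size * self.cell_size

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point; clipped to the grid."""
        col = int((x - self.origin[0]) // self.cell_size)
        row = int((y - self.origin[1]) // self.cell_size)
        nrows, ncols = self.shape
        return min(max(row, 0), nrows - 1), min(max(col, 0), ncols - 1)


@dataclasses.dataclass
class Raster:
    """Single-band raster on a :class:`GridConfig`; NaN marks NA cells."""

    grid: GridConfig
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError(
                f"raster shape {self.values.shape} does not match grid "
                f"{self.grid.shape}")

    def aligned_with(self, other: "Raster") -> bool:
        return self.grid == other.grid


def _require_aligned(a: Raster, b: Raster, what: str) -> None:
    if not a.aligned_with(b):
        raise ValueError(f"{what}: rasters are on different grids")


def rasterize_line_length(lines, grid: GridConfig) -> Raster:
    """Exact per-cell line length (km).

    Each segment is split at every grid-line crossing and each piece's
    length assigned to the cell containing it, so the summed raster
    equals the total (clipped) line length up to floating-point error.
    Zero-length segments are skipped (count logged).
    """
    nrows, ncols = grid.shape
    out = np.zeros((nrows, ncols))
    x0, y0 = grid.origin
    cs = grid.cell_size
    n_degenerate = 0
    for line in lines:
        coords = np.asarray(getattr(line, "coords", line), dtype=float)
        for (xa, ya), (xb, yb) in zip(coords[:-1], coords[1:]):
            seg_len = float(np.hypot(xb - xa, yb - ya))
            if seg_len == 0.0:
                n_degenerate += 1
                continue
            # parametric positions of all grid-line crossings
            ts = [0.0, 1.0]
            for (a, b, o) in ((xa, xb, x0), (ya, yb, y0)):
                if b != a:
                    lo, hi = sorted((a, b))
                    k0 = int(np.ceil((lo - o) / cs))
                    k1 = int(np.floor((hi - o) / cs))
                    for k in range(k0, k1 + 1):
                        t = (o + k * cs - a) / (b - a)
                        if 0.0 < t < 1.0:
                            ts.append(t)
            ts = sorted(set(ts))
            for t1, t2 in zip(ts[:-1], ts[1:]):
                tm = 0.5 * (t1 + t2)
                xm = xa + tm * (xb - xa)
                ym = ya + tm * (yb - ya)
                r = int((ym - y0) // cs)
                c = int((xm - x0) // cs)
                if 0 <= r < nrows and 0 <= c < ncols:
                    out[r, c] += (t2 - t1) * seg_len
    if n_degenerate:
        logger.warning("skipped %d zero-length segments", n_degenerate)
    return Raster(grid, out)


def moving_window_density(length_raster: Raster, grid: Optional[GridConfig] = None
                          ) -> Raster:
    """Line density (km/km²) in a circular moving window.

    Window membership is by cell-centre distance; every window is divided
    by the full window area π·r² including at the study-area edge — the
    standard GIS line-density convention, which treats area outside the
    extent as carrying zero line length.
    """
    grid = grid or length_raster.grid
    r_cells = grid.window_radius / grid.cell_size
    k = int(np.floor(r_cells))
    dy, dx = np.mgrid[-k:k + 1, -k:k + 1]
    footprint = (dy * dy + dx * dx) <= r_cells * r_cells
    summed = ndimage.convolve(length_raster.values, footprint.astype(float),
                              mode="constant", cval=0.0)
    area = np.pi * grid.window_radius ** 2
    return Raster(grid, summed / area)


def mask_by_suitability(density: Raster, suitability: Raster,
                        threshold: float = 0.20) -> Raster:
    """NA out density cells whose climate suitability is below threshold."""
    _require_aligned(density, suitability, "mask_by_suitability")
    values = density.values.copy()
    values[suitability.values < threshold] = np.nan
    return Raster(density.grid, values)


@dataclasses.dataclass
class PatchTable:
    """Contiguous available-habitat patches (8-neighbour adjacency).

    ``patches`` has one row per patch: id, area_ha, n_cells, occupied.
    ``top_shares`` maps k to the fraction of total available area in the
    k largest patches.
    """

    patches: pd.DataFrame
    total_area_ha: float
    top_shares: dict[int, float]

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    @property
    def n_occupied(self) -> int:
        return int(self.patches["occupied"].sum())


def patch_statistics(mask: Raster, observations: Optional[np.ndarray] = None,
                     top_k: tuple[int, ...] = (1, 14)) -> PatchTable:
    """Connected components of the available (non-NA, nonzero-mask) cells.

    ``mask`` may be boolean-valued or any raster whose non-NA cells count
    as available.  A patch is flagged occupied when any observation point
    falls inside it.  Areas are reported in hectares (1 km² = 100 ha).
    """
    avail = np.isfinite(mask.values) & (mask.values != 0) \
        if mask.values.dtype != bool else mask.values
    structure = np.ones((3, 3), dtype=int)  # 8-connectivity
    labels, n = ndimage.label(avail, structure=structure)
    cell_ha = mask.grid.cell_area * 100.0
    if n == 0:
        return PatchTable(
            patches=pd.DataFrame(columns=["patch_id", "n_cells", "area_ha",
                                          "occupied"]),
            total_area_ha=0.0, top_shares={k: float("nan") for k in top_k})
    counts = np.bincount(labels.ravel())[1:]
    occupied = np.zeros(n, dtype=bool)
    if observations is not None and len(observations):
        for x, y in np.asarray(observations, dtype=float):
            r, c = mask.grid.cell_of(x, y)
            lab = labels[r, c]
            if lab > 0:
                occupied[lab - 1] = True
    patches = pd.DataFrame({
        "patch_id": np.arange(1, n + 1),
        "n_cells": counts,
        "area_ha": counts * cell_ha,
        "occupied": occupied,
    }).sort_values("area_ha", ascending=False, kind="stable").reset_index(drop=True)
    total = float(patches["area_ha"].sum())
    shares = {k: float(patches["area_ha"].head(k).sum() / total) for k in top_k}
    return PatchTable(patches=patches, total_area_ha=total, top_shares=shares)


@dataclasses.dataclass
class DensityCurve:
    """Kernel-smoothed probability density of a sample of values."""

    x: Optional[np.ndarray]
    density: Optional[np.ndarray]
    mean: float
    se: float
    n: int
    degenerate: bool = False

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        if self.degenerate:
            raise ValueError("degenerate (zero-variance) distribution")
        return np.interp(grid, self.x, self.density, left=0.0, right=0.0)


def value_density_distribution(raster: Raster | np.ndarray,
                               points: Optional[np.ndarray] = None,
                               n_grid: int = 512) -> DensityCurve:
    """Gaussian kernel density (Silverman bandwidth) of raster values.

    Without ``points`` the sample is all non-NA cells (availability);
    with ``points`` it is the raster value at each point's cell (use).
    The returned curve integrates to 1; the mean and SE of the raw
    values are reported alongside.  A zero-variance sample is flagged
    degenerate (spike) instead of smoothed.
    """
    if isinstance(raster, Raster):
        if points is not None:
            pts = np.asarray(points, dtype=float)
            values = np.array([raster.values[raster.grid.cell_of(x, y)]
                               for x, y in pts])
            values = values[np.isfinite(values)]
        else:
            values = raster.values[np.isfinite(raster.values)]
    else:
        values = np.asarray(raster, dtype=float)
        values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("need at least 2 finite values for a distribution")
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(values.size))
    if values.std() == 0.0:
        return DensityCurve(x=None, density=None, mean=mean, se=0.0,
                            n=values.size, degenerate=True)
    kde = stats.gaussian_kde(values, bw_method="silverman")
    h = np.sqrt(kde.covariance[0, 0])
    x = np.linspace(values.min() - 4 * h, values.max() + 4 * h, n_grid)
    return DensityCurve(x=x, density=kde(x), mean=mean, se=se, n=values.size)


def ownership_shares(mask: Raster, ownership: Raster) -> dict:
    """Fraction of available (non-NA) cells per ownership class."""
    _require_aligned(mask, ownership, "ownership_shares")
    avail = np.isfinite(mask.values)
    if not avail.any():
        return {}
    classes = ownership.values[avail]
    uniq, counts = np.unique(classes, return_counts=True)
    total = counts.sum()
    return {int(u) if float(u).is_integer() else float(u): c / total
            for u, c in zip(uniq, counts)}
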