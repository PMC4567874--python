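"""Threat-category occupancy summaries and spatial proximity/overlap
analyses.

Three views of how hypothesised threats relate to where a species
persists:

* per-category naive occupancy rates and shares of occupied sites for a
  categorical threat variable (habitat loss, grazing class, fish status,
  hydroperiod, ...);
* the fraction of focal sites (e.g. breeding locations) lying within
  given distances of threat features (invasive-species observations,
  pathogen records, predator-occupied stream segments);
* kernel-density overlap of species along environmental gradients
  (shoreline density, temperature, precipitation), quantified with the
  overlap coefficient ∫ min(f, g) of the two normalised densities.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Mapping, Sequence
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from .landscape import DensityCurve, Raster, value_density_distribution

__all__ = [
    "CategorySummary",
    "category_occupancy",
    "ProximityResult",
    "proximity_fractions",
    "overlap_coefficient",
    "GradientOverlap",
    "gradient_overlap",
]


@dataclasses.dataclass
class CategorySummary:
    """Per-category occupancy summary for one threat variable.

    ``table`` columns: category, n, n_occupied, rate, share.  ``rate``
    is the category's naive occupancy rate (habitat use relative to
    availability); ``share`` is the category's fraction of all occupied
    sites (where the species persists in the current landscape).
    """

    variable: str
    table: pd.DataFrame
    n_missing: int

    @property
    def total_occupied(self) -> int:
        return int(self.table["n_occupied"].sum())


def category_occupancy(table: pd.DataFrame, variable: str) -> CategorySummary:
    """Naive occupancy rate and occupied-site share per category.

    Rows with a missing category value are excluded and counted, so the
    effective sample size varies with the threat variable analysed.
    Shares are NA when no site is occupied.
    """
    sub = table[[variable, "occupancy"]]
    n_missing = int(sub[variable].isna().sum())
    sub = sub.dropna(subset=[variable])
    grouped = sub.groupby(variable, sort=True)["occupancy"]
    out = pd.DataFrame({
        "category": list(grouped.groups),
        "n": grouped.size().to_numpy(),
        "n_occupied": grouped.sum().to_numpy().astype(int),
    })
    out["rate"] = out["n_occupied"] / out["n"]
    total_occ = out["n_occupied"].sum()
    out["share"] = out["n_occupied"] / total_occ if total_occ > 0 else np.nan
    return CategorySummary(variable=variable, table=out, n_missing=n_missing)


@dataclasses.dataclass
class ProximityResult:
    """Fractions of focal points within each radius of any reference
    feature (non-decreasing in radius by construction)."""

    radii: tuple[float, ...]
    fractions: tuple[float, ...]
    n_focal: int

    def as_dict(self) -> dict:
        return dict(zip(self.radii, self.fractions))


def _as_geometries(geoms) -> list:
    out = []
    for g in geoms:
        if hasattr(g, "distance"):
            out.append(g)
        else:
            arr = np.asarray(g, dtype=float)
            if arr.ndim == 1:
                out.append(Point(arr))
            else:
                out.append(LineString(arr))
    return out


def proximity_fractions(focal_points, reference_geometries,
                        radii: Sequence[float]) -> ProximityResult:
    """Fraction of focal points within each distance of the references.

    Distances are exact planar point-to-geometry distances (perpendicular
    or endpoint distance for polylines).  An empty reference set gives
    fraction 0 at every radius.
    """
    radii = tuple(float(r) for r in radii)
    if any(b < a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be sorted ascending")
    focal = [p if isinstance(p, Point) else Point(np.asarray(p, dtype=float))
             for p in focal_points]
    refs = _as_geometries(reference_geometries)
    n = len(focal)
    if not refs or n == 0:
        return ProximityResult(radii, tuple(0.0 for _ in radii), n)
    mins = np.array([min(ref.distance(pt) for ref in refs) for pt in focal])
    fracs = tuple(float((mins <= r).mean()) for r in radii)
    return ProximityResult(radii, fracs, n)


def overlap_coefficient(a: DensityCurve, b: DensityCurve,
                        n_grid: int = 2048) -> float:
    """Overlap coefficient ∫ min(f, g) of two smoothed densities, in [0, 1]."""
    if a.degenerate or b.degenerate:
        raise ValueError("overlap undefined for a degenerate distribution")
    lo = min(a.x.min(), b.x.min())
    hi = max(a.x.max(), b.x.max())
    grid = np.linspace(lo, hi, n_grid)
    fa = a.evaluate(grid)
    fb = b.evaluate(grid)
    return float(np.trapezoid(np.minimum(fa, fb), grid))


@dataclasses.dataclass
class GradientOverlap:
    """Per-species densities along one gradient plus pairwise overlaps."""

    gradient: str
    curves: dict[str, DensityCurve]
    overlaps: dict[tuple[str, str], float]


def gradient_overlap(
    point_sets: Mapping[str, np.ndarray],
    gradients: Mapping[str, Raster],
) -> dict[str, GradientOverlap]:
    """Compare species' distributions along environmental gradients.

    Each gradient raster is sampled at every species' point locations;
    per-species kernel densities are built and all pairwise overlap
    coefficients computed.  Species with fewer than 2 points are skipped
    with a warning.
    """
    usable = {}
    for sp, pts in point_sets.items():
        pts = np.asarray(pts, dtype=float)
        if len(pts) < 2:
            warnings.warn(f"species {sp!r} has fewer than 2 points; skipped")
            continue
        usable[sp] = pts
    out: dict[str, GradientOverlap] = {}
    for gname, raster in gradients.items():
        curves = {sp: value_density_distribution(raster, points=pts)
                  for sp, pts in usable.items()}
        overlaps = {}
        species = sorted(curves)
        for i, a in enumerate(species):
            for b in species[i + 1:]:
                if curves[a].degenerate or curves[b].degenerate:
                    continue
                overlaps[(a, b)] = overlap_coefficient(curves[a], curves[b])
        out[gname] = GradientOverlap(gradient=gname, curves=curves,
                                     overlaps=overlaps)
    return out
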