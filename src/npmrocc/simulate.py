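"""Synthetic survey tables and landscapes for occupancy analyses.

Real amphibian survey data of the kind this package analyses (agency
field surveys, hydrography layers) are rarely public, so every
downstream stage is exercised against synthetic inputs whose statistical
structure matches the analysis assumptions:

* occupancy is generated from a *multiplicative* response surface —
  a base rate times Gaussian/sigmoid responses to continuous covariates
  times per-level categorical multipliers — mirroring the multiplicative
  kernel weighting the NPMR estimator assumes;
* landscapes are planar bundles of random-walk stream networks,
  spatially autocorrelated climate-suitability rasters, ownership
  rasters and clustered species observation points.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; the draw order is documented on each
generator so identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .landscape import GridConfig, Raster, rasterize_line_length, moving_window_density

__all__ = [
    "ContinuousEffect",
    "TrueSurface",
    "DatasetProfile",
    "LandscapeConfig",
    "LandscapeBundle",
    "true_occupancy_prob",
    "calibrate_base_rate",
    "generate_survey",
    "generate_landscape",
]


@dataclasses.dataclass(frozen=True)
class ContinuousEffect:
    """One continuous covariate's response: ``gaussian`` (unimodal optimum
    at ``center`` with niche breadth ``width``) or ``sigmoid`` (monotone
    increase through midpoint ``center`` with steepness scale ``width``)."""

    name: str
    shape: str  # "gaussian" | "sigmoid"
    center: float
    width: float

    def __post_init__(self):
        if self.shape not in ("gaussian", "sigmoid"):
            raise ValueError(f"unknown effect shape: {self.shape!r}")
        if not self.width > 0:
            raise ValueError(f"{self.name}: width must be > 0")

    def response(self, x: float) -> float:
        z = (float(x) - self.center) / self.width
        if self.shape == "gaussian":
            return float(np.exp(-0.5 * z * z))
        return float(1.0 / (1.0 + np.exp(-z)))


@dataclasses.dataclass
class TrueSurface:
    """Ground-truth multiplicative occupancy surface.

    Occupancy probability at a covariate point is
    ``base_rate × Π continuous responses × Π categorical multipliers``;
    every factor lies in [0, 1], so the product is a valid probability.
    ``noise_predictors`` names covariates that are drawn but carry no
    effect (for selection/recovery experiments).
    """

    base_rate: float
    continuous_effects: tuple[ContinuousEffect, ...] = ()
    categorical_effects: dict[str, dict] = dataclasses.field(default_factory=dict)
    noise_predictors: tuple[str, ...] = ()

    def __post_init__(self):
        if not 0.0 <= self.base_rate <= 1.0:
            raise ValueError("base_rate must lie in [0, 1]")
        self.continuous_effects = tuple(self.continuous_effects)
        self.noise_predictors = tuple(self.noise_predictors)
        for var, mult in self.categorical_effects.items():
            for level, m in mult.items():
                if not 0.0 <= m <= 1.0:
                    raise ValueError(
                        f"{var}[{level!r}]: multiplier must lie in [0, 1]")

    @property
    def effect_predictors(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.continuous_effects) + tuple(
            self.categorical_effects)


def true_occupancy_prob(covariates: Mapping, surface: TrueSurface) -> float:
    """Occupancy probability at one covariate point under the true surface."""
    p = surface.base_rate
    for eff in surface.continuous_effects:
        if eff.name not in covariates:
            raise KeyError(f"covariates are missing predictor {eff.name!r}")
        p *= eff.response(covariates[eff.name])
    for var, multipliers in surface.categorical_effects.items():
        if var not in covariates:
            raise KeyError(f"covariates are missing predictor {var!r}")
        level = covariates[var]
        if level not in multipliers:
            raise KeyError(f"no multiplier for level {level!r} of {var!r}")
        p *= multipliers[level]
    return float(p)


@dataclasses.dataclass
class DatasetProfile:
    """Sampling profile of one survey dataset.

    ``covariate_distributions`` maps each covariate to a distribution
    spec dict: ``{"kind": "uniform", "low": a, "high": b}``,
    ``{"kind": "lognormal", "mean": m, "sigma": s}`` or
    ``{"kind": "categorical", "freqs": {level: prob, ...}}``
    (frequencies must sum to 1).
    """

    name: str
    n_sites: int
    target_occupancy: float
    covariate_distributions: dict[str, dict]

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 0.0 <= self.target_occupancy <= 1.0:
            raise ValueError("target_occupancy must lie in [0, 1]")
        for name, spec in self.covariate_distributions.items():
            if spec.get("kind") == "categorical":
                total = sum(spec["freqs"].values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"{name}: category frequencies sum to {total}, not 1")


def _draw_covariate(rng: np.random.Generator, spec: dict, n: int) -> np.ndarray:
    kind = spec["kind"]
    if kind == "uniform":
        return rng.uniform(spec["low"], spec["high"], size=n)
    if kind == "lognormal":
        return rng.lognormal(spec["mean"], spec["sigma"], size=n)
    if kind == "categorical":
        levels = sorted(spec["freqs"])
        probs = np.array([spec["freqs"][lv] for lv in levels], dtype=float)
        return rng.choice(np.asarray(levels, dtype=object), size=n, p=probs)
    raise ValueError(f"unknown covariate distribution kind: {kind!r}")


def _multiplier_draws(rng: np.random.Generator, profile: DatasetProfile,
                      surface: TrueSurface, n: int) -> np.ndarray:
    """Effect multiplier (everything except base_rate) for n covariate draws."""
    m = np.ones(n)
    probe = TrueSurface(base_rate=1.0,
                        continuous_effects=surface.continuous_effects,
                        categorical_effects=surface.categorical_effects)
    draws = {name: _draw_covariate(rng, spec, n)
             for name, spec in profile.covariate_distributions.items()
             if name in probe.effect_predictors}
    for name in probe.effect_predictors:
        if name not in draws:
            raise ValueError(f"profile does not cover surface predictor {name!r}")
    for i in range(n):
        m[i] = true_occupancy_prob({k: v[i] for k, v in draws.items()}, probe)
    return m


def calibrate_base_rate(profile: DatasetProfile, surface: TrueSurface,
                        rng: np.random.Generator, n_mc: int = 10_000,
                        tol: float = 0.01) -> float:
    """Base rate making expected occupancy match the profile target.

    The expectation is taken over ``n_mc`` Monte Carlo covariate draws;
    the base rate is found by bisection on [0, 1] to within ``tol`` of
    the target.  Raises when the target is unreachable (the mean effect
    multiplier is too small for any base rate in [0, 1]).
    """
    target = profile.target_occupancy
    if target == 0.0:
        return 0.0
    mean_mult = _multiplier_draws(rng, profile, surface, n_mc).mean()
    if mean_mult < target - tol:
        raise ValueError(
            f"target occupancy {target} unreachable: maximum attainable "
            f"expected occupancy is {mean_mult:.3f}")
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if mid * mean_mult < target:
            lo = mid
        else:
            hi = mid
    return min(1.0, 0.5 * (lo + hi))


def generate_survey(profile: DatasetProfile, surface: TrueSurface,
                    seed: int) -> pd.DataFrame:
    """Generate one synthetic survey table.

    Draw order from the seed: (1) base-rate calibration Monte Carlo,
    (2) site covariates in the profile's declaration order,
    (3) Bernoulli occupancy.  Identical seed ⇒ identical table.
    """
    rng = np.random.default_rng(seed)
    base = calibrate_base_rate(profile, surface, rng)
    calibrated = dataclasses.replace(surface, base_rate=base)
    n = profile.n_sites
    data: dict[str, np.ndarray] = {}
    for name, spec in profile.covariate_distributions.items():
        data[name] = _draw_covariate(rng, spec, n)
    probs = np.array([
        true_occupancy_prob({k: v[i] for k, v in data.items()}, calibrated)
        for i in range(n)
    ])
    occupancy = (rng.uniform(size=n) < probs).astype(int)
    out = pd.DataFrame({"site_id": [f"{profile.name}-{i:04d}" for i in range(n)],
                        "occupancy": occupancy})
    for name, vals in data.items():
        out[name] = vals
    out.attrs["dataset"] = profile.name
    out.attrs["base_rate"] = base
    return out


# ---------------------------------------------------------------------------
# landscape generation


@dataclasses.dataclass
class LandscapeConfig:
    """Configuration of a synthetic planar landscape (coordinates in km).

    ``total_stream_length`` is the requested summed polyline length;
    ``observation_counts`` maps species name to number of observation
    points; ``preference_weight`` ≥ 0 biases observation placement
    toward cells of high shoreline density (0 = uniform over the extent).
    """

    extent: tuple[float, float] = (54.0, 54.0)
    cell_size: float = 0.27
    window_radius: float = 5.0
    total_stream_length: float = 150.0
    stream_step: float = 0.5
    stream_turn_sd: float = 0.5
    suitability_smooth: float = 6.0
    suitability_skew: float = 3.0
    n_owner_classes: int = 3
    owner_labels: tuple[str, ...] = ("BLM", "USFS", "private", "state")
    observation_counts: dict[str, int] = dataclasses.field(default_factory=dict)
    preference_weight: float = 2.0

    def __post_init__(self):
        if self.cell_size <= 0 or min(self.extent) <= 0:
            raise ValueError("cell size and extent must be positive")
        if self.n_owner_classes < 3:
            raise ValueError("need at least 3 ownership classes")

    def grid(self) -> GridConfig:
        ncols = int(round(self.extent[0] / self.cell_size))
        nrows = int(round(self.extent[1] / self.cell_size))
        return GridConfig(origin=(0.0, 0.0), shape=(nrows, ncols),
                          cell_size=self.cell_size,
                          window_radius=self.window_radius)


@dataclasses.dataclass
class LandscapeBundle:
    """Streams + aligned rasters + species observations on one grid."""

    grid: GridConfig
    streams: list[np.ndarray]            # (k, 2) coordinate arrays, km
    suitability: Raster                  # values in [0, 1]
    ownership: Raster                    # integer class codes
    owner_labels: tuple[str, ...]
    observations: dict[str, np.ndarray]  # species -> (m, 2) points


def _random_walk_streams(rng: np.random.Generator, config: LandscapeConfig
                         ) -> list[np.ndarray]:
    """Correlated random walks, reflected at the extent boundary, built
    until the summed length equals the request (last step trimmed)."""
    w, h = config.extent
    target = config.total_stream_length
    streams: list[np.ndarray] = []
    total = 0.0
    while total < target - 1e-9:
        pts = [rng.uniform((0, 0), (w, h))]
        heading = rng.uniform(0, 2 * np.pi)
        length = 0.0
        reach = min(target - total, rng.uniform(0.2, 0.6) * target)
        while length < reach - 1e-9:
            step = min(config.stream_step, reach - length)
            heading += rng.normal(0.0, config.stream_turn_sd)
            nxt = pts[-1] + step * np.array([np.cos(heading), np.sin(heading)])
            # reflect at boundaries to stay inside the extent
            for d, lim in enumerate((w, h)):
                if nxt[d] < 0:
                    nxt[d] = -nxt[d]
                    heading += np.pi / 2
                elif nxt[d] > lim:
                    nxt[d] = 2 * lim - nxt[d]
                    heading += np.pi / 2
            nxt = np.clip(nxt, [0, 0], [w, h])
            actual = float(np.linalg.norm(nxt - pts[-1]))
            if actual < 1e-12:
                continue
            pts.append(nxt)
            length += actual
        if len(pts) > 1:
            streams.append(np.asarray(pts))
            total += length
    return streams


def _smoothed_field(rng: np.random.Generator, shape: tuple[int, int],
                    sigma: float) -> np.ndarray:
    noise = rng.normal(size=shape)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    lo, hi = smooth.min(), smooth.max()
    return (smooth - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def generate_landscape(config: LandscapeConfig, seed: int) -> LandscapeBundle:
    """Generate a synthetic landscape bundle.

    Draw order from the seed: (1) stream random walks, (2) suitability
    noise field, (3) ownership noise fields, (4) observation points per
    species in the declaration order of ``observation_counts``.
    """
    if config.total_stream_length <= 0 and config.preference_weight > 0 and any(
            n > 0 for n in config.observation_counts.values()):
        raise ValueError("observations prefer shoreline but the requested "
                         "stream length is 0")
    rng = np.random.default_rng(seed)
    grid = config.grid()
    streams = _random_walk_streams(rng, config) if config.total_stream_length > 0 else []
    # raising the normalised field to a power right-skews it, mimicking
    # climate-suitability surfaces that are low over most of the extent
    suitability = Raster(grid, _smoothed_field(rng, grid.shape,
                                               config.suitability_smooth)
                         ** config.suitability_skew)
    fields = np.stack([_smoothed_field(rng, grid.shape, config.suitability_smooth)
                       for _ in range(config.n_owner_classes)])
    ownership = Raster(grid, np.argmax(fields, axis=0).astype(float))
    labels = tuple(config.owner_labels[: config.n_owner_classes])

    density = None
    if streams and config.preference_weight > 0:
        lengths = rasterize_line_length(streams, grid)
        density = moving_window_density(lengths, grid)

    observations: dict[str, np.ndarray] = {}
    nrows, ncols = grid.shape
    for species, count in config.observation_counts.items():
        if count == 0:
            observations[species] = np.empty((0, 2))
            continue
        if density is None or config.preference_weight == 0:
            probs = np.full(nrows * ncols, 1.0 / (nrows * ncols))
        else:
            weights = 1.0 + config.preference_weight * (
                density.values / max(density.values.mean(), 1e-12))
            probs = (weights / weights.sum()).ravel()
        cells = rng.choice(nrows * ncols, size=count, p=probs)
        rows, cols = np.divmod(cells, ncols)
        offs = rng.uniform(size=(count, 2))
        xs = grid.origin[0] + (cols + offs[:, 0]) * grid.cell_size
        ys = grid.origin[1] + (rows + offs[:, 1]) * grid.cell_size
        observations[species] = np.column_stack([xs, ys])
    return LandscapeBundle(grid=grid, streams=streams, suitability=suitability,
                           ownership=ownership, owner_labels=labels,
                           observations=observations)
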