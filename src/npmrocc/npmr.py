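"""Kernel-weighted local-mean occupancy estimation (NPMR core).

Nonparametric multiplicative regression (NPMR) estimates the probability
that a species occupies a site as the kernel-weighted mean of binary
presence/absence responses in the site's *environmental* neighbourhood:
the weight of observation *k* for a target point is the product, over the
model's predictors, of a Gaussian kernel (continuous predictors) or an
exact-match indicator (categorical predictors).  Multiplicative weighting
encodes Shelford's law of tolerance: unsuitability along any single axis
drives the weight — and hence the local occupancy estimate's support —
to zero.

Model fit is measured by ``loo_log_beta``, the base-10 log likelihood
ratio of the model over the naive model (the overall occupancy rate),
computed under leave-one-out cross-validation so that adding predictors
is only rewarded when they genuinely generalise.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "PredictorSpec",
    "NPMRModel",
    "infer_specs",
    "kernel_weight",
    "weight_matrix",
    "target_weights",
    "local_mean_estimate",
    "loo_predictions",
    "loo_log_beta",
    "neighborhood_size",
    "naive_rate",
]

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclasses.dataclass(frozen=True)
class PredictorSpec:
    """Description of a single habitat predictor.

    Parameters
    ----------
    name:
        Column name in the survey table.
    kind:
        ``"continuous"`` or ``"categorical"``.
    observed_range:
        ``(min, max)`` of the observed values; required for continuous
        predictors (tolerances are expressed as fractions of this range).
    levels:
        Category levels; required for categorical predictors.
    """

    name: str
    kind: str
    observed_range: Optional[tuple[float, float]] = None
    levels: Optional[tuple] = None

    def __post_init__(self):
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise ValueError(f"unknown predictor kind: {self.kind!r}")
        if self.kind == CONTINUOUS and self.observed_range is not None:
            lo, hi = self.observed_range
            if not lo < hi:
                raise ValueError(
                    f"{self.name}: observed_range must satisfy min < max"
                )
        if self.kind == CATEGORICAL and self.levels is not None:
            if len(self.levels) < 2:
                raise ValueError(f"{self.name}: need at least 2 levels")

    @property
    def range_width(self) -> float:
        if self.observed_range is None:
            raise ValueError(f"{self.name}: no observed_range recorded")
        return self.observed_range[1] - self.observed_range[0]


@dataclasses.dataclass
class NPMRModel:
    """A predictor subset with per-predictor Gaussian tolerances.

    ``tolerances`` maps each *continuous* predictor in the subset to the
    standard deviation of its Gaussian weighting kernel (same units as
    the predictor); ecologically the tolerance is the niche breadth along
    that axis.  Categorical predictors carry no tolerance — their kernel
    is an exact-match indicator.  ``min_neighborhood`` is the minimum
    summed weight below which an estimate is considered unreliable and
    reported as NA.
    """

    predictors: tuple[str, ...] = ()
    tolerances: dict[str, float] = dataclasses.field(default_factory=dict)
    min_neighborhood: float = 1.0

    def __post_init__(self):
        self.predictors = tuple(self.predictors)
        for name, tol in self.tolerances.items():
            if name not in self.predictors:
                raise ValueError(f"tolerance for {name!r} not in predictor subset")
            if not tol > 0:
                raise ValueError(f"tolerance for {name!r} must be > 0")

    @property
    def size(self) -> int:
        return len(self.predictors)


def infer_specs(table: pd.DataFrame, columns) -> dict[str, PredictorSpec]:
    """Build :class:`PredictorSpec` objects from a survey table.

    Numeric columns become continuous predictors with their observed
    range; everything else becomes categorical with the observed levels.
    """
    specs: dict[str, PredictorSpec] = {}
    for name in columns:
        col = table[name]
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            vals = col.dropna().to_numpy(dtype=float)
            if vals.size == 0:
                raise ValueError(f"column {name!r} has no observed values")
            lo, hi = float(vals.min()), float(vals.max())
            specs[name] = PredictorSpec(name, CONTINUOUS, observed_range=(lo, hi))
        else:
            levels = tuple(sorted(col.dropna().unique().tolist()))
            specs[name] = PredictorSpec(name, CATEGORICAL, levels=levels)
    return specs


def naive_rate(table: pd.DataFrame) -> float:
    """Naive occupancy rate: fraction of surveyed sites with a detection."""
    return float(np.asarray(table["occupancy"], dtype=float).mean())


def kernel_weight(target_value, obs_value, spec: PredictorSpec, tolerance=None):
    """Weight of a single observation along a single predictor.

    Continuous: ``exp(-(target - obs)^2 / (2 tolerance^2))``.
    Categorical: 1 on an exact level match, else 0.
    A missing observed value contributes weight 0.
    """
    if spec.kind == CONTINUOUS:
        if tolerance is None or not tolerance > 0:
            raise ValueError(f"{spec.name}: tolerance must be > 0")
        if obs_value is None or (isinstance(obs_value, float) and np.isnan(obs_value)):
            return 0.0
        d = float(target_value) - float(obs_value)
        return float(np.exp(-(d * d) / (2.0 * tolerance * tolerance)))
    # categorical
    if obs_value is None or (isinstance(obs_value, float) and np.isnan(obs_value)):
        return 0.0
    return 1.0 if obs_value == target_value else 0.0


def _column_weights(
    targets: np.ndarray, obs: np.ndarray, spec: PredictorSpec, tolerance
) -> np.ndarray:
    """Vectorised kernel weights: targets (m,) x observations (n,) -> (m, n)."""
    if spec.kind == CONTINUOUS:
        if tolerance is None or not tolerance > 0:
            raise ValueError(f"{spec.name}: tolerance must be > 0")
        t = np.asarray(targets, dtype=float)[:, None]
        o = np.asarray(obs, dtype=float)[None, :]
        w = np.exp(-((t - o) ** 2) / (2.0 * tolerance * tolerance))
        w[np.isnan(w)] = 0.0  # missing on either side
        return w
    t = np.asarray(targets, dtype=object)[:, None]
    o = np.asarray(obs, dtype=object)[None, :]
    w = (t == o).astype(float)
    # pandas missing values never match anything (NaN == NaN is False for
    # floats but object arrays need the explicit mask)
    miss = pd.isna(np.asarray(obs, dtype=object))[None, :]
    w[np.broadcast_to(miss, w.shape)] = 0.0
    return w


def weight_matrix(
    table: pd.DataFrame, model: NPMRModel, specs: Mapping[str, PredictorSpec]
) -> np.ndarray:
    """(n, n) matrix of multiplicative kernel weights between table rows.

    ``W[i, k]`` weights row *k* when estimating occupancy at row *i*'s
    covariate point.  A row missing any model predictor gets weight 0 as
    an observation for every target needing that predictor.
    """
    n = len(table)
    W = np.ones((n, n), dtype=float)
    for name in model.predictors:
        spec = specs[name]
        col = table[name].to_numpy()
        W *= _column_weights(col, col, spec, model.tolerances.get(name))
    return W


def target_weights(
    target: Mapping,
    table: pd.DataFrame,
    model: NPMRModel,
    specs: Mapping[str, PredictorSpec],
) -> np.ndarray:
    """(n,) kernel weights of the table rows for one arbitrary target point."""
    n = len(table)
    w = np.ones(n, dtype=float)
    for name in model.predictors:
        if name not in target:
            raise KeyError(f"target point is missing model predictor {name!r}")
        spec = specs[name]
        col = table[name].to_numpy()
        w *= _column_weights(np.asarray([target[name]], dtype=object), col, spec,
                             model.tolerances.get(name))[0]
    return w


def local_mean_estimate(
    target: Mapping,
    table: pd.DataFrame,
    model: NPMRModel,
    specs: Mapping[str, PredictorSpec],
    exclude_site=None,
) -> float:
    """Kernel-weighted mean occupancy at a target covariate point.

    Returns NaN when the summed weight of contributing rows falls below
    ``model.min_neighborhood`` — too few data in the target's region of
    predictor space to trust the estimate.
    """
    if len(table) == 0:
        raise ValueError("survey table is empty")
    w = target_weights(target, table, model, specs)
    y = np.asarray(table["occupancy"], dtype=float)
    if exclude_site is not None:
        keep = (table["site_id"] != exclude_site).to_numpy()
        w = w * keep
    sw = w.sum()
    if sw < model.min_neighborhood:
        return float("nan")
    return float((w @ y) / sw)


def loo_predictions(
    table: pd.DataFrame,
    model: NPMRModel,
    specs: Mapping[str, PredictorSpec],
    W: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Leave-one-out estimate at every survey row (NaN where unreliable)."""
    if len(table) == 0:
        raise ValueError("survey table is empty")
    y = np.asarray(table["occupancy"], dtype=float)
    if model.size == 0:
        # naive model: without covariates the LOO estimate at each row is
        # the occupancy rate of the remaining rows
        n = len(y)
        return (y.sum() - y) / (n - 1) if n > 1 else np.full(n, np.nan)
    if W is None:
        W = weight_matrix(table, model, specs)
    diag = np.diag(W).copy()
    sw = W.sum(axis=1) - diag
    num = W @ y - diag * y
    with np.errstate(invalid="ignore", divide="ignore"):
        est = num / sw
    est[sw < model.min_neighborhood] = np.nan
    return est


def loo_log_beta(
    table: pd.DataFrame,
    model: NPMRModel,
    specs: Mapping[str, PredictorSpec],
    epsilon: float = 1e-3,
    W: Optional[np.ndarray] = None,
) -> float:
    """Leave-one-out log likelihood ratio over the naive model (powers of 10).

    For each row the model's LOO estimate is compared, in base-10
    log-likelihood, with the overall occupancy rate.  Rows whose estimate
    is NA (neighbourhood too sparse) fall back to the naive rate and so
    contribute zero improvement.  Estimates are clamped to
    ``[epsilon, 1 - epsilon]`` before taking logs.
    """
    y = np.asarray(table["occupancy"], dtype=float)
    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        raise ValueError("naive occupancy rate is degenerate (0 or 1); "
                         "log beta is undefined")
    if model.size == 0:
        return 0.0
    phat = loo_predictions(table, model, specs, W=W)
    phat = np.where(np.isnan(phat), ybar, phat)
    phat = np.clip(phat, epsilon, 1.0 - epsilon)
    ll_model = np.sum(y * np.log10(phat) + (1.0 - y) * np.log10(1.0 - phat))
    ll_naive = np.sum(y * np.log10(ybar) + (1.0 - y) * np.log10(1.0 - ybar))
    return float(ll_model - ll_naive)


def neighborhood_size(
    table: pd.DataFrame,
    model: NPMRModel,
    specs: Mapping[str, PredictorSpec],
    W: Optional[np.ndarray] = None,
) -> float:
    """Average neighbourhood size N*.

    Mean, over rows, of the summed kernel weight of all *other* rows —
    the average number of sample units effectively contributing to each
    leave-one-out estimate.
    """
    if len(table) == 0:
        raise ValueError("survey table is empty")
    if model.size == 0:
        return float(len(table) - 1)
    if W is None:
        W = weight_matrix(table, model, specs)
    sw = W.sum(axis=1) - np.diag(W)
    return float(sw.mean())
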