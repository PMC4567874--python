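"""Free search over predictor subsets and tolerance grids, with
overfitting controls and resampling inference.

The search mimics how practitioners fit NPMR occupancy models: for each
model size *p* it finds the predictor subset and per-predictor tolerance
combination maximising the leave-one-out log likelihood ratio (logβ),
subject to a minimum average neighbourhood size and a minimum
data-to-predictor ratio.  The final model is the largest *p* whose fit
improves on the next-smaller best model by at least a relative
``improvement_threshold`` (default 2.5%).

Inference on the selected model uses
* bootstrap resampling (rows resampled with replacement; fit statistics
  recomputed with the model's form and tolerances held fixed), and
* a Monte Carlo randomisation test (response shuffled; free search rerun
  at the selected model size) for the null hypothesis that the fit is no
  better than chance.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from collections.abc import Mapping, Sequence
from typing import Optional

import numpy as np
import pandas as pd

from .npmr import (
    CATEGORICAL,
    CONTINUOUS,
    NPMRModel,
    PredictorSpec,
    loo_log_beta,
    loo_predictions,
    neighborhood_size,
    weight_matrix,
)

__all__ = [
    "SearchControls",
    "LadderEntry",
    "free_search",
    "select_final",
    "bootstrap_logbeta",
    "monte_carlo_test",
    "sensitivity",
    "BootstrapResult",
]

_DEFAULT_GRID = tuple(round(0.05 * i, 2) for i in range(1, 21))


@dataclasses.dataclass
class SearchControls:
    """Knobs of the free search.

    ``tolerance_grid_levels`` are fractions of each continuous
    predictor's observed range (default 5%..100% in 5% steps).
    ``min_data_per_predictor`` caps model size at n / that ratio;
    ``min_avg_neighborhood`` discards candidate models whose average
    neighbourhood size N* falls below it.  ``max_exhaustive_combos``
    bounds the factorial tolerance grid per subset; larger grids are
    optimised by deterministic coordinate descent on the same grid.
    """

    tolerance_grid_levels: tuple[float, ...] = _DEFAULT_GRID
    max_predictors: int = 5
    min_avg_neighborhood: float = 1.0
    min_data_per_predictor: float = 10.0
    improvement_threshold: float = 0.025
    max_exhaustive_combos: int = 400
    epsilon: float = 1e-3
    min_neighborhood: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self):
        levels = tuple(float(v) for v in self.tolerance_grid_levels)
        if not levels or any(not 0 < v <= 1 for v in levels):
            raise ValueError("tolerance grid levels must lie in (0, 1]")
        self.tolerance_grid_levels = tuple(sorted(levels))
        if self.improvement_threshold <= 0:
            raise ValueError("improvement_threshold must be > 0")


@dataclasses.dataclass
class LadderEntry:
    """Best model found at one model size, with its fit statistics."""

    size: int
    model: NPMRModel
    log_beta: float
    n_star: float
    tolerance_levels: dict[str, float] = dataclasses.field(default_factory=dict)


class _Engine:
    """Vectorised evaluator: caches per-(predictor, tolerance-level)
    weight matrices in float32 and scores predictor/tolerance combos by
    LOO logβ.  float32 keeps the cache small; the winning models are
    re-scored in float64 for reporting."""

    def __init__(self, table: pd.DataFrame, candidates: Mapping[str, PredictorSpec],
                 controls: SearchControls):
        self.table = table
        self.specs = dict(candidates)
        self.controls = controls
        self.y = np.asarray(table["occupancy"], dtype=np.float32)
        self.ybar = float(self.y.mean())
        self.n = len(table)
        ll_naive = self.n * (self.ybar * np.log10(self.ybar)
                             + (1 - self.ybar) * np.log10(1 - self.ybar))
        self._ll_naive = np.float32(ll_naive)
        self._base: dict[str, np.ndarray] = {}   # categorical match / sq dist
        self._wcache: dict[tuple[str, float], np.ndarray] = {}

    def _base_matrix(self, name: str) -> np.ndarray:
        if name not in self._base:
            spec = self.specs[name]
            col = self.table[name].to_numpy()
            if spec.kind == CONTINUOUS:
                x = np.asarray(col, dtype=np.float32)
                d = x[:, None] - x[None, :]
                m = d * d
                m[np.isnan(m)] = np.inf  # missing -> zero weight at any tolerance
            else:
                o = np.asarray(col, dtype=object)
                m = (o[:, None] == o[None, :]).astype(np.float32)
                miss = pd.isna(o)
                m[miss, :] = 0.0
                m[:, miss] = 0.0
            self._base[name] = m
        return self._base[name]

    def tolerance_for(self, name: str, level: float) -> float:
        return level * self.specs[name].range_width

    def weights(self, name: str, level: Optional[float]) -> np.ndarray:
        spec = self.specs[name]
        if spec.kind == CATEGORICAL:
            return self._base_matrix(name)
        key = (name, float(level))
        if key not in self._wcache:
            tol = self.tolerance_for(name, level)
            with np.errstate(invalid="ignore"):
                w = np.exp(-self._base_matrix(name) / np.float32(2.0 * tol * tol))
            w[~np.isfinite(w)] = 0.0
            self._wcache[key] = w.astype(np.float32)
        return self._wcache[key]

    def evaluate(self, W: np.ndarray) -> tuple[float, float]:
        """(logβ, N*) of a product weight matrix, LOO with NA fallback."""
        diag = np.diagonal(W)
        sw = W.sum(axis=1) - diag
        num = W @ self.y - diag * self.y
        with np.errstate(invalid="ignore", divide="ignore"):
            phat = num / sw
        bad = sw < self.controls.min_neighborhood
        phat = np.where(bad | np.isnan(phat), self.ybar, phat)
        eps = self.controls.epsilon
        phat = np.clip(phat, eps, 1.0 - eps)
        y = self.y
        ll = np.sum(y * np.log10(phat) + (1.0 - y) * np.log10(1.0 - phat))
        return float(ll - self._ll_naive), float(sw.mean())

    def combo_matrix(self, names: Sequence[str], levels: Mapping[str, float]) -> np.ndarray:
        W = None
        for name in names:
            w = self.weights(name, levels.get(name))
            W = w.copy() if W is None else W * w
        return W

    def score(self, names: Sequence[str], levels: Mapping[str, float]) -> tuple[float, float]:
        return self.evaluate(self.combo_matrix(names, levels))


def _is_better(cand: tuple, best: tuple) -> bool:
    """(logβ, N*, names) ordering: higher logβ, then higher N*, then
    lexicographically earlier predictor-name tuple."""
    if best is None:
        return True
    lb_c, ns_c, names_c = cand[:3]
    lb_b, ns_b, names_b = best[:3]
    if lb_c != lb_b:
        return lb_c > lb_b
    if ns_c != ns_b:
        return ns_c > ns_b
    return names_c < names_b


def _best_tolerances(engine: _Engine, names: tuple[str, ...]):
    """Best tolerance-level assignment for one predictor subset.

    Factorial grid when the number of combinations is small enough;
    otherwise deterministic coordinate descent on the grid (start at the
    middle level, sweep predictors in order, prefer larger tolerances on
    ties, iterate to a fixed point)."""
    controls = engine.controls
    grid = controls.tolerance_grid_levels
    cont = [n for n in names if engine.specs[n].kind == CONTINUOUS]
    if not cont:
        lb, ns = engine.score(names, {})
        return {}, lb, ns
    n_combos = len(grid) ** len(cont)
    best = None  # (logβ, N*, levels)
    if n_combos <= controls.max_exhaustive_combos:
        for combo in itertools.product(grid, repeat=len(cont)):
            levels = dict(zip(cont, combo))
            lb, ns = engine.score(names, levels)
            if best is None or (lb, ns) > (best[0], best[1]):
                best = (lb, ns, levels)
    else:
        mid = grid[len(grid) // 2]
        levels = {n: mid for n in cont}
        lb, ns = engine.score(names, levels)
        best = (lb, ns, dict(levels))
        for _ in range(5):
            changed = False
            for name in cont:
                others = {k: v for k, v in levels.items() if k != name}
                local = None
                for lev in grid:  # ascending; >= keeps the larger tolerance on ties
                    cand_levels = {**others, name: lev}
                    lb, ns = engine.score(names, cand_levels)
                    if local is None or (lb, ns) >= (local[0], local[1]):
                        local = (lb, ns, lev)
                if local[2] != levels[name]:
                    changed = True
                levels[name] = local[2]
                if (local[0], local[1]) > (best[0], best[1]):
                    best = (local[0], local[1], dict(levels))
            if not changed:
                break
    return best[2], best[0], best[1]


def _entry_from(engine: _Engine, names: tuple[str, ...], levels: Mapping[str, float],
                controls: SearchControls) -> LadderEntry:
    tolerances = {n: engine.tolerance_for(n, lev) for n, lev in levels.items()}
    model = NPMRModel(predictors=names, tolerances=tolerances,
                      min_neighborhood=controls.min_neighborhood)
    # re-score in float64 for reporting
    W = weight_matrix(engine.table, model, engine.specs)
    lb = loo_log_beta(engine.table, model, engine.specs,
                      epsilon=controls.epsilon, W=W)
    ns = neighborhood_size(engine.table, model, engine.specs, W=W)
    return LadderEntry(size=len(names), model=model, log_beta=lb, n_star=ns,
                       tolerance_levels=dict(levels))


def free_search(
    table: pd.DataFrame,
    candidates: Mapping[str, PredictorSpec] | Sequence[PredictorSpec],
    controls: Optional[SearchControls] = None,
    sizes: Optional[Sequence[int]] = None,
) -> list[LadderEntry]:
    """Best model per size p = 0..max_predictors (the model "ladder").

    Subsets are enumerated exhaustively for p ≤ 3 and grown greedily from
    the best smaller model beyond that (the added predictor's tolerance
    is optimised on the grid; the base model's tolerances are kept).
    Models violating the minimum average neighbourhood size or the
    data-to-predictor ratio are discarded.  Ties are broken by higher N*
    then lexicographic predictor names, so the result is deterministic.
    """
    controls = controls or SearchControls()
    if not isinstance(candidates, Mapping):
        candidates = {s.name: s for s in candidates}
    engine = _Engine(table, candidates, controls)
    n = len(table)
    naive = LadderEntry(
        size=0,
        model=NPMRModel(min_neighborhood=controls.min_neighborhood),
        log_beta=0.0,
        n_star=float(n - 1),
    )
    ladder = [naive]
    max_p = min(controls.max_predictors, len(candidates),
                int(n // controls.min_data_per_predictor))
    if sizes is not None:
        max_p = min(max_p, max(sizes, default=0))
    names_sorted = tuple(sorted(candidates))
    best_by_size: dict[int, tuple] = {}  # size -> (logβ32, N*, names, levels)

    for p in range(1, max_p + 1):
        best = None
        if p <= 3:
            subsets = itertools.combinations(names_sorted, p)
        else:
            prev = best_by_size.get(p - 1)
            if prev is None:
                break
            base_names = prev[2]
            subsets = (tuple(sorted(base_names + (extra,)))
                       for extra in names_sorted if extra not in base_names)
        for names in subsets:
            if p <= 3:
                levels, lb, ns = _best_tolerances(engine, names)
            else:
                base_levels = best_by_size[p - 1][3]
                extra = next(n_ for n_ in names if n_ not in best_by_size[p - 1][2])
                if engine.specs[extra].kind == CONTINUOUS:
                    local = None
                    for lev in controls.tolerance_grid_levels:
                        cand = {**base_levels, extra: lev}
                        lb, ns = engine.score(names, cand)
                        if local is None or (lb, ns) >= (local[0], local[1]):
                            local = (lb, ns, cand)
                    lb, ns, levels = local
                else:
                    levels = dict(base_levels)
                    lb, ns = engine.score(names, levels)
            if ns < controls.min_avg_neighborhood:
                continue
            if _is_better((lb, ns, names), best):
                best = (lb, ns, names, levels)
        if best is None:
            break
        best_by_size[p] = best
        ladder.append(_entry_from(engine, best[2], best[3], controls))
    if sizes is not None:
        ladder = [e for e in ladder if e.size in set(sizes) | {0}]
    return ladder


def select_final(ladder: Sequence[LadderEntry],
                 improvement_threshold: float = 0.025) -> LadderEntry:
    """Apply the stepwise ≥2.5% improvement rule to a model ladder.

    Returns the entry at the largest size p such that every step up to p
    improves logβ by at least the relative threshold over the best model
    one size smaller (the p=1 step additionally requires logβ > 0).
    Falls back to the naive (size-0) entry when no step qualifies.
    """
    by_size = {e.size: e for e in ladder}
    selected = by_size[0]
    prev_lb = 0.0
    p = 1
    while p in by_size:
        lb = by_size[p].log_beta
        if p == 1:
            ok = lb > 0
        else:
            ok = lb >= (1.0 + improvement_threshold) * prev_lb
        if not ok:
            break
        selected = by_size[p]
        prev_lb = lb
        p += 1
    return selected


@dataclasses.dataclass
class BootstrapResult:
    mean: float
    se: float
    n_boot: int
    n_redrawn: int = 0


def bootstrap_logbeta(
    table: pd.DataFrame,
    model: NPMRModel,
    specs: Mapping[str, PredictorSpec],
    n_boot: int = 100,
    seed: Optional[int] = None,
    epsilon: float = 1e-3,
) -> BootstrapResult:
    """Bootstrap the LOO logβ of a fixed model.

    Rows are resampled with replacement (same n); each resample's logβ is
    computed against the resample's own naive rate with the model's form
    and tolerances held fixed.  Degenerate resamples (all-0 or all-1
    response) are redrawn and counted.  SE is the standard deviation of
    the replicate values.
    """
    rng = np.random.default_rng(seed)
    n = len(table)
    y = np.asarray(table["occupancy"], dtype=float)
    if y.min() == y.max():
        raise ValueError("constant response: bootstrap logβ undefined")
    values = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if 0.0 < y[idx].mean() < 1.0:
                break
            n_redrawn += 1
        sub = table.iloc[idx].reset_index(drop=True)
        values[b] = loo_log_beta(sub, model, specs, epsilon=epsilon)
    return BootstrapResult(
        mean=float(values.mean()),
        se=float(values.std(ddof=1)),
        n_boot=n_boot,
        n_redrawn=n_redrawn,
    )


def monte_carlo_test(
    table: pd.DataFrame,
    candidates: Mapping[str, PredictorSpec],
    controls: SearchControls,
    observed_logbeta: float,
    size: int,
    n_perm: int = 100,
    seed: Optional[int] = None,
) -> float:
    """Monte Carlo randomisation p-value for a selected model's fit.

    The response is shuffled ``n_perm`` times; each time the free search
    is rerun restricted to the selected model's size and the best logβ
    recorded.  p = (1 + #{null ≥ observed}) / (n_perm + 1), so p is never
    exactly zero.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(table["occupancy"]).copy()
    exceed = 0
    for _ in range(n_perm):
        shuffled = table.copy()
        shuffled["occupancy"] = rng.permutation(y)
        if size == 0:
            null_lb = 0.0
        else:
            ladder = free_search(shuffled, candidates, controls, sizes=[size])
            entries = [e for e in ladder if e.size == size]
            null_lb = entries[0].log_beta if entries else 0.0
        if null_lb >= observed_logbeta:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


def sensitivity(
    table: pd.DataFrame,
    model: NPMRModel,
    specs: Mapping[str, PredictorSpec],
    predictor: str,
) -> float:
    """Relative importance of a continuous predictor in a fitted model.

    Each row's value of the predictor is nudged by ±5% of the
    predictor's observed range and the model's LOO estimate at that row
    recomputed; sensitivity is the mean absolute change in the estimate
    over both directions and all rows, divided by 5% of the response
    range (1 for binary occupancy).  A value of 1 means a ±5% nudge
    moves the estimate by 5% on average.
    """
    if predictor not in model.predictors:
        warnings.warn(f"predictor {predictor!r} is not in the model; sensitivity 0")
        return 0.0
    spec = specs[predictor]
    if spec.kind != CONTINUOUS:
        raise ValueError("sensitivity is defined for continuous predictors only")
    delta = 0.05 * spec.range_width
    y = np.asarray(table["occupancy"], dtype=float)

    # weights from all predictors except the perturbed one
    others = NPMRModel(
        predictors=tuple(p for p in model.predictors if p != predictor),
        tolerances={k: v for k, v in model.tolerances.items() if k != predictor},
        min_neighborhood=model.min_neighborhood,
    )
    W_others = weight_matrix(table, others, specs)
    x = np.asarray(table[predictor], dtype=float)
    tol = model.tolerances[predictor]

    def loo_est(shift: float) -> np.ndarray:
        t = (x + shift)[:, None]
        with np.errstate(invalid="ignore"):
            wp = np.exp(-((t - x[None, :]) ** 2) / (2.0 * tol * tol))
        wp[np.isnan(wp)] = 0.0
        W = W_others * wp
        diag = np.diag(W).copy()
        sw = W.sum(axis=1) - diag
        with np.errstate(invalid="ignore", divide="ignore"):
            est = (W @ y - diag * y) / sw
        est[sw < model.min_neighborhood] = np.nan
        return est

    base = loo_est(0.0)
    up = loo_est(delta)
    down = loo_est(-delta)
    diffs = np.concatenate([np.abs(up - base), np.abs(down - base)])
    diffs = diffs[~np.isnan(diffs)]
    if diffs.size == 0:
        return 0.0
    return float(diffs.mean() / 0.05)
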