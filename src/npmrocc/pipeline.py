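"""Per-dataset orchestration: predictor screening, model fitting and the
reporting surfaces built on a fitted NPMR occupancy model.

``fit_dataset`` chains the full analysis for one survey table:
correlation screening of candidate predictors, free search over subsets
and tolerances, stepwise selection, bootstrap stability, a Monte Carlo
randomisation test and per-predictor sensitivities/tolerances — bundled
into a :class:`FitReport`.  ``predict_by_group`` and
``response_profile`` turn a fitted model into the two standard views of
an occupancy surface: average modelled occupancy per habitat class
(with Duncan's multiple-range letter groups) and the modelled response
along one predictor with the others held at a fixed context.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from collections.abc import Mapping, Sequence
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .npmr import (
    CATEGORICAL,
    CONTINUOUS,
    NPMRModel,
    PredictorSpec,
    infer_specs,
    local_mean_estimate,
    loo_predictions,
    naive_rate,
)
from .search import (
    BootstrapResult,
    LadderEntry,
    SearchControls,
    bootstrap_logbeta,
    free_search,
    monte_carlo_test,
    select_final,
    sensitivity,
)

__all__ = [
    "screen_predictors",
    "fit_dataset",
    "FitReport",
    "GroupPrediction",
    "predict_by_group",
    "duncan_letters",
    "ResponseProfile",
    "response_profile",
]


# ---------------------------------------------------------------------------
# predictor screening


def _association(table: pd.DataFrame, a: PredictorSpec, b: PredictorSpec) -> float:
    """Pairwise association in [0, 1]: |Pearson r| (continuous pair),
    Cramér's V (categorical pair) or the correlation ratio (mixed)."""
    cols = table[[a.name, b.name]].dropna()
    if len(cols) < 3:
        return 0.0
    if a.kind == CONTINUOUS and b.kind == CONTINUOUS:
        x = cols[a.name].to_numpy(dtype=float)
        y = cols[b.name].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            return 0.0
        return float(abs(np.corrcoef(x, y)[0, 1]))
    if a.kind == CATEGORICAL and b.kind == CATEGORICAL:
        ct = pd.crosstab(cols[a.name], cols[b.name])
        if min(ct.shape) < 2:
            return 0.0
        chi2 = stats.chi2_contingency(ct.to_numpy(), correction=False)[0]
        n = ct.to_numpy().sum()
        return float(np.sqrt(chi2 / (n * (min(ct.shape) - 1))))
    cont, cat = (a, b) if a.kind == CONTINUOUS else (b, a)
    x = cols[cont.name].to_numpy(dtype=float)
    groups = cols[cat.name].to_numpy(dtype=object)
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    if ss_total == 0:
        return 0.0
    ss_between = sum(len(xg := x[groups == g]) * (xg.mean() - grand) ** 2
                     for g in pd.unique(groups))
    return float(np.sqrt(ss_between / ss_total))


def _univariate_logbeta(table: pd.DataFrame, spec: PredictorSpec,
                        controls: SearchControls) -> float:
    ladder = free_search(table, {spec.name: spec}, controls)
    return ladder[1].log_beta if len(ladder) > 1 else float("-inf")


def screen_predictors(
    table: pd.DataFrame,
    candidates: Mapping[str, PredictorSpec],
    r_threshold: float = 0.7,
    controls: Optional[SearchControls] = None,
) -> dict[str, PredictorSpec]:
    """Drop one member of every over-associated predictor pair.

    Pairs whose association reaches ``r_threshold`` are resolved by
    keeping the member with the larger univariate logβ (ties keep the
    lexicographically earlier name).  Pairs are processed in descending
    association order, so the result is deterministic.
    """
    controls = controls or SearchControls()
    names = sorted(candidates)
    if len(names) < 2:
        return dict(candidates)
    pairs = []
    for na, nb in itertools.combinations(names, 2):
        assoc = _association(table, candidates[na], candidates[nb])
        if assoc >= r_threshold:
            pairs.append((assoc, na, nb))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    dropped: set[str] = set()
    ulb: dict[str, float] = {}
    for assoc, na, nb in pairs:
        if na in dropped or nb in dropped:
            continue
        for n_ in (na, nb):
            if n_ not in ulb:
                ulb[n_] = _univariate_logbeta(table, candidates[n_], controls)
        if ulb[na] > ulb[nb]:
            dropped.add(nb)
        elif ulb[nb] > ulb[na]:
            dropped.add(na)
        else:
            dropped.add(max(na, nb))
    return {n_: candidates[n_] for n_ in names if n_ not in dropped}


# ---------------------------------------------------------------------------
# dataset fit


@dataclasses.dataclass
class FitReport:
    """Everything reported about one dataset's fitted occupancy model."""

    dataset: str
    n_sites: int
    naive_rate: float
    model: NPMRModel
    log_beta: float
    n_star: float
    bootstrap: Optional[BootstrapResult]
    mc_p: Optional[float]
    predictors: list[dict]
    ladder: list[dict]
    screened_out: list[str]

    def to_dict(self) -> dict:
        return {
            "dataset": self.dataset,
            "n_sites": self.n_sites,
            "naive_rate": self.naive_rate,
            "model": {
                "predictors": list(self.model.predictors),
                "tolerances": dict(self.model.tolerances),
                "min_neighborhood": self.model.min_neighborhood,
            },
            "log_beta": self.log_beta,
            "n_star": self.n_star,
            "bootstrap": None if self.bootstrap is None else {
                "mean": self.bootstrap.mean,
                "se": self.bootstrap.se,
                "n_boot": self.bootstrap.n_boot,
                "n_redrawn": self.bootstrap.n_redrawn,
            },
            "mc_p": self.mc_p,
            "predictors": self.predictors,
            "ladder": self.ladder,
            "screened_out": self.screened_out,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def to_text(self) -> str:
        """Human-readable fit summary (one row per model predictor)."""
        lines = [
            f"dataset: {self.dataset}   n = {self.n_sites}   "
            f"naive rate = {self.naive_rate:.3f}",
            f"logB = {self.log_beta:.2f}   N* = {self.n_star:.1f}"
            + (f"   bootstrap = {self.bootstrap.mean:.2f} +/- "
               f"{self.bootstrap.se:.2f}" if self.bootstrap else "")
            + (f"   MC p = {self.mc_p:.3g}" if self.mc_p is not None else ""),
            f"{'predictor':<16}{'kind':<13}{'sensitivity':>12}{'tolerance':>18}",
        ]
        for p in self.predictors:
            if p["kind"] == CONTINUOUS:
                tol = f"{p['tolerance']:.3g} ({p['tolerance_pct']:.0f}%)"
                sens = f"{p['sensitivity']:.2f}"
            else:
                tol, sens = "na", "na"
            lines.append(f"{p['name']:<16}{p['kind']:<13}{sens:>12}{tol:>18}")
        return "\n".join(lines)


def fit_dataset(
    table: pd.DataFrame,
    candidates: Optional[Mapping[str, PredictorSpec]] = None,
    controls: Optional[SearchControls] = None,
    r_threshold: float = 0.7,
    run_bootstrap: bool = True,
    run_monte_carlo: bool = True,
    n_boot: int = 100,
    n_perm: int = 100,
) -> FitReport:
    """Full analysis of one survey table.

    Seed flow: ``controls.seed`` feeds a generator from which the
    bootstrap seed, then the Monte Carlo seed, are drawn in that order.
    """
    controls = controls or SearchControls()
    if candidates is None:
        cols = [c for c in table.columns if c not in ("site_id", "occupancy")]
        candidates = infer_specs(table, cols)
    ybar = naive_rate(table)
    retained = screen_predictors(table, candidates, r_threshold, controls)
    screened_out = sorted(set(candidates) - set(retained))
    ladder = free_search(table, retained, controls)
    final = select_final(ladder, controls.improvement_threshold)

    rng = np.random.default_rng(controls.seed)
    boot_seed = int(rng.integers(2 ** 31))
    mc_seed = int(rng.integers(2 ** 31))

    boot = None
    if run_bootstrap and final.size > 0:
        boot = bootstrap_logbeta(table, final.model, retained, n_boot=n_boot,
                                 seed=boot_seed, epsilon=controls.epsilon)
    mc_p = None
    if run_monte_carlo:
        if final.size == 0:
            mc_p = 1.0
        else:
            mc_p = monte_carlo_test(table, retained, controls, final.log_beta,
                                    size=final.size, n_perm=n_perm, seed=mc_seed)

    predictors = []
    for name in final.model.predictors:
        spec = retained[name]
        entry: dict = {"name": name, "kind": spec.kind}
        if spec.kind == CONTINUOUS:
            tol = final.model.tolerances[name]
            entry["sensitivity"] = sensitivity(table, final.model, retained, name)
            entry["tolerance"] = tol
            entry["tolerance_pct"] = 100.0 * tol / spec.range_width
        else:
            entry["sensitivity"] = None
            entry["tolerance"] = None
            entry["tolerance_pct"] = None
        predictors.append(entry)

    return FitReport(
        dataset=str(table.attrs.get("dataset", "")),
        n_sites=len(table),
        naive_rate=ybar,
        model=final.model,
        log_beta=final.log_beta,
        n_star=final.n_star,
        bootstrap=boot,
        mc_p=mc_p,
        predictors=predictors,
        ladder=[{"size": e.size, "predictors": list(e.model.predictors),
                 "log_beta": e.log_beta, "n_star": e.n_star} for e in ladder],
        screened_out=screened_out,
    )


# ---------------------------------------------------------------------------
# group predictions and Duncan's multiple-range letters


@dataclasses.dataclass
class GroupPrediction:
    """Average modelled occupancy for one habitat group."""

    group: object
    mean: float
    se: float
    n: int
    n_na: int
    letter: str = ""


def duncan_letters(groups: Mapping, alpha: float = 0.05) -> dict:
    """Duncan's multiple-range test letter display.

    ``groups`` maps label to an array of values (each with ≥2 values).
    Groups are ranked by mean; ranges are compared against the least
    significant range ``q(p_r, r, df) · sqrt(MSE / n_h)`` where
    ``p_r = (1 - alpha)^(r-1)`` is Duncan's protection level for a span
    of r means, MSE is the one-way ANOVA residual mean square and n_h
    the harmonic mean size of the span's extreme groups.  Groups inside
    a non-significant range share a letter.
    """
    labels = sorted(groups, key=lambda g: (-np.mean(groups[g]), str(g)))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrs = {g: np.asarray(groups[g], dtype=float) for g in labels}
    for g, a in arrs.items():
        if a.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    k = len(labels)
    N = sum(a.size for a in arrs.values())
    means = {g: a.mean() for g, a in arrs.items()}
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs.values())
    df = N - k
    mse = ss_within / df if df > 0 else 0.0

    def lsr(span_labels):
        r = len(span_labels)
        if mse == 0.0:
            return 0.0
        n_h = stats.hmean([arrs[span_labels[0]].size, arrs[span_labels[-1]].size])
        q = stats.studentized_range.ppf((1 - alpha) ** (r - 1), r, df)
        return q * np.sqrt(mse / n_h)

    # top-down range testing with Duncan's containment (protection) rule
    ns_ranges: list[tuple[int, int]] = []
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if any(a <= i and j <= b for a, b in ns_ranges):
                continue
            sub = labels[i:j + 1]
            if means[sub[0]] - means[sub[-1]] <= lsr(sub) + 1e-12:
                ns_ranges.append((i, j))
    letters = {g: "" for g in labels}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    covered = set()
    idx = 0
    for i, j in sorted(ns_ranges):
        for m in range(i, j + 1):
            letters[labels[m]] += alphabet[idx]
            covered.add(m)
        idx += 1
    for m, g in enumerate(labels):
        if m not in covered:
            letters[g] = alphabet[idx]
            idx += 1
    # normalise: letters in rank order without gaps
    order = {}
    for g in labels:
        for ch in letters[g]:
            order.setdefault(ch, alphabet[len(order)])
    return {g: "".join(order[ch] for ch in letters[g]) for g in labels}


def predict_by_group(
    table: pd.DataFrame,
    model: NPMRModel,
    specs: Mapping[str, PredictorSpec],
    group_variable: str,
    alpha: float = 0.05,
    letters: bool = True,
) -> list[GroupPrediction]:
    """Average LOO model prediction per level of a grouping variable.

    Sites whose prediction is NA (too few data in their region of
    predictor space) are excluded from the mean and counted.  SE is over
    sites (sd/√n); single-site groups get SE = NaN.  Letters come from
    Duncan's multiple-range test on the per-site predictions.
    """
    preds = loo_predictions(table, model, specs)
    groups = table[group_variable]
    out: list[GroupPrediction] = []
    valid_by_group: dict = {}
    for g in sorted(pd.unique(groups.dropna()), key=str):
        sel = (groups == g).to_numpy()
        vals = preds[sel]
        ok = vals[~np.isnan(vals)]
        n_na = int(np.isnan(vals).sum())
        if ok.size == 0:
            out.append(GroupPrediction(g, float("nan"), float("nan"),
                                       int(sel.sum()), n_na))
            continue
        se = float(ok.std(ddof=1) / np.sqrt(ok.size)) if ok.size > 1 else float("nan")
        out.append(GroupPrediction(g, float(ok.mean()), se, int(sel.sum()), n_na))
        if ok.size >= 2:
            valid_by_group[g] = ok
    if letters and len(valid_by_group) >= 2:
        assigned = duncan_letters(valid_by_group, alpha=alpha)
        for gp in out:
            gp.letter = assigned.get(gp.group, "")
    return sorted(out, key=lambda gp: (-(gp.mean if np.isfinite(gp.mean) else -1),
                                       str(gp.group)))


# ---------------------------------------------------------------------------
# response profiles


@dataclasses.dataclass
class ResponseProfile:
    """Modelled occupancy along one predictor with the rest held fixed."""

    predictor: str
    values: np.ndarray
    context: dict
    predictions: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({self.predictor: self.values,
                           "prediction": self.predictions})
        for key, val in self.context.items():
            df[key] = val
        return df


def response_profile(
    table: pd.DataFrame,
    model: NPMRModel,
    specs: Mapping[str, PredictorSpec],
    varying: str,
    context: Mapping,
    n_grid: int = 50,
) -> ResponseProfile:
    """Predictions on an even grid across one predictor's observed range.

    All other model predictors are held at the given context values;
    grid points whose environmental neighbourhood is too sparse come
    back NA, mirroring how sparse regions are dropped from reported
    response curves.
    """
    if varying not in model.predictors:
        raise ValueError(f"{varying!r} is not in the model")
    missing = [p for p in model.predictors if p != varying and p not in context]
    if missing:
        raise ValueError(f"context is missing model predictors: {missing}")
    lo, hi = specs[varying].observed_range
    xs = np.linspace(lo, hi, n_grid)
    preds = np.empty(n_grid)
    for i, x in enumerate(xs):
        target = dict(context)
        target[varying] = x
        preds[i] = local_mean_estimate(target, table, model, specs)
    return ResponseProfile(predictor=varying, values=xs, context=dict(context),
                           predictions=preds)
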