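"""NPMR core estimator: kernels, local means, LOO logβ, neighbourhood size."""

import math

import numpy as np
import pandas as pd
import pytest

from npmrocc import (
    NPMRModel,
    PredictorSpec,
    kernel_weight,
    local_mean_estimate,
    loo_log_beta,
    naive_rate,
    neighborhood_size,
)
from npmrocc.npmr import weight_matrix

from conftest import make_table, random_table, specs_for

CONT = PredictorSpec("x", "continuous", observed_range=(0.0, 10.0))
CAT = PredictorSpec("h", "categorical", levels=("beaver pond", "spring/seep"))


# ---------------------------------------------------------------------------
# independent brute-force oracles (pure python, no numpy vectorisation)


def oracle_weight(tv, ov, kind, tol):
    if ov is None or (isinstance(ov, float) and math.isnan(ov)):
        return 0.0
    if kind == "continuous":
        return math.exp(-((tv - ov) ** 2) / (2 * tol * tol))
    return 1.0 if tv == ov else 0.0


def oracle_estimate(target, table, model, specs, exclude=None):
    num = den = 0.0
    for _, row in table.iterrows():
        if exclude is not None and row["site_id"] == exclude:
            continue
        w = 1.0
        for name in model.predictors:
            w *= oracle_weight(target[name], row[name], specs[name].kind,
                               model.tolerances.get(name))
        num += w * row["occupancy"]
        den += w
    if den < model.min_neighborhood:
        return float("nan")
    return num / den


def oracle_logbeta(table, model, specs, eps=1e-3):
    ybar = table["occupancy"].mean()
    ll_model = ll_naive = 0.0
    for _, row in table.iterrows():
        p = oracle_estimate(row, table, model, specs, exclude=row["site_id"])
        if math.isnan(p):
            p = ybar
        p = min(max(p, eps), 1 - eps)
        y = row["occupancy"]
        ll_model += y * math.log10(p) + (1 - y) * math.log10(1 - p)
        ll_naive += y * math.log10(ybar) + (1 - y) * math.log10(1 - ybar)
    return ll_model - ll_naive


# ---------------------------------------------------------------------------


class TestKernelWeight:
    def test_gaussian_formula(self):
        got = kernel_weight(0.0, 1.0, CONT, tolerance=0.5)
        assert got == pytest.approx(math.exp(-2), abs=1e-9)
        assert got == pytest.approx(0.135335, abs=1e-6)

    def test_peak_at_target(self):
        assert kernel_weight(4.2, 4.2, CONT, tolerance=1.0) == 1.0

    def test_categorical_mismatch_is_zero(self):
        assert kernel_weight("beaver pond", "spring/seep", CAT) == 0.0
        assert kernel_weight("beaver pond", "beaver pond", CAT) == 1.0

    def test_missing_observation_gets_zero_weight(self):
        assert kernel_weight(1.0, float("nan"), CONT, tolerance=1.0) == 0.0

    @pytest.mark.parametrize("tol", [0.0, -1.0])
    def test_nonpositive_tolerance_rejected(self, tol):
        with pytest.raises(ValueError):
            kernel_weight(0.0, 1.0, CONT, tolerance=tol)


class TestLocalMeanEstimate:
    def test_hand_computed_weighted_mean(self):
        table = make_table([0, 1, 2], [1, 0, 1])
        model = NPMRModel(("x",), {"x": 1.0})
        specs = specs_for(table)
        got = local_mean_estimate({"x": 0.0}, table, model, specs)
        w = [1.0, math.exp(-0.5), math.exp(-2)]
        assert got == pytest.approx((w[0] + w[2]) / sum(w), abs=1e-12)
        assert got == pytest.approx(0.651793, abs=1e-5)

    def test_flat_kernel_limit_is_arithmetic_mean(self):
        table = make_table([0, 1, 2], [1, 0, 1])
        model = NPMRModel(("x",), {"x": 1e6 * 2.0})
        got = local_mean_estimate({"x": 0.0}, table, model, specs_for(table))
        assert got == pytest.approx(2 / 3, abs=1e-9)

    def test_sparse_neighborhood_returns_nan(self):
        table = make_table([0, 0.1, 0.2], [1, 0, 1])
        model = NPMRModel(("x",), {"x": 0.05}, min_neighborhood=1.0)
        got = local_mean_estimate({"x": 9.0}, table, model, specs_for(table))
        assert math.isnan(got)

    def test_empty_table_raises(self):
        table = make_table([], [])
        model = NPMRModel(("x",), {"x": 1.0})
        with pytest.raises(ValueError):
            local_mean_estimate({"x": 0.0}, table, model,
                                {"x": CONT})

    def test_oracle_equivalence_on_random_tables(self, rng):
        """Vectorised estimator matches the brute-force double loop to
        1e-12 on 50 random mixed-type tables."""
        for _ in range(50):
            n = int(rng.integers(5, 31))
            table = random_table(rng, n, n_cont=2, n_cat=1)
            specs = specs_for(table)
            model = NPMRModel(
                ("x0", "x1", "c0"),
                {"x0": float(rng.uniform(0.5, 5)),
                 "x1": float(rng.uniform(0.5, 5))},
                min_neighborhood=0.5,
            )
            target = {"x0": float(rng.uniform(0, 10)),
                      "x1": float(rng.uniform(0, 10)),
                      "c0": str(rng.choice(["a", "b", "c"]))}
            got = local_mean_estimate(target, table, model, specs)
            want = oracle_estimate(target, table, model, specs)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_estimates_bounded_by_response_range(self, rng):
        for _ in range(20):
            table = random_table(rng, 20)
            model = NPMRModel(("x0",), {"x0": 1.0}, min_neighborhood=0.1)
            got = local_mean_estimate(
                {"x0": float(rng.uniform(0, 10))}, table, model,
                specs_for(table))
            if not math.isnan(got):
                assert 0.0 <= got <= 1.0


class TestLooLogBeta:
    def test_zero_predictor_model_is_exactly_zero(self, rng):
        table = random_table(rng, 25)
        assert loo_log_beta(table, NPMRModel(), specs_for(table)) == 0.0

    def test_hand_computed_two_cluster_value(self):
        # two identical pairs far apart: every LOO estimate equals its
        # twin's response, clamped at 1 - eps / eps
        table = make_table([0, 0, 10, 10], [1, 1, 0, 0])
        model = NPMRModel(("x",), {"x": 1.0})
        got = loo_log_beta(table, model, specs_for(table), epsilon=1e-3)
        want = 4 * math.log10(0.999) - 4 * math.log10(0.5)
        assert got == pytest.approx(want, abs=1e-9)
        assert got == pytest.approx(1.2024, abs=1e-3)

    def test_row_order_invariance(self, rng):
        table = random_table(rng, 20, signal=True)
        model = NPMRModel(("x0",), {"x0": 1.5})
        specs = specs_for(table)
        shuffled = table.sample(frac=1, random_state=3).reset_index(drop=True)
        assert loo_log_beta(table, model, specs) == pytest.approx(
            loo_log_beta(shuffled, model, specs), abs=1e-10)

    def test_degenerate_naive_rate_raises(self):
        table = make_table([0, 1, 2], [1, 1, 1])
        with pytest.raises(ValueError):
            loo_log_beta(table, NPMRModel(("x",), {"x": 1.0}),
                         specs_for(table))

    def test_oracle_equivalence_on_random_tables(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 31))
            table = random_table(rng, n, n_cont=2, n_cat=1,
                                 signal=bool(rng.integers(2)))
            specs = specs_for(table)
            model = NPMRModel(
                ("x0", "c0"), {"x0": float(rng.uniform(0.5, 5))},
                min_neighborhood=0.8)
            got = loo_log_beta(table, model, specs)
            want = oracle_logbeta(table, model, specs)
            assert got == pytest.approx(want, abs=1e-9)

    def test_noise_predictor_with_flat_kernel_changes_nothing(self, rng):
        table = random_table(rng, 25, n_cont=2, signal=True)
        specs = specs_for(table)
        base = NPMRModel(("x0",), {"x0": 1.0})
        extended = NPMRModel(("x0", "x1"), {"x0": 1.0, "x1": 1e8})
        assert loo_log_beta(table, extended, specs) == pytest.approx(
            loo_log_beta(table, base, specs), abs=1e-6)
        assert neighborhood_size(table, extended, specs) == pytest.approx(
            neighborhood_size(table, base, specs), abs=1e-6)

    def test_null_response_gives_small_logbeta_on_average(self):
        """Cross-validation penalises covariate noise: logβ of a model
        fit to response independent of x is ~<= 0 in expectation."""
        values = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            table = random_table(r, 40)
            model = NPMRModel(("x0",), {"x0": 2.0})
            values.append(loo_log_beta(table, model, specs_for(table)))
        assert np.mean(values) <= 0.5


class TestNeighborhoodSize:
    def test_flat_kernel_gives_n_minus_one(self, rng):
        table = random_table(rng, 4)
        model = NPMRModel(("x0",), {"x0": 1e9})
        assert neighborhood_size(table, model, specs_for(table)) == \
            pytest.approx(3.0, abs=1e-6)

    def test_two_disjoint_categories(self):
        table = pd.DataFrame({
            "site_id": [f"s{i}" for i in range(10)],
            "occupancy": [1, 0] * 5,
            "h": ["a"] * 5 + ["b"] * 5,
        })
        model = NPMRModel(("h",))
        assert neighborhood_size(table, model, specs_for(table)) == \
            pytest.approx(4.0)

    def test_vanishing_tolerance_gives_zero(self, rng):
        table = random_table(rng, 8)
        model = NPMRModel(("x0",), {"x0": 1e-9})
        assert neighborhood_size(table, model, specs_for(table)) == \
            pytest.approx(0.0, abs=1e-9)


def test_missing_covariate_row_excluded_from_weights(rng):
    table = make_table([0.0, 0.1, np.nan, 0.2], [1, 0, 1, 1])
    model = NPMRModel(("x",), {"x": 1.0})
    specs = {"x": CONT}
    W = weight_matrix(table, model, specs)
    assert (W[:, 2] == 0).all()  # the NaN row never contributes
    assert (W[2, :] == 0).all()  # and has no neighbourhood of its own
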