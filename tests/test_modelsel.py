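"""Family racing, permutation importance, probe selection, adjusted R^2."""

import numpy as np
import pandas as pd
import pytest

from beeftradeoff.modelsel import (
    PROBE,
    FittedModel,
    ModelTask,
    _OLS,
    _SIR,
    apparent_adj_r2,
    compare_families,
    corrected_adj_r2,
    fit_model,
    importance,
    make_tasks,
    select_predictors,
)
from beeftradeoff.pretreat import IndicatorTable


def _table(cols: dict, groups: dict) -> IndicatorTable:
    df = pd.DataFrame(cols)
    return IndicatorTable(df, groups, {c: "passthrough" for c in df.columns})


def _linear_table(n=60, seed=0, noise=0.0, coefs=(3.0, -2.0, 0.0)):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, len(coefs)))
    y = X @ np.array(coefs) + noise * rng.standard_normal(n)
    cols = {f"x{i+1}": X[:, i] for i in range(len(coefs))}
    cols["y"] = y
    groups = {f"x{i+1}": "CP" for i in range(len(coefs))}
    groups["y"] = "NQ"
    return _table(cols, groups)


class TestTasks:
    def test_candidate_counts_by_group(self, indicators):
        tasks = {t.response: t for t in make_tasks(indicators)}
        assert len(tasks) == 24
        for name, task in tasks.items():
            g = indicators.group_map[name]
            expected = 21 if g == "AP" else 17
            assert len(task.candidates) == expected
            assert name not in task.candidates
            assert all(indicators.group_map[c] != g for c in task.candidates)


class TestCompareFamilies:
    def test_noiseless_linear_truth_crowns_lm(self):
        data = _linear_table(n=60, noise=0.0)
        task = ModelTask("y", ["x1", "x2", "x3"])
        fs = compare_families(task, data, n_splits=10, seed=0, rf_trees=30)
        assert fs.champion == "lm"
        assert fs.mse["lm"].median() < 1e-10

    def test_rf_beats_lm_on_strong_nonlinearity(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((200, 3))
            y = np.sign(X[:, 0]) * X[:, 0] ** 2 + 0.2 * rng.standard_normal(200)
            data = _table(
                {"x1": X[:, 0], "x2": X[:, 1], "x3": X[:, 2], "y": y},
                {"x1": "CP", "x2": "CP", "x3": "CP", "y": "NQ"},
            )
            fs = compare_families(
                ModelTask("y", ["x1", "x2", "x3"]), data,
                n_splits=6, seed=seed, rf_trees=80, families=("lm", "rf"),
            )
            wins += fs.mse["rf"].median() < fs.mse["lm"].median()
        assert wins > 10

    def test_pure_noise_mse_near_response_variance(self):
        rng = np.random.default_rng(42)
        n = 300
        cols = {f"x{i}": rng.standard_normal(n) for i in range(1, 4)}
        cols["y"] = rng.standard_normal(n)
        data = _table(cols, {"x1": "CP", "x2": "CP", "x3": "CP", "y": "NQ"})
        fs = compare_families(
            ModelTask("y", ["x1", "x2", "x3"]), data, n_splits=10, seed=1, rf_trees=60
        )
        var = np.var(cols["y"], ddof=1)
        for fam in fs.mse.columns:
            assert 0.8 * var <= fs.mse[fam].median() <= 1.3 * var

    def test_champion_invariant_to_candidate_order(self):
        data = _linear_table(n=40, noise=0.5)
        a = compare_families(ModelTask("y", ["x1", "x2", "x3"]), data, n_splits=5, seed=3, rf_trees=30)
        b = compare_families(ModelTask("y", ["x3", "x1", "x2"]), data, n_splits=5, seed=3, rf_trees=30)
        assert a.champion == b.champion
        pd.testing.assert_frame_equal(a.mse, b.mse)


class TestImportance:
    def test_signal_orders_importance(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((80, 2))
            y = 2 * X[:, 0] + X[:, 1] + 0.3 * rng.standard_normal(80)
            data = _table(
                {"x1": X[:, 0], "x2": X[:, 1], "y": y},
                {"x1": "CP", "x2": "CP", "y": "NQ"},
            )
            imp = importance(ModelTask("y", ["x1", "x2"]), data, "lm", n_splits=10, seed=seed)
            hits += imp["x1"] > imp["x2"]
        assert hits >= 18

    def test_irrelevant_candidate_near_zero(self):
        rng = np.random.default_rng(7)
        n = 400
        X = rng.standard_normal((n, 3))
        y = X[:, 0] + 0.1 * rng.standard_normal(n)
        data = _table(
            {"x1": X[:, 0], "x2": X[:, 1], "x3": X[:, 2], "y": y},
            {"x1": "CP", "x2": "CP", "x3": "CP", "y": "NQ"},
        )
        imp = importance(ModelTask("y", ["x1", "x2", "x3"]), data, "lm", n_splits=20, seed=7)
        assert abs(imp["x2"]) < 0.05 * imp["x1"]

    def test_constant_column_importance_exactly_zero(self):
        rng = np.random.default_rng(8)
        n = 50
        data = _table(
            {
                "x1": rng.standard_normal(n),
                "c": np.ones(n) * 3.0,
                "y": rng.standard_normal(n),
            },
            {"x1": "CP", "c": "CP", "y": "NQ"},
        )
        # constant column enters prediction but permuting it is a no-op
        imp = importance(
            ModelTask("y", ["x1", "c"]), data, "rf", n_splits=5, seed=8, rf_trees=20
        )
        assert imp["c"] == 0.0


class TestSelectPredictors:
    def test_probe_keeps_true_drops_null(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 80
            X = rng.standard_normal((n, 10))
            y = 2.0 * X[:, 0] + 1.5 * X[:, 1] + 0.3 * rng.standard_normal(n)
            cols = {f"x{i+1}": X[:, i] for i in range(10)}
            cols["y"] = y
            groups = {f"x{i+1}": "CP" for i in range(10)}
            groups["y"] = "NQ"
            data = _table(cols, groups)
            task = ModelTask("y", [f"x{i+1}" for i in range(10)])
            imp = importance(task, data, "lm", n_splits=10, seed=seed)
            kept = select_predictors(imp)
            hits += {"x1", "x2"} <= set(kept)
        assert hits >= 18

    def test_fallback_to_top_one(self):
        imp = pd.Series({"a": -0.1, "b": -0.2, PROBE: 0.5})
        assert select_predictors(imp) == ["a"]

    def test_disabled_threshold_keeps_all(self):
        imp = pd.Series({"a": -0.1, "b": -0.2, PROBE: 0.5})
        assert select_predictors(imp, probe_importance=-np.inf) == ["a", "b"]


class TestFitModel:
    def test_lm_exact_coefficient_recovery(self):
        data = _linear_table(n=50, noise=0.0, coefs=(3.0, -2.0))
        model = fit_model(ModelTask("y", ["x1", "x2"]), data, "lm", ["x1", "x2"])
        np.testing.assert_allclose(model.estimator.coef_, [3.0, -2.0], atol=1e-10)

    def test_lm_residuals_orthogonal_to_predictors(self):
        data = _linear_table(n=50, noise=1.0)
        model = fit_model(ModelTask("y", ["x1", "x2"]), data, "lm", ["x1", "x2"])
        resid = data.values["y"] - model.predict(data.values[["x1", "x2"]].to_numpy())
        for c in ("x1", "x2"):
            assert abs(np.dot(resid, data.values[c])) < 1e-8

    def test_ridge_shrinks_single_predictor(self):
        rng = np.random.default_rng(5)
        n = 30
        x = rng.standard_normal(n)
        y = 2.0 * x + rng.standard_normal(n)
        data = _table({"x1": x, "y": y}, {"x1": "CP", "y": "NQ"})
        lm = fit_model(ModelTask("y", ["x1"]), data, "lm", ["x1"])
        rd = fit_model(ModelTask("y", ["x1"]), data, "ridge", ["x1"])
        assert abs(rd.estimator.coef_[0]) <= abs(lm.estimator.coef_[0]) + 1e-12

    def test_sir_recovers_single_index_direction(self):
        rng = np.random.default_rng(6)
        n, p = 500, 4
        beta = np.array([0.5, -0.5, 0.5, 0.5])
        X = rng.standard_normal((n, p))
        y = np.tanh(X @ beta) + 0.05 * rng.standard_normal(n)
        cols = {f"x{i+1}": X[:, i] for i in range(p)}
        cols["y"] = y
        groups = {f"x{i+1}": "CP" for i in range(p)}
        groups["y"] = "NQ"
        data = _table(cols, groups)
        model = fit_model(ModelTask("y", list(cols)[:p]), data, "sir", list(cols)[:p])
        cos = abs(np.dot(model.estimator.direction_, beta) / np.linalg.norm(beta))
        assert cos > 0.95

    def test_empty_subset_rejected(self):
        data = _linear_table()
        with pytest.raises(ValueError):
            fit_model(ModelTask("y", ["x1"]), data, "lm", [])


class TestAdjustedR2:
    def test_perfect_fit_is_one(self):
        data = _linear_table(n=40, noise=0.0)
        model = fit_model(ModelTask("y", ["x1", "x2"]), data, "lm", ["x1", "x2"])
        assert apparent_adj_r2(model, data) == pytest.approx(1.0)

    def test_formula_value(self):
        # adjR2 = 1 - (1 - R2)(n - 1)/(n - p - 1); R2=0.9, n=30, p=5 -> 0.8792
        assert 1 - (1 - 0.9) * 29 / 24 == pytest.approx(0.87917, abs=1e-4)
        rng = np.random.default_rng(9)
        n, p = 30, 5
        X = rng.standard_normal((n, p))
        y = X[:, 0] + rng.standard_normal(n)
        cols = {f"x{i+1}": X[:, i] for i in range(p)}
        cols["y"] = y
        data = _table(cols, {c: ("CP" if c != "y" else "NQ") for c in cols})
        model = fit_model(ModelTask("y", list(cols)[:p]), data, "lm", list(cols)[:p])
        pred = model.predict(X)
        r2 = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
        expected = 1 - (1 - r2) * (n - 1) / (n - p - 1)
        assert apparent_adj_r2(model, data) == pytest.approx(expected)

    def test_too_few_animals_errors(self):
        data = _linear_table(n=4, noise=0.0)
        model = fit_model(ModelTask("y", ["x1", "x2", "x3"]), data, "lm", ["x1", "x2", "x3"])
        with pytest.raises(ValueError):
            apparent_adj_r2(model, data)


class TestCorrectedAdjR2:
    def test_noiseless_truth_has_no_optimism(self):
        data = _linear_table(n=40, noise=0.0)
        task = ModelTask("y", ["x1", "x2"])
        q = corrected_adj_r2(task, data, "lm", ["x1", "x2"], B=30, seed=0)
        assert abs(q.adjR2_corrected - q.adjR2_apparent) < 0.01

    def test_small_and_large_B_stay_below_apparent(self):
        data = _linear_table(n=40, noise=1.5)
        task = ModelTask("y", ["x1", "x2", "x3"])
        for B in (2, 100):
            q = corrected_adj_r2(task, data, "lm", ["x1", "x2", "x3"], B=B, seed=1)
            assert q.adjR2_corrected <= q.adjR2_apparent + 0.05

    def test_B_below_two_rejected(self):
        data = _linear_table()
        with pytest.raises(ValueError):
            corrected_adj_r2(ModelTask("y", ["x1"]), data, "lm", ["x1"], B=1)


class TestHelpers:
    def test_ols_handles_singular_design(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(20)
        X = np.column_stack([x, x])  # perfectly collinear
        with pytest.warns(UserWarning, match="singular"):
            m = _OLS().fit(X, 2 * x)
        np.testing.assert_allclose(m.predict(X), 2 * x, atol=1e-8)

    def test_sir_prediction_is_finite(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((30, 3))
        y = X[:, 0] ** 2
        m = _SIR().fit(X, y)
        assert np.all(np.isfinite(m.predict(X)))
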