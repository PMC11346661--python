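"""Metrics, LOOCV protocol, tuning and feature-selection tests."""

import numpy as np
import pandas as pd
import pytest

from ripescan.modeling import (
    ModelConfig,
    default_dt_grid,
    default_rf_grid,
    loocv_evaluate,
    nested_loocv,
    r2,
    rmse,
    run_study,
    select_features,
    tune,
)

TINY_DT_GRID = [
    ModelConfig("DT", max_depth=md, min_samples_leaf=2, max_leaf_nodes=None)
    for md in (1, 3, 9)
]
TINY_RF_GRID = [ModelConfig("RF", ntree=nt, mtry=2) for nt in (3, 10)]


class TestMetrics:
    def test_rmse_hand_values(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert rmse([0, 0], [3, 4]) == pytest.approx(np.sqrt(25 / 2))
        y = np.array([1.0, 2.0, 3.0])
        assert rmse(y, y + 0.7) == pytest.approx(0.7)

    def test_rmse_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            rmse([1, 2], [1, 2, 3])

    def test_r2_limits(self):
        y = np.array([1.0, 2, 3, 4])
        assert r2(y, y) == 1.0
        assert r2(y, np.full(4, y.mean())) == 0.0

    def test_r2_matches_two_pass_oracle(self, rng):
        y = rng.normal(size=50)
        p = y + rng.normal(0, 0.5, 50)
        ssres = sum((yi - pi) ** 2 for yi, pi in zip(y, p))
        sstot = sum((yi - y.mean()) ** 2 for yi in y)
        assert r2(y, p) == pytest.approx(1 - ssres / sstot, abs=1e-12)

    def test_r2_constant_target_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            r2([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestLOOCV:
    def test_perfect_feature_is_learnable(self, rng):
        X = rng.normal(size=(30, 3))
        y = X[:, 0].copy()
        res = loocv_evaluate(ModelConfig("DT", max_depth=9), X, y)
        assert res.val_r2 >= 0.95
        assert len(res.predictions) == 30

    def test_constant_target_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="constant"):
            loocv_evaluate(ModelConfig("DT", max_depth=3), X, np.ones(10))

    def test_nonfinite_inputs_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        X[3, 1] = np.nan
        with pytest.raises(ValueError, match="finite"):
            loocv_evaluate(ModelConfig("DT", max_depth=3), X, np.arange(10.0))

    def test_no_leakage_of_heldout_target(self, rng):
        """Perturbing sample i's target must not change its own held-out
        prediction (the fold-i model never sees y_i)."""
        X = rng.normal(size=(20, 4))
        y = X[:, 0] + rng.normal(0, 0.1, 20)
        cfg = ModelConfig("DT", max_depth=5)
        base = loocv_evaluate(cfg, X, y)
        for i in (0, 7, 19):
            y2 = y.copy()
            y2[i] += 100.0
            pert = loocv_evaluate(cfg, X, y2)
            assert pert.predictions[i] == base.predictions[i]

    def test_rf_deterministic_for_fixed_seed(self, rng):
        X = rng.normal(size=(15, 3))
        y = rng.normal(size=15)
        cfg = ModelConfig("RF", ntree=5, mtry=2, seed=3)
        a = loocv_evaluate(cfg, X, y)
        b = loocv_evaluate(cfg, X, y)
        np.testing.assert_array_equal(a.predictions, b.predictions)

    def test_validation_uses_heldout_predictions_only(self, rng):
        X = rng.normal(size=(12, 2))
        y = rng.normal(size=12)
        res = loocv_evaluate(ModelConfig("DT", max_depth=9), X, y)
        assert res.val_rmse == pytest.approx(rmse(y, res.predictions))
        assert res.train_rmse < res.val_rmse  # depth-9 tree overfits noise


class TestTune:
    def test_single_config_grid(self, rng):
        X = rng.normal(size=(10, 2))
        y = X[:, 0]
        only = [ModelConfig("DT", max_depth=3)]
        res = tune("DT", X, y, grid=only)
        assert res.config == only[0]

    def test_beats_stump_on_linear_target(self, rng):
        X = rng.normal(size=(40, 1))
        y = X[:, 0]
        res = tune("DT", X, y, grid=default_dt_grid())
        stump = loocv_evaluate(ModelConfig("DT", max_depth=1), X, y)
        assert res.config.max_depth >= 1
        assert res.val_rmse <= stump.val_rmse

    def test_deterministic_selection(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        a = tune("DT", X, y, grid=TINY_DT_GRID)
        b = tune("DT", X, y, grid=TINY_DT_GRID)
        assert a.config == b.config and a.val_rmse == b.val_rmse

    def test_early_abandonment_matches_naive_search(self, rng):
        # the SSE-capped grid traversal must select the same config and
        # metrics as evaluating every configuration in full
        X = rng.normal(size=(25, 3))
        y = X[:, 0] + rng.normal(0, 0.3, 25)
        grid = default_dt_grid()[:40]
        fast = tune("DT", X, y, grid=grid)
        naive = min(
            (loocv_evaluate(c, X, y) for c in grid),
            key=lambda r: r.val_rmse,
        )
        assert fast.val_rmse == naive.val_rmse
        assert fast.config == naive.config

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            tune("DT", rng.normal(size=(10, 2)), rng.normal(size=10), grid=[])


class TestSelectFeatures:
    def test_single_feature_pool(self, rng):
        pool = pd.DataFrame({"only": rng.normal(size=15)})
        y = pool["only"] * 2 + rng.normal(0, 0.1, 15)
        res = select_features("DT", pool, y, grid=TINY_DT_GRID)
        assert res.features == ["only"]

    def test_signal_feature_found_among_noise(self, rng):
        n, p = 68, 10
        X = rng.normal(size=(n, p))
        y = X[:, 0] + rng.normal(0, 0.05, n)
        pool = pd.DataFrame(X, columns=[f"x{k}" for k in range(p)])
        res = select_features("RF", pool, y, grid=TINY_RF_GRID, seed=1)
        assert "x0" in res.features

    def test_selected_subset_no_worse_than_full_pool(self, rng):
        n, p = 30, 6
        X = rng.normal(size=(n, p))
        y = X[:, 1] - X[:, 3] + rng.normal(0, 0.2, n)
        pool = pd.DataFrame(X, columns=[f"x{k}" for k in range(p)])
        res = select_features("DT", pool, y, grid=TINY_DT_GRID)
        full = tune("DT", pool, y, grid=TINY_DT_GRID)
        assert res.val_rmse <= full.val_rmse + 1e-12

    def test_exact_feature_reaches_ceiling(self, rng):
        n = 32
        pool = pd.DataFrame({"exact": rng.normal(size=n), "noise": rng.normal(size=n)})
        y = pool["exact"].to_numpy()
        res = select_features(
            "DT", pool, y,
            grid=[ModelConfig("DT", max_depth=int(np.ceil(np.log2(n))) )],
        )
        assert res.val_r2 >= 0.95

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_features("DT", pd.DataFrame(), np.arange(3.0))


class TestNestedLOOCV:
    def test_honest_error_not_better_than_biased(self, rng):
        n = 20
        X = rng.normal(size=(n, 3))
        y = X[:, 0] + rng.normal(0, 0.3, n)
        pool = pd.DataFrame(X, columns=["a", "b", "c"])
        grid = [ModelConfig("DT", max_depth=3)]
        biased = select_features("DT", pool, y, grid=grid)
        honest = nested_loocv("DT", pool, y, grid=grid)
        assert len(honest.predictions) == n
        assert honest.val_rmse >= biased.val_rmse - 1e-9


class TestRunStudy:
    def test_report_cardinality_and_columns(self, rng):
        n = 24
        traits = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "species": "mandarin", "stage": "ripe",
            "T1": rng.normal(size=n), "T2": rng.normal(size=n),
        })
        sri_pool = pd.DataFrame(rng.normal(size=(n, 3)), columns=["s1", "s2", "s3"])
        rgbi_pool = pd.DataFrame(rng.normal(size=(n, 2)), columns=["r1", "r2"])
        report = run_study(
            traits, sri_pool, rgbi_pool,
            models=("DT",), pools=("SRI", "RGBI", "HV"),
            dt_grid=TINY_DT_GRID, seed=1,
        )
        assert len(report) == 2 * 1 * 3
        hv_row = report[(report["pool"] == "HV") & (report["variable"] == "T1")].iloc[0]
        assert hv_row["n_features"] <= 5
        assert {"variable", "model", "pool", "suggested_features", "parameters",
                "train_r2", "train_rmse", "val_r2", "val_rmse"} <= set(report.columns)

    def test_default_rf_grid_shape(self):
        grid = default_rf_grid(4)
        assert len(grid) == 25 * 4
        assert {c.ntree for c in grid} == set(range(1, 26))
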