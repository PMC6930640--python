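"""The repeated-split modelling protocol and its adapters."""

import numpy as np
import pytest

from fpqsar import harness, metrics
from fpqsar.harness import ModelSpec


class TestSplitData:
    def test_partition_sizes_match_convention(self):
        idx = harness.split_data(2229, 0.8, seed=0)
        assert len(idx.train_idx) == 1783
        assert len(idx.test_idx) == 446

    def test_disjoint_and_covering(self):
        idx = harness.split_data(10, 0.8, seed=1)
        assert set(idx.train_idx) | set(idx.test_idx) == set(range(10))
        assert set(idx.train_idx) & set(idx.test_idx) == set()

    def test_seed_determinism_and_variation(self):
        a = harness.split_data(50, 0.8, seed=5)
        b = harness.split_data(50, 0.8, seed=5)
        c = harness.split_data(50, 0.8, seed=6)
        assert np.array_equal(a.train_idx, b.train_idx)
        assert not np.array_equal(a.train_idx, c.train_idx)

    @pytest.mark.parametrize("frac", [0.0, 1.0, 1.5])
    def test_bad_fraction_rejected(self, frac):
        with pytest.raises(ValueError):
            harness.split_data(100, frac, seed=0)


class TestFitPredict:
    def test_rf_near_interpolates_noiseless_signal(self, rng):
        X = rng.poisson(2.0, size=(150, 5)).astype(float)
        y = X[:, 0]
        pred = harness.fit_predict(ModelSpec("RF", {"n_trees": 100}, 1), X, y, X)
        assert metrics.r_squared(y, pred) >= 0.95

    @pytest.mark.parametrize("method", ["DT", "SVM", "DNN", "RF"])
    def test_constant_response_predicted_everywhere(self, method, rng):
        X = rng.normal(size=(60, 4))
        y = np.full(60, 6.5)
        hp = {"n_trees": 20} if method == "RF" else {}
        pred = harness.fit_predict(ModelSpec(method, hp, 2), X, y, X)
        # the network converges toward the constant rather than hitting it
        atol = 0.75 if method == "DNN" else 0.05
        assert np.allclose(pred, 6.5, atol=atol)
        assert pred.mean() == pytest.approx(6.5, abs=0.25)

    @pytest.mark.parametrize("method", ["DT", "SVM", "DNN", "RF"])
    def test_seed_determinism(self, method, strong_signal_data):
        X, y, _ = strong_signal_data
        hp = {"n_trees": 30} if method == "RF" else {}
        spec = ModelSpec(method, hp, seed=7)
        a = harness.fit_predict(spec, X.values, y, X.values[:20])
        b = harness.fit_predict(spec, X.values, y, X.values[:20])
        assert np.array_equal(a, b)

    def test_unrecognized_method_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("GBM", {}, 0)


class TestCrossValidate:
    def test_leave_one_out_structure(self, rng):
        X = rng.normal(size=(12, 3))
        y = X[:, 0] + rng.normal(0, 0.1, 12)
        preds = harness.cross_validate(ModelSpec("DT", {"prune": False}, 0), X, y, k=12)
        assert len(preds.predicted) == 12
        assert preds.partition == "cv"

    def test_balanced_fold_sizes(self):
        from sklearn.model_selection import KFold

        for n, k in [(23, 10), (100, 7), (12, 5)]:
            sizes = [len(te) for _, te in KFold(k).split(np.empty((n, 1)))]
            assert max(sizes) - min(sizes) <= 1

    def test_strong_signal_recovery(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(2.0, size=(500, 5)).astype(float)
        y = X @ np.array([0.5, 0.4, 0.3, 0.2, 0.1]) + rng.normal(0, 0.1, 500)
        preds = harness.cross_validate(
            ModelSpec("RF", {"n_trees": 100}, 1), X, y, k=10, seed=4
        )
        assert metrics.r_squared(preds.observed, preds.predicted) >= 0.8

    def test_k_larger_than_n_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            harness.cross_validate(ModelSpec("DT"), X, X[:, 0], k=6)


class TestTuneMtry:
    def test_singleton_grid_short_circuits(self, rng):
        X = rng.normal(size=(30, 4))
        assert harness.tune_rf_mtry(X, X[:, 0], grid=[2], k=3) == 2

    def test_duplicate_grid_entries_tie_to_smaller(self, rng):
        X = rng.normal(size=(30, 4))
        assert harness.tune_rf_mtry(X, X[:, 0], grid=[2, 2, 2], k=3) == 2

    def test_deterministic_choice(self, strong_signal_data):
        X, y, _ = strong_signal_data
        a = harness.tune_rf_mtry(X.values, y, grid=[1, 20], k=5, seed=9, n_trees=50)
        b = harness.tune_rf_mtry(X.values, y, grid=[1, 20], k=5, seed=9, n_trees=50)
        assert a == b

    def test_empty_grid_rejected(self, rng):
        X = rng.normal(size=(30, 4))
        with pytest.raises(ValueError):
            harness.tune_rf_mtry(X, X[:, 0], grid=[])


class TestRunProtocol:
    def test_report_shape_contract(self, strong_signal_data):
        X, y, _ = strong_signal_data
        models = [ModelSpec(m, {"n_trees": 20} if m == "RF" else {}, 0)
                  for m in ("DT", "SVM", "DNN", "RF")]
        rep = harness.run_protocol(
            X.values[:80], y[:80], models, n_splits=2, base_seed=1, cv_folds=4
        )
        s = rep.summary()
        assert set(s) == {"DT", "SVM", "DNN", "RF"}
        for m in s:
            assert set(s[m]) == {"train", "cv", "test"}
            for part in s[m]:
                assert set(s[m][part]) == {"R2", "RMSE", "MAE", "rm2", "delta_rm2"}
                for stat in s[m][part].values():
                    assert set(stat) == {"mean", "sd"}

    def test_noiseless_signal_rf_test_r2(self, rng):
        # tree-friendly signal: two small-count features, fully bagged forest
        X = rng.poisson(2.0, size=(300, 5)).astype(float)
        y = 0.6 * X[:, 0] + 0.4 * X[:, 1]
        rep = harness.run_protocol(
            X, y, [ModelSpec("RF", {"n_trees": 100, "mtry": 5}, 0)],
            n_splits=3, base_seed=2, cv_folds=None,
        )
        s = rep.summary()["RF"]["test"]["R2"]
        assert s["mean"] >= 0.95
        assert s["sd"] <= 0.05

    def test_sd_uses_n_minus_1(self, strong_signal_data):
        X, y, _ = strong_signal_data
        rep = harness.run_protocol(
            X.values, y, [ModelSpec("RF", {"n_trees": 20}, 0)],
            n_splits=3, base_seed=5, cv_folds=None,
        )
        vals = [ms.R2 for ms in rep.per_split["RF"]["test"]]
        assert rep.summary()["RF"]["test"]["R2"]["sd"] == pytest.approx(
            np.std(vals, ddof=1)
        )

    def test_single_split_rejected(self, strong_signal_data):
        X, y, _ = strong_signal_data
        with pytest.raises(ValueError):
            harness.run_protocol(X.values, y, [ModelSpec("RF")], n_splits=1)

    def test_rf_beats_single_tree_on_cv(self, strong_signal_data):
        """Bagging many trees should outpredict one pruned tree."""
        X, y, _ = strong_signal_data
        wins = 0
        for seed in range(5):
            rf = harness.cross_validate(
                ModelSpec("RF", {"n_trees": 100}, seed), X.values, y, k=5, seed=seed
            )
            dt = harness.cross_validate(
                ModelSpec("DT", {}, seed), X.values, y, k=5, seed=seed
            )
            q2_rf = metrics.r_squared(rf.observed, rf.predicted)
            q2_dt = metrics.r_squared(dt.observed, dt.predicted)
            wins += q2_rf >= q2_dt
        assert wins >= 4


class TestYScramble:
    def test_single_permutation_count(self, strong_signal_data):
        X, y, _ = strong_signal_data
        scr = harness.y_scramble(
            ModelSpec("RF", {"n_trees": 50}, 0), X.values[:80], y[:80],
            n_permutations=1, seed=3, k=4,
        )
        assert scr.n_permutations == 1
        assert len(scr.permuted_points) == 1

    def test_zero_permutations_rejected(self, strong_signal_data):
        X, y, _ = strong_signal_data
        with pytest.raises(ValueError):
            harness.y_scramble(ModelSpec("RF"), X.values, y, n_permutations=0)


def test_raw_gini_importance_scale(strong_signal_data):
    """Raw node-purity importances are unnormalized: total RSS reduction per
    tree, so informative features score on the scale of n * var(y)."""
    X, y, _ = strong_signal_data
    model = harness.fit_model(ModelSpec("RF", {"n_trees": 50}, 0), X.values, y)
    imp = harness.raw_gini_importance(model, len(y))
    assert imp.shape == (X.n_features,)
    assert (imp >= 0).all()
    assert imp.sum() == pytest.approx(len(y) * y.var(), rel=0.5)
    top3 = set(np.argsort(imp)[-3:])
    assert top3 == {0, 1, 2}
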