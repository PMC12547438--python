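"""Boosting engine: split oracle, descent, predictions, serialization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import seabedlitter as sl

from conftest import enumerate_stump_candidates, oracle_best_stump


def _table(X, y, names=None):
    names = names or [f"x{j}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    df["y"] = y
    return df


class TestFitTree:
    def test_constant_target_single_leaf(self):
        rng = np.random.default_rng(0)
        tree = sl.fit_tree(rng.normal(size=(12, 3)), np.full(12, 3.5), depth=2)
        assert tree.is_leaf and tree.leaf_value == pytest.approx(3.5)

    def test_six_point_toy_matches_exhaustive_search(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0], [4.0], [5.0]])
        y = np.array([1.0, 1.2, 0.8, 5.0, 5.3, 4.9])
        tree = sl.fit_tree(X, y, depth=1, minobs=1)
        f, thr, _ = oracle_best_stump(X, y, minobs=1)
        assert tree.split_feature == f"x{f}"
        assert tree.split_threshold == pytest.approx(thr)  # midpoint 2.5
        assert tree.left.leaf_value == pytest.approx(1.0)
        assert tree.right.leaf_value == pytest.approx(5.0 + 0.3 - 0.1, abs=0.2)

    def test_minobs_larger_than_n_gives_mean_leaf(self):
        X = np.arange(8, dtype=float)[:, None]
        y = np.arange(8, dtype=float)
        tree = sl.fit_tree(X, y, depth=1, minobs=9)
        assert tree.is_leaf and tree.leaf_value == pytest.approx(y.mean())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sl.fit_tree(np.empty((0, 2)), np.empty(0))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(4, 30),
        p=st.integers(1, 5),
        minobs=st.integers(1, 3),
    )
    def test_stump_matches_brute_force_oracle(self, seed, n, p, minobs):
        """Greedy depth-1 split achieves the optimum of an exhaustive
        enumeration of all (feature, midpoint) candidates; when that
        optimum is unique the split itself matches (distinct features can
        induce the identical partition and tie exactly)."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        tree = sl.fit_tree(X, y, depth=1, minobs=minobs)
        candidates = enumerate_stump_candidates(X, y, minobs=minobs)
        if not candidates or max(c[2] for c in candidates) <= 0:
            assert tree.is_leaf
            return
        red_max = max(c[2] for c in candidates)
        tol = 1e-9 * max(red_max, 1e-12)
        chosen = [
            c for c in candidates
            if c[0] == int(tree.split_feature[1:])
            and c[1] == pytest.approx(tree.split_threshold, rel=1e-12)
        ]
        assert chosen, "returned split not among enumerated candidates"
        assert chosen[0][2] >= red_max - tol  # achieves the optimum
        ties = [c for c in candidates if c[2] >= red_max - tol]
        if len(ties) == 1:
            f, thr, _ = ties[0]
            assert tree.split_feature == f"x{f}"
            assert tree.split_threshold == pytest.approx(thr, rel=1e-12)

    def test_depth_two_refines_depth_one(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 3))
        y = np.where(X[:, 0] > 0, 2.0, -2.0) + np.where(X[:, 1] > 0.5, 1.0, 0.0)
        fidx = {f"x{j}": j for j in range(3)}
        sse1 = np.sum((y - sl.fit_tree(X, y, depth=1).predict(X, fidx)) ** 2)
        sse2 = np.sum((y - sl.fit_tree(X, y, depth=2).predict(X, fidx)) ** 2)
        assert sse2 < sse1
        assert sl.fit_tree(X, y, depth=2).max_depth() <= 2


class TestFitBoostedModel:
    def test_ntrees_zero_predicts_mean(self, station_table):
        params = sl.BoostParams(ntrees=0)
        model = sl.fit_boosted_model(station_table, "mp_count", sl.DEFAULT_PREDICTORS, params)
        pred = model.predict(station_table)
        np.testing.assert_allclose(pred, station_table["mp_count"].mean())

    def test_noiseless_step_fit_exactly_in_one_stump(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = 2.0 + 3.0 * (x > 0.4)
        df = _table(x[:, None], y)
        params = sl.BoostParams(ntrees=1, depth=1, minobs=1, shrinkage=1.0, bag_fraction=1.0)
        model = sl.fit_boosted_model(df, "y", ["x0"], params)
        np.testing.assert_allclose(model.predict(df), y, atol=1e-12)

    def test_training_sse_monotone_descent_without_bagging(self, station_table):
        params = sl.BoostParams(ntrees=60, bag_fraction=1.0, seed=2)
        model = sl.fit_boosted_model(station_table, "mp_count", sl.DEFAULT_PREDICTORS, params)
        y = station_table["mp_count"].to_numpy()
        X = station_table[sl.DEFAULT_PREDICTORS].to_numpy()
        pred = np.full(len(y), model.baseline)
        sse_prev = np.sum((y - pred) ** 2)
        fidx = {n: j for j, n in enumerate(model.feature_names)}
        for tree in model.trees:
            pred = pred + model.shrinkage * tree.predict(X, fidx)
            sse = np.sum((y - pred) ** 2)
            assert sse <= sse_prev * (1 + 1e-12)
            sse_prev = sse

    def test_small_shrinkage_drives_training_mae_down(self):
        # noiseless additive data: many shrunken stumps approach the target
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 2))
        y = np.where(X[:, 0] > 0, 4.0, 0.0) + np.where(X[:, 1] > 0, 2.0, 0.0)
        df = _table(X, y)
        params = sl.BoostParams(ntrees=2000, minobs=1, shrinkage=0.05, bag_fraction=1.0)
        model = sl.fit_boosted_model(df, "y", ["x0", "x1"], params)
        assert np.mean(np.abs(y - model.predict(df))) < 0.05

    def test_identical_params_identical_ensemble(self, station_table):
        params = sl.BoostParams(ntrees=50, seed=9)
        a = sl.fit_boosted_model(station_table, "mp_count", sl.DEFAULT_PREDICTORS, params)
        b = sl.fit_boosted_model(station_table, "mp_count", sl.DEFAULT_PREDICTORS, params)
        np.testing.assert_array_equal(a.predict(station_table), b.predict(station_table))
        assert a.to_dict() == b.to_dict()

    def test_bags_independent_of_ntrees_prefix(self, station_table):
        # tree m is a pure function of (seed, m): growing the ensemble
        # does not change earlier trees
        short = sl.BoostParams(ntrees=10, seed=4)
        long = sl.BoostParams(ntrees=25, seed=4)
        a = sl.fit_boosted_model(station_table, "mp_count", sl.DEFAULT_PREDICTORS, short)
        b = sl.fit_boosted_model(station_table, "mp_count", sl.DEFAULT_PREDICTORS, long)
        assert [t.to_dict() for t in a.trees] == [t.to_dict() for t in b.trees[:10]]

    def test_nonfinite_input_rejected(self, station_table):
        bad = station_table.copy()
        bad.loc[3, "silt_fraction"] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            sl.fit_boosted_model(bad, "mp_count", sl.DEFAULT_PREDICTORS, sl.BoostParams())

    def test_kernel_stump_agrees_with_fit_tree(self):
        # the compiled stump path and the recursive reference pick the
        # same first split on random residuals
        rng = np.random.default_rng(12)
        for trial in range(20):
            X = rng.normal(size=(30, 4))
            y = rng.normal(size=30)
            df = _table(X, y)
            params = sl.BoostParams(ntrees=1, minobs=3, shrinkage=1.0, bag_fraction=1.0)
            model = sl.fit_boosted_model(df, "y", [f"x{j}" for j in range(4)], params)
            ref = sl.fit_tree(X, y - y.mean(), depth=1, minobs=3)
            stump = model.trees[0]
            assert stump.split_feature == ref.split_feature
            assert stump.split_threshold == pytest.approx(ref.split_threshold)


class TestPredictModel:
    def test_empty_ensemble_constant_baseline(self):
        model = sl.BoostedModel(baseline=7.0, shrinkage=0.1, feature_names=["a"], _trees=[])
        np.testing.assert_allclose(model.predict(np.array([[1.0], [2.0]])), 7.0)

    def test_hand_computed_single_stump(self):
        # stump {x > 2: +1, else -1}, shrinkage 0.5, baseline 10; x=3 -> 10.5
        stump = sl.RegressionTree(
            split_feature="x",
            split_threshold=2.0,
            left=sl.RegressionTree(leaf_value=-1.0),
            right=sl.RegressionTree(leaf_value=1.0),
        )
        model = sl.BoostedModel(baseline=10.0, shrinkage=0.5, feature_names=["x"], _trees=[stump])
        assert model.predict(np.array([[3.0]]))[0] == pytest.approx(10.5)
        assert model.predict(np.array([[1.0]]))[0] == pytest.approx(9.5)

    def test_training_predictions_match_retained_fitted_values(self, station_table, fast_params):
        model = sl.fit_boosted_model(
            station_table, "mp_count", sl.DEFAULT_PREDICTORS, fast_params
        )
        np.testing.assert_allclose(
            model.predict(station_table), model.fitted_values, rtol=1e-10
        )

    def test_missing_feature_column_rejected(self, station_table, fast_params):
        model = sl.fit_boosted_model(
            station_table, "mp_count", sl.DEFAULT_PREDICTORS, fast_params
        )
        with pytest.raises(ValueError, match="missing feature"):
            model.predict(station_table.drop(columns=["silt_fraction"]))

    def test_serialization_round_trip(self, tmp_path, station_table, fast_params):
        model = sl.fit_boosted_model(
            station_table, "mp_count", sl.DEFAULT_PREDICTORS, fast_params
        )
        path = tmp_path / "model.json"
        model.to_json(path)
        back = sl.BoostedModel.from_json(path)
        np.testing.assert_allclose(
            back.predict(station_table), model.predict(station_table), rtol=1e-12
        )

    def test_cross_check_against_sklearn_gbm(self, station_table):
        """Independent oracle: sklearn's gradient boosting with matched
        settings (no subsampling, squared-error splits) produces near-
        identical training predictions."""
        sklearn = pytest.importorskip("sklearn.ensemble")
        params = sl.BoostParams(
            ntrees=100, depth=1, minobs=5, shrinkage=0.1, bag_fraction=1.0
        )
        ours = sl.fit_boosted_model(station_table, "mp_count", sl.DEFAULT_PREDICTORS, params)
        X = station_table[sl.DEFAULT_PREDICTORS].to_numpy()
        y = station_table["mp_count"].to_numpy()
        ref = sklearn.GradientBoostingRegressor(
            n_estimators=100, max_depth=1, min_samples_leaf=5, learning_rate=0.1,
            random_state=0,
        ).fit(X, y)
        np.testing.assert_allclose(ours.predict(station_table), ref.predict(X), rtol=1e-6)


class TestPartialDependence:
    def test_ignored_feature_gives_flat_curve(self):
        # feature "b" never appears in a split: clamping it cannot move
        # any prediction, so the averaged curve is constant
        stump = sl.RegressionTree(
            split_feature="a", split_threshold=0.0,
            left=sl.RegressionTree(leaf_value=0.0), right=sl.RegressionTree(leaf_value=1.0),
        )
        model2 = sl.BoostedModel(baseline=5.0, shrinkage=1.0, feature_names=["a", "b"], _trees=[stump])
        df = pd.DataFrame({"a": [0.5, -0.5, 1.5], "b": [0.0, 1.0, 2.0]})
        _, flat = sl.partial_dependence(model2, df, "b", np.linspace(-1, 1, 5))
        np.testing.assert_allclose(flat, flat[0])

    def test_single_stump_pd_is_step_at_threshold(self):
        stump = sl.RegressionTree(
            split_feature="a", split_threshold=0.7,
            left=sl.RegressionTree(leaf_value=-2.0), right=sl.RegressionTree(leaf_value=2.0),
        )
        model = sl.BoostedModel(baseline=1.0, shrinkage=0.5, feature_names=["a"], _trees=[stump])
        df = pd.DataFrame({"a": np.linspace(-3, 3, 11)})
        grid = np.array([0.0, 0.69, 0.71, 2.0])
        _, curve = sl.partial_dependence(model, df, "a", grid)
        np.testing.assert_allclose(curve, [0.0, 0.0, 2.0, 2.0])  # 1 ± 0.5*2

    def test_curve_bounded_by_attainable_predictions(self, station_table, fast_params):
        model = sl.fit_boosted_model(
            station_table, "mp_count", sl.DEFAULT_PREDICTORS, fast_params
        )
        grid = np.linspace(-3, 3, 9)
        _, curve = sl.partial_dependence(model, station_table, "silt_fraction", grid)
        lo = model.baseline + model.shrinkage * sum(
            (t.leaf_value if t.is_leaf else min(t.left.leaf_value, t.right.leaf_value))
            for t in model.trees
        )
        hi = model.baseline + model.shrinkage * sum(
            (t.leaf_value if t.is_leaf else max(t.left.leaf_value, t.right.leaf_value))
            for t in model.trees
        )
        assert (curve >= lo - 1e-9).all() and (curve <= hi + 1e-9).all()

    def test_unknown_feature_rejected(self, station_table, fast_params):
        model = sl.fit_boosted_model(
            station_table, "mp_count", sl.DEFAULT_PREDICTORS, fast_params
        )
        with pytest.raises(ValueError, match="unknown feature"):
            sl.partial_dependence(model, station_table, "nope", [0.0])


class TestBoostParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"ntrees": -1},
            {"depth": 0},
            {"minobs": 0},
            {"shrinkage": 0.0},
            {"shrinkage": 1.5},
            {"bag_fraction": 0.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sl.BoostParams(**kwargs)
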