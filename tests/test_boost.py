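"""Boosted trees: exhaustive-search oracle, hand-computed toys, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import surveysel as sv
from surveysel.boost import fit_regression_tree
from surveysel.exceptions import ConfigurationError


# ---------------------------------------------------------------------------
# independent exhaustive oracle for tree growth


def _oracle_best_split(X, r, rows, min_node_size):
    """Naive triple-loop split search: every (variable, midpoint threshold)."""
    best = (0.0, -1, np.nan)
    for j in range(X.shape[1]):
        vals = sorted(set(X[rows, j]))
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = (lo + hi) / 2
            left = [i for i in rows if X[i, j] <= thr]
            right = [i for i in rows if X[i, j] > thr]
            if len(left) < min_node_size or len(right) < min_node_size:
                continue
            # gain as reduction in residual sum of squares; with dyadic
            # residuals the arithmetic is exact, so mathematical ties are
            # bit-exact ties and the tie-break behaviour is comparable
            sl = float(sum(sorted((float(r[i]) for i in left))))
            sa = float(sum(sorted((float(r[i]) for i in rows))))
            sr = sa - sl
            gain = sl ** 2 / len(left) + sr ** 2 / len(right) - sa ** 2 / len(rows)
            if gain > best[0]:
                best = (gain, j, thr)
    return best


def _oracle_tree(X, r, max_terminal_nodes, min_node_size):
    """Best-first growth with the naive split search; returns splits + leaves."""
    leaves = {0: list(range(len(r)))}
    splits = []
    next_id = 1
    candidates = {0: _oracle_best_split(X, r, leaves[0], min_node_size)}
    while len(leaves) < max_terminal_nodes:
        best_leaf, best = -1, (0.0, -1, np.nan)
        for leaf in sorted(leaves):
            cand = candidates[leaf]
            if cand[1] >= 0 and cand[0] > best[0]:
                best_leaf, best = leaf, cand
        if best_leaf < 0:
            break
        gain, j, thr = best
        rows = leaves.pop(best_leaf)
        left = [i for i in rows if X[i, j] <= thr]
        right = [i for i in rows if X[i, j] > thr]
        splits.append((j, thr, gain))
        lid, rid = next_id, next_id + 1
        next_id += 2
        leaves[lid], leaves[rid] = left, right
        del candidates[best_leaf]
        candidates[lid] = _oracle_best_split(X, r, left, min_node_size)
        candidates[rid] = _oracle_best_split(X, r, right, min_node_size)
    leaf_values = sorted(float(r[idx].mean()) for idx in leaves.values())
    return splits, leaf_values


def _tree_splits(tree):
    return [(tree.feature[i], tree.threshold[i], tree.improvement[i])
            for i in range(len(tree.feature)) if tree.feature[i] >= 0]


class TestRegressionTree:
    def test_binary_stump_improvement_four(self):
        X = np.array([[1.0], [1.0], [0.0], [0.0]])
        r = np.array([1.0, 1.0, -1.0, -1.0])
        tree = fit_regression_tree(X, r, max_terminal_nodes=2, min_node_size=1)
        splits = _tree_splits(tree)
        assert len(splits) == 1
        assert splits[0][0] == 0 and splits[0][1] == pytest.approx(0.5)
        assert splits[0][2] == pytest.approx(4.0)
        assert sorted(tree.value[i] for i in tree.leaf_ids()) == [-1.0, 1.0]

    def test_constant_residuals_single_leaf(self):
        X = np.random.default_rng(0).standard_normal((20, 2))
        tree = fit_regression_tree(X, np.full(20, 0.7), 4, min_node_size=2)
        assert tree.n_leaves == 1
        assert tree.value[0] == pytest.approx(0.7)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        n=st.integers(4, 25),
        p=st.integers(1, 3),
        max_leaves=st.integers(2, 6),
        seed=st.integers(0, 10_000),
        discrete=st.booleans(),
    )
    def test_matches_exhaustive_oracle(self, n, p, max_leaves, seed, discrete):
        """Grown tree equals the naive exhaustive-search tree on random toys,
        including tied splits from discretized predictors."""
        rng = np.random.default_rng(seed)
        X = (rng.integers(0, 4, size=(n, p)).astype(float) if discrete
             else rng.standard_normal((n, p)))
        r = rng.integers(-16, 17, size=n) / 8.0  # dyadic: sums are float-exact
        tree = fit_regression_tree(X, r, max_leaves, min_node_size=1)
        splits, leaf_values = _oracle_tree(X, r, max_leaves, 1)
        got = _tree_splits(tree)
        assert len(got) == len(splits)
        # node storage order differs from split-application order; compare as sets
        got = sorted(got)
        splits = sorted(splits)
        for (fj, ft, fi), (oj, ot, oi) in zip(got, splits):
            assert fj == oj
            assert ft == pytest.approx(ot, abs=1e-12)
            assert fi == pytest.approx(oi, rel=1e-9, abs=1e-9)
        got_leaves = sorted(tree.value[i] for i in tree.leaf_ids())
        assert np.allclose(got_leaves, leaf_values, atol=1e-12)

    def test_threshold_strictly_between_observed_values(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 2))
        r = rng.standard_normal(30)
        tree = fit_regression_tree(X, r, 5, min_node_size=2)
        for i in range(len(tree.feature)):
            if tree.feature[i] >= 0:
                col = X[:, tree.feature[i]]
                assert (col < tree.threshold[i]).any()
                assert (col > tree.threshold[i]).any()
                assert tree.threshold[i] not in col


def _toy_boost_data(n=200, seed=1):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 3))
    eta = -0.5 + 1.2 * X[:, 0]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return pd.DataFrame(X, columns=["x1", "x2", "x3"]), y


class TestBoosting:
    def test_single_newton_step_matches_hand_computation(self):
        """lambda=1, full bag, stump, 1 iteration: F = F0 + gamma per leaf,
        with gamma = sum(resid)/sum(p(1-p)) recomputed independently here."""
        X = pd.DataFrame({"x": [0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0]})
        y = np.array([0, 0, 0, 1, 1, 1, 1, 0], dtype=float)
        cfg = sv.BoostConfig(shrinkage=1.0, bag_fraction=1.0, max_terminal_nodes=2,
                             max_iterations=1, train_fraction=0.5, min_node_size=1,
                             seed=5)
        res = sv.BernoulliBoost(y, X, cfg).fit()
        tr = res.train_idx
        ybar = y[tr].mean()
        F0 = np.log(ybar / (1 - ybar))
        assert res.F0 == pytest.approx(F0)
        assert len(res.trees) == 1
        p0 = 1 / (1 + np.exp(-F0))
        resid = y[tr] - p0
        xtr = X.to_numpy()[tr, 0]
        for side in (0.0, 1.0):
            sel = xtr == side
            if sel.sum() == 0:
                continue
            gamma = resid[sel].sum() / (sel.sum() * p0 * (1 - p0))
            pred_rows = np.where(X["x"].to_numpy() == side)[0]
            expected_p = 1 / (1 + np.exp(-(F0 + gamma)))
            got = res.predict(X.iloc[pred_rows])
            if res.best_iteration == 1:
                assert np.allclose(got, expected_p, atol=1e-12)

    def test_zero_trees_predicts_constant(self):
        X, y = _toy_boost_data()
        cfg = sv.BoostConfig(shrinkage=0.1, max_iterations=1, seed=2)
        res = sv.BernoulliBoost(y, X, cfg).fit()
        res.best_iteration = 0
        p = res.predict(X)
        assert np.allclose(p, 1 / (1 + np.exp(-res.F0)))

    def test_vanishing_shrinkage_keeps_predictions_near_constant(self):
        X, y = _toy_boost_data()
        cfg = sv.BoostConfig(shrinkage=1e-8, max_iterations=1, patience=0, seed=3)
        res = sv.BernoulliBoost(y, X, cfg).fit()
        p = res.predict(X)
        assert np.abs(p - 1 / (1 + np.exp(-res.F0))).max() < 1e-6

    def test_stopping_keeps_at_least_constant_model(self):
        X, y = _toy_boost_data(n=500, seed=4)
        cfg = sv.BoostConfig(shrinkage=0.05, max_iterations=200, patience=5, seed=4)
        res = sv.BernoulliBoost(y, X, cfg).fit()
        assert res.best_iteration <= 200
        assert res.val_loglik[res.best_iteration] >= res.val_loglik[0]

    def test_determinism(self):
        X, y = _toy_boost_data(n=300, seed=6)
        cfg = sv.BoostConfig(shrinkage=0.05, max_iterations=50, patience=5, seed=7)
        a = sv.BernoulliBoost(y, X, cfg).fit()
        b = sv.BernoulliBoost(y, X, cfg).fit()
        assert a.best_iteration == b.best_iteration
        assert np.array_equal(a.predict(X), b.predict(X))
        assert a.variable_importance().equals(b.variable_importance())

    def test_bagging_eventually_covers_every_training_row(self):
        X, y = _toy_boost_data(n=300, seed=8)
        cfg = sv.BoostConfig(shrinkage=0.01, bag_fraction=0.5, max_iterations=200,
                             patience=200, seed=9)
        res = sv.BernoulliBoost(y, X, cfg).fit()
        assert res.bag_coverage == 1.0

    def test_unknown_column_rejected(self):
        X, y = _toy_boost_data()
        cfg = sv.BoostConfig(shrinkage=0.1, max_iterations=5, patience=5, seed=1)
        res = sv.BernoulliBoost(y, X, cfg).fit()
        with pytest.raises(ConfigurationError):
            res.predict(X.rename(columns={"x1": "other"}))

    def test_json_round_trip_reproduces_predictions(self):
        X, y = _toy_boost_data(n=300, seed=21)
        cfg = sv.BoostConfig(shrinkage=0.05, max_iterations=40, patience=5, seed=22)
        res = sv.BernoulliBoost(y, X, cfg).fit()
        back = sv.BoostResults.from_json(res.to_json())
        assert np.allclose(back.predict(X), res.predict(X), atol=0)

    def test_runs_on_incomplete_data(self):
        X, y = _toy_boost_data(n=400, seed=10)
        X.loc[::5, "x1"] = np.nan
        cfg = sv.BoostConfig(shrinkage=0.05, max_iterations=50, patience=5, seed=11)
        res = sv.BernoulliBoost(y, X, cfg).fit()
        p = res.predict(X)
        assert np.isfinite(p).all() and (0 < p).all() and (p < 1).all()


class TestImportance:
    def test_normalization_sums_to_hundred(self):
        X, y = _toy_boost_data(n=400, seed=12)
        cfg = sv.BoostConfig(shrinkage=0.05, max_iterations=100, patience=10, seed=13)
        imp = sv.BernoulliBoost(y, X, cfg).fit().variable_importance()
        assert imp.sum() == pytest.approx(100.0, abs=1e-9)
        assert (imp >= 0).all()

    def test_informative_predictor_dominates(self):
        X, y = _toy_boost_data(n=1000, seed=14)
        cfg = sv.BoostConfig(shrinkage=0.05, max_iterations=150, patience=10, seed=15)
        imp = sv.BernoulliBoost(y, X, cfg).fit().variable_importance()
        assert imp["x1"] > imp["x2"] and imp["x1"] > imp["x3"]

    def test_no_splits_warns_and_returns_zero(self):
        X = pd.DataFrame({"x": np.zeros(50)})  # unsplittable predictor
        y = np.tile([0.0, 1.0], 25)
        cfg = sv.BoostConfig(shrinkage=0.1, max_iterations=3, patience=3,
                             min_node_size=1, seed=16)
        res = sv.BernoulliBoost(y, X, cfg).fit()
        with pytest.warns(UserWarning, match="no splits"):
            imp = res.variable_importance()
        assert (imp == 0).all()


class TestPseudoR2:
    def test_constant_model_gives_zero(self):
        X, y = _toy_boost_data()
        cfg = sv.BoostConfig(shrinkage=0.1, max_iterations=1, seed=17)
        res = sv.BernoulliBoost(y, X, cfg).fit()
        res.best_iteration = 0
        # model predicting the mean of the evaluated rows -> 0 by construction
        y_bal = np.tile([0.0, 1.0], len(y) // 2)
        res.F0 = 0.0  # logistic(0) = 0.5 = mean of y_bal
        assert res.pseudo_r2(X, y_bal) == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_likelihood_ratio(self):
        X, y = _toy_boost_data(n=200, seed=18)
        cfg = sv.BoostConfig(shrinkage=0.1, max_iterations=20, patience=5, seed=19)
        res = sv.BernoulliBoost(y, X, cfg).fit()
        p = np.clip(res.predict(X), 1e-12, 1 - 1e-12)
        ll_model = (y * np.log(p) + (1 - y) * np.log(1 - p)).sum()
        pbar = y.mean()
        ll_null = (y * np.log(pbar) + (1 - y) * np.log(1 - pbar)).sum()
        assert res.pseudo_r2(X, y) == pytest.approx(1 - ll_model / ll_null, abs=1e-9)

    def test_single_class_outcome_rejected(self):
        X, y = _toy_boost_data()
        cfg = sv.BoostConfig(shrinkage=0.1, max_iterations=2, patience=2, seed=20)
        res = sv.BernoulliBoost(y, X, cfg).fit()
        with pytest.raises(ConfigurationError):
            res.pseudo_r2(X, np.ones(len(y)))
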