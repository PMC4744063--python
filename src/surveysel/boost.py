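"""Stochastic gradient-boosted regression trees for a binary outcome.

A from-scratch MART-style booster with Bernoulli loss: an additive model of
small regression trees, each fit to the pseudo-residuals y - p of the
current ensemble on a random bag of training rows, with leaf values replaced
by the one-step Newton estimate, shrinkage lambda on every tree's
contribution, and validation-based early stopping.  Per-variable relative
importance is the per-tree average of squared-error split improvements,
normalized to sum to 100%.

Rows with a missing value for a split variable are excluded from that
split's improvement computation and routed to the child that received more
training rows, so the booster runs directly on incomplete data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = ["BoostConfig", "RegressionTree", "BernoulliBoost", "BoostResults",
           "fit_regression_tree"]


@dataclass
class BoostConfig:
    """Boosting hyperparameters.

    ``shrinkage`` is the multiplier lambda on each tree's contribution;
    ``bag_fraction`` the share of training rows drawn (without replacement)
    per iteration; ``train_fraction`` the share of rows used for training
    versus validation-based stopping; ``patience`` the number of consecutive
    non-improving validation evaluations tolerated before stopping (0 =
    strict first-non-improvement).
    """

    shrinkage: float = 0.001
    bag_fraction: float = 0.5
    max_terminal_nodes: int = 5
    max_iterations: int = 10_000
    train_fraction: float = 0.6
    min_node_size: int = 10
    patience: int = 0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.shrinkage <= 1:
            raise ConfigurationError("shrinkage must lie in (0, 1]")
        if not 0 < self.bag_fraction <= 1:
            raise ConfigurationError("bag_fraction must lie in (0, 1]")
        if self.max_terminal_nodes < 2:
            raise ConfigurationError("max_terminal_nodes must be >= 2")
        if not 0 < self.train_fraction < 1:
            raise ConfigurationError("train_fraction must lie in (0, 1)")


class RegressionTree:
    """Binary regression tree stored as parallel node arrays.

    Internal nodes carry (feature, threshold, squared-error improvement);
    leaves carry a fitted value.  ``majority_left`` records, per internal
    node, whether rows missing the split feature route left (the child that
    received more training rows).
    """

    __slots__ = ("feature", "threshold", "left", "right", "value",
                 "improvement", "majority_left", "n_node")

    def __init__(self):
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.value: list[float] = []
        self.improvement: list[float] = []
        self.majority_left: list[bool] = []
        self.n_node: list[int] = []

    def _new_node(self, value, n):
        self.feature.append(-1)
        self.threshold.append(np.nan)
        self.left.append(-1)
        self.right.append(-1)
        self.value.append(float(value))
        self.improvement.append(0.0)
        self.majority_left.append(True)
        self.n_node.append(int(n))
        return len(self.value) - 1

    @property
    def n_leaves(self) -> int:
        return sum(1 for f in self.feature if f < 0)

    def leaf_ids(self):
        return [i for i, f in enumerate(self.feature) if f < 0]

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf index for every row of X (NaN routed to the majority child)."""
        node = np.zeros(len(X), dtype=int)
        pending = [0]
        while pending:
            i = pending.pop()
            if self.feature[i] < 0:
                continue
            sel = node == i
            x = X[sel, self.feature[i]]
            with np.errstate(invalid="ignore"):
                go_left = x <= self.threshold[i]
            go_left[np.isnan(x)] = self.majority_left[i]
            nxt = np.where(go_left, self.left[i], self.right[i])
            node[sel] = nxt
            pending.extend([self.left[i], self.right[i]])
        return node

    def predict(self, X: np.ndarray) -> np.ndarray:
        values = np.asarray(self.value)
        return values[self.apply(X)]

    def per_feature_improvement(self, n_features: int) -> np.ndarray:
        out = np.zeros(n_features)
        for f, imp in zip(self.feature, self.improvement):
            if f >= 0:
                out[f] += imp
        return out

    def to_dict(self) -> dict:
        return {
            "feature": list(self.feature),
            "threshold": [None if np.isnan(t) else t for t in self.threshold],
            "left": list(self.left),
            "right": list(self.right),
            "value": list(self.value),
            "improvement": list(self.improvement),
            "majority_left": list(self.majority_left),
            "n_node": list(self.n_node),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        tree = cls()
        tree.feature = list(d["feature"])
        tree.threshold = [np.nan if t is None else float(t) for t in d["threshold"]]
        tree.left = list(d["left"])
        tree.right = list(d["right"])
        tree.value = [float(v) for v in d["value"]]
        tree.improvement = [float(v) for v in d["improvement"]]
        tree.majority_left = [bool(b) for b in d["majority_left"]]
        tree.n_node = [int(v) for v in d["n_node"]]
        return tree


def _best_split(X, r, rows, min_node_size):
    """Exhaustive best split for one leaf: (improvement, feature, threshold).

    Improvement is the reduction in residual sum of squares over the rows
    with an observed value of the split feature.  Ties are broken toward the
    lowest feature index, then the smallest threshold (both achieved by scan
    order with strict improvement comparison).
    """
    best = (0.0, -1, np.nan)
    r_rows = r[rows]
    for j in range(X.shape[1]):
        x = X[rows, j]
        obs = ~np.isnan(x)
        xo = x[obs]
        n = len(xo)
        if n < 2 * min_node_size:
            continue
        order = np.argsort(xo, kind="mergesort")
        xs = xo[order]
        rs = r_rows[obs][order]
        cum = np.cumsum(rs)
        S = cum[-1]
        nl = np.arange(1, n)
        valid = (nl >= min_node_size) & (nl <= n - min_node_size) & (xs[:-1] < xs[1:])
        if not valid.any():
            continue
        cl = cum[:-1]
        with np.errstate(invalid="ignore", divide="ignore"):
            delta = cl ** 2 / nl + (S - cl) ** 2 / (n - nl) - S ** 2 / n
        delta[~valid] = -np.inf
        i = int(np.argmax(delta))  # first max = smallest threshold
        if np.isfinite(delta[i]) and delta[i] > best[0]:
            best = (float(delta[i]), j, float((xs[i] + xs[i + 1]) / 2))
    return best


def fit_regression_tree(X, r, max_terminal_nodes: int, min_node_size: int = 10) -> RegressionTree:
    """Greedy best-first regression tree on residual targets.

    Repeatedly splits the leaf whose best split maximally reduces the
    residual sum of squares until ``max_terminal_nodes`` leaves are reached
    or no admissible split remains.  Leaf values are mean residuals (the
    booster later replaces them with Newton steps).  Constant residuals give
    a single-leaf tree.
    """
    X = np.asarray(X, dtype=float)
    r = np.asarray(r, dtype=float)
    tree = RegressionTree()
    root = tree._new_node(r.mean() if len(r) else 0.0, len(r))
    leaf_rows = {root: np.arange(len(r))}
    candidates = {root: _best_split(X, r, leaf_rows[root], min_node_size)}
    while tree.n_leaves < max_terminal_nodes:
        # earliest-created leaf wins ties (strict > in creation order)
        best_leaf, best_cand = -1, (0.0, -1, np.nan)
        for leaf in sorted(leaf_rows):
            cand = candidates[leaf]
            if cand[1] >= 0 and cand[0] > best_cand[0]:
                best_leaf, best_cand = leaf, cand
        if best_leaf < 0:
            break
        imp, j, thr = best_cand
        rows = leaf_rows.pop(best_leaf)
        x = X[rows, j]
        with np.errstate(invalid="ignore"):
            go_left = x <= thr
        obs = ~np.isnan(x)
        n_left_obs = int((go_left & obs).sum())
        n_right_obs = int((obs & ~go_left).sum())
        majority_left = n_left_obs >= n_right_obs
        go_left[~obs] = majority_left
        lrows, rrows = rows[go_left], rows[~go_left]
        lid = tree._new_node(r[lrows].mean() if len(lrows) else 0.0, len(lrows))
        rid = tree._new_node(r[rrows].mean() if len(rrows) else 0.0, len(rrows))
        tree.feature[best_leaf] = j
        tree.threshold[best_leaf] = thr
        tree.left[best_leaf] = lid
        tree.right[best_leaf] = rid
        tree.improvement[best_leaf] = imp
        tree.majority_left[best_leaf] = majority_left
        del candidates[best_leaf]
        leaf_rows[lid], leaf_rows[rid] = lrows, rrows
        candidates[lid] = _best_split(X, r, lrows, min_node_size)
        candidates[rid] = _best_split(X, r, rrows, min_node_size)
    return tree


def _bernoulli_ll(y, p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


class BernoulliBoost:
    """Boosted-trees model for a binary outcome.

    Parameters
    ----------
    endog : array of 0/1
    exog : DataFrame or array of predictors (NaN allowed)
    config : BoostConfig
    """

    def __init__(self, endog, exog, config: BoostConfig | None = None):
        exog = pd.DataFrame(exog)
        self.feature_names = list(exog.columns)
        self.X = exog.to_numpy(dtype=float)
        self.y = np.asarray(endog, dtype=float)
        if len(self.X) != len(self.y):
            raise ConfigurationError("endog and exog lengths differ")
        self.config = config if config is not None else BoostConfig()

    def fit(self) -> "BoostResults":
        cfg = self.config
        X, y = self.X, self.y
        n = len(y)
        rng = np.random.default_rng(cfg.seed)
        perm = rng.permutation(n)
        n_train = int(round(cfg.train_fraction * n))
        train_idx, val_idx = perm[:n_train], perm[n_train:]
        y_train, y_val = y[train_idx], y[val_idx]
        if len(np.unique(y_train)) < 2:
            raise ConfigurationError("training outcome has a single class")

        pbar = y_train.mean()
        F0 = float(np.log(pbar / (1 - pbar)))
        F = np.full(n, F0)
        bag_size = int(np.ceil(cfg.bag_fraction * n_train))
        if bag_size == 0:
            raise ConfigurationError("empty bag")

        val_ll = [_bernoulli_ll(y_val, 1 / (1 + np.exp(-F[val_idx])))]
        trees: list[RegressionTree] = []
        best_ll, best_iter, since_best = val_ll[0], 0, 0
        bag_seen = np.zeros(n_train, dtype=bool)
        for _it in range(1, cfg.max_iterations + 1):
            p_train = 1 / (1 + np.exp(-F[train_idx]))
            resid = y_train - p_train
            bag_local = rng.choice(n_train, size=bag_size, replace=False)
            bag_seen[bag_local] = True
            bag = train_idx[bag_local]
            tree = fit_regression_tree(X[bag], resid[bag_local],
                                       cfg.max_terminal_nodes, cfg.min_node_size)
            # replace leaf means with Newton steps computed on the bag
            leaf_of = tree.apply(X[bag])
            r_bag = resid[bag_local]
            h_bag = p_train[bag_local] * (1 - p_train[bag_local])
            for leaf in tree.leaf_ids():
                sel = leaf_of == leaf
                denom = max(h_bag[sel].sum(), 1e-8)
                tree.value[leaf] = float(r_bag[sel].sum() / denom)
            F = F + cfg.shrinkage * tree.predict(X)
            trees.append(tree)
            ll = _bernoulli_ll(y_val, 1 / (1 + np.exp(-F[val_idx])))
            val_ll.append(ll)
            if ll > best_ll:
                best_ll, best_iter, since_best = ll, _it, 0
            else:
                since_best += 1
                if since_best > cfg.patience:
                    break
        return BoostResults(
            model=self, F0=F0, trees=trees, shrinkage=cfg.shrinkage,
            best_iteration=best_iter, val_loglik=np.asarray(val_ll),
            train_idx=train_idx, val_idx=val_idx, bag_coverage=float(bag_seen.mean()),
        )


@dataclass
class BoostResults:
    """Fitted boosted ensemble: prediction, importance, pseudo-R2."""

    model: BernoulliBoost
    F0: float
    trees: list
    shrinkage: float
    best_iteration: int
    val_loglik: np.ndarray
    train_idx: np.ndarray = field(repr=False, default=None)
    val_idx: np.ndarray = field(repr=False, default=None)
    bag_coverage: float = np.nan

    @property
    def feature_names(self):
        return self.model.feature_names

    def decision_function(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        unknown = [c for c in self.feature_names if c not in X.columns]
        if unknown:
            raise ConfigurationError(f"missing predictor columns: {unknown}")
        Xa = X[self.feature_names].to_numpy(dtype=float)
        F = np.full(len(Xa), self.F0)
        for tree in self.trees[: self.best_iteration]:
            F += self.shrinkage * tree.predict(Xa)
        return F

    def predict(self, X) -> np.ndarray:
        """Probabilities logistic(F0 + lambda * sum of retained trees)."""
        return 1 / (1 + np.exp(-self.decision_function(X)))

    def variable_importance(self) -> pd.Series:
        """Relative importance percentages, summing to exactly 100.

        Raw importance of a variable is the sum of squared-error improvements
        of its splits across the retained trees divided by the number of
        retained trees; never-split variables score 0.
        """
        k = len(self.feature_names)
        raw = np.zeros(k)
        retained = self.trees[: self.best_iteration]
        for tree in retained:
            raw += tree.per_feature_improvement(k)
        if retained:
            raw /= len(retained)
        total = raw.sum()
        if total <= 0:
            warnings.warn("no splits in any retained tree; importance undefined (all zero)")
            return pd.Series(raw, index=self.feature_names)
        return pd.Series(100.0 * raw / total, index=self.feature_names)

    def to_json(self) -> str:
        """Serialize the fitted ensemble (F0, shrinkage, tree arrays)."""
        import json

        return json.dumps({
            "F0": self.F0,
            "shrinkage": self.shrinkage,
            "best_iteration": self.best_iteration,
            "feature_names": self.feature_names,
            "trees": [t.to_dict() for t in self.trees[: self.best_iteration]],
        })

    @classmethod
    def from_json(cls, text: str) -> "BoostResults":
        """Rebuild a prediction-capable results object from :meth:`to_json`."""
        import json

        d = json.loads(text)
        model = BernoulliBoost(np.zeros(0), pd.DataFrame(columns=d["feature_names"]))
        return cls(model=model, F0=float(d["F0"]),
                   trees=[RegressionTree.from_dict(t) for t in d["trees"]],
                   shrinkage=float(d["shrinkage"]),
                   best_iteration=int(d["best_iteration"]),
                   val_loglik=np.zeros(0))

    def pseudo_r2(self, X, y) -> float:
        """1 - ll_model / ll_null on the supplied rows (null = their mean)."""
        y = np.asarray(y, dtype=float)
        if len(np.unique(y)) < 2:
            raise ConfigurationError("pseudo-R2 undefined for a single-class outcome")
        p = self.predict(X)
        ll_model = _bernoulli_ll(y, p)
        ll_null = _bernoulli_ll(y, np.full(len(y), y.mean()))
        return 1.0 - ll_model / ll_null
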