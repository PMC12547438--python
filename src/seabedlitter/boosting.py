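"""From-scratch gradient-boosted regression trees with squared-error loss.

The model underlying the storage-potential analysis is

    MP = f(X1, ..., Xp),

with ``f`` an additive ensemble of small regression trees fitted
stage-wise to residuals: ``f(x) = baseline + shrinkage * sum_m T_m(x)``.
The survey configuration uses depth-1 trees (stumps), 400 of them, with a
minimum of 10 observations per terminal node; shrinkage and row
subsampling follow the conventional defaults of the gbm family (0.1 and
0.5) and are exposed as parameters.

Split rule
----------
Greedy squared-error reduction. Candidate thresholds are midpoints between
consecutive distinct sorted values of a feature; a row goes right iff
``x > threshold``; both children must contain at least ``minobs`` training
rows; ties in reduction are broken toward the lowest feature index, then
the lowest threshold. Leaf values are in-leaf target means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._stump_kernel import _fit_stump_ensemble, _predict_stumps

__all__ = [
    "BoostParams",
    "RegressionTree",
    "BoostedModel",
    "fit_tree",
    "fit_boosted_model",
    "predict_model",
    "partial_dependence",
]


@dataclass(frozen=True)
class BoostParams:
    """Boosting hyperparameters.

    ``ntrees``/``depth``/``minobs`` default to the survey configuration
    (400 / 1 / 10); ``depth`` counts sequential split levels, so depth 1
    is a stump.
    """

    ntrees: int = 400
    depth: int = 1
    minobs: int = 10
    shrinkage: float = 0.1
    bag_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntrees < 0:
            raise ValueError("ntrees must be >= 0")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.minobs < 1:
            raise ValueError("minobs must be >= 1")
        if not (0.0 < self.shrinkage <= 1.0):
            raise ValueError("shrinkage must be in (0, 1]")
        if not (0.0 < self.bag_fraction <= 1.0):
            raise ValueError("bag_fraction must be in (0, 1]")

    def with_seed(self, seed: int) -> "BoostParams":
        return replace(self, seed=int(seed))


@dataclass
class RegressionTree:
    """A binary regression tree node.

    Either a leaf (``leaf_value`` set) or an internal node with
    ``split_feature``/``split_threshold`` and two children. Rows with
    feature value strictly greater than the threshold go right.
    """

    leaf_value: float | None = None
    split_feature: str | None = None
    split_threshold: float | None = None
    left: "RegressionTree | None" = None
    right: "RegressionTree | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.leaf_value is not None

    def predict(self, X: np.ndarray, feature_index: dict[str, int]) -> np.ndarray:
        """Evaluate the tree on an (n, p) array."""
        out = np.empty(X.shape[0])
        self._fill(X, feature_index, np.arange(X.shape[0]), out)
        return out

    def _fill(self, X, feature_index, rows, out) -> None:
        if self.is_leaf:
            out[rows] = self.leaf_value
            return
        col = X[rows, feature_index[self.split_feature]]
        go_right = col > self.split_threshold
        self.right._fill(X, feature_index, rows[go_right], out)
        self.left._fill(X, feature_index, rows[~go_right], out)

    def max_depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.max_depth(), self.right.max_depth())

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"leaf": self.leaf_value}
        return {
            "feature": self.split_feature,
            "threshold": self.split_threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        if "leaf" in d:
            return cls(leaf_value=float(d["leaf"]))
        return cls(
            split_feature=d["feature"],
            split_threshold=float(d["threshold"]),
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


def _as_matrix(features, feature_names=None):
    """Coerce a DataFrame or array to (X float64 C-order, names)."""
    if isinstance(features, pd.DataFrame):
        names = list(features.columns) if feature_names is None else list(feature_names)
        X = np.ascontiguousarray(features[names].to_numpy(dtype=np.float64))
    else:
        X = np.ascontiguousarray(np.asarray(features, dtype=np.float64))
        if X.ndim == 1:
            X = X[:, None]
        if feature_names is None:
            names = [f"x{j}" for j in range(X.shape[1])]
        else:
            names = list(feature_names)
    return X, names


def _best_split(X, t, rows, minobs):
    """Greedy best split of a node.

    Returns (feature_idx, threshold, left_rows, right_rows, left_mean,
    right_mean) or None. Same scan order and arithmetic as the compiled
    stump kernel, so both paths pick identical splits.
    """
    n = rows.size
    if n < 2 * minobs:
        return None
    vals = t[rows]
    S = 0.0
    for v in vals:
        S += v
    mean = S / n
    node_sse = float(np.sum((vals - mean) ** 2))

    best_gain = -np.inf
    best = None
    for f in range(X.shape[1]):
        col = X[rows, f]
        order = np.argsort(col, kind="stable")
        vv = col[order]
        rr = vals[order]
        SL = 0.0
        for s in range(n - 1):
            SL += rr[s]
            if vv[s] == vv[s + 1]:
                continue
            nL = s + 1
            nR = n - nL
            if nL < minobs or nR < minobs:
                continue
            SR = S - SL
            gain = SL * SL / nL + SR * SR / nR
            if gain > best_gain:
                best_gain = gain
                best = (f, (vv[s] + vv[s + 1]) / 2.0, nL, SL / nL, SR / nR)
    if best is None:
        return None
    # require a strict squared-error reduction relative to the node SSE
    reduction = best_gain - S * S / n
    if reduction <= 1e-12 * max(node_sse, 1e-300):
        return None
    f, thr, _, lmean, rmean = best
    go_right = X[rows, f] > thr
    return f, thr, rows[~go_right], rows[go_right], lmean, rmean


def fit_tree(
    features,
    targets,
    depth: int = 1,
    minobs: int = 1,
    feature_names: Sequence[str] | None = None,
) -> RegressionTree:
    """Fit a greedy least-squares regression tree.

    ``depth`` limits sequential split levels (1 = stump). If no candidate
    split leaves ``minobs`` rows on both sides (or none reduces the
    squared error), the node becomes a leaf with the target mean.
    """
    X, names = _as_matrix(features, feature_names)
    t = np.asarray(targets, dtype=np.float64)
    if X.shape[0] == 0 or t.size == 0:
        raise ValueError("cannot fit a tree on empty input")
    if X.shape[0] != t.size:
        raise ValueError("features and targets disagree on row count")

    def build(rows: np.ndarray, level: int) -> RegressionTree:
        if level >= depth:
            return RegressionTree(leaf_value=float(np.mean(t[rows])))
        split = _best_split(X, t, rows, minobs)
        if split is None:
            return RegressionTree(leaf_value=float(np.mean(t[rows])))
        f, thr, lrows, rrows, _, _ = split
        return RegressionTree(
            split_feature=names[f],
            split_threshold=float(thr),
            left=build(lrows, level + 1),
            right=build(rrows, level + 1),
        )

    return build(np.arange(X.shape[0]), 0)


@dataclass
class BoostedModel:
    """An additive stump/tree ensemble: ``baseline + shrinkage * sum(trees)``."""

    baseline: float
    shrinkage: float
    feature_names: list[str]
    fitted_values: np.ndarray | None = None
    _stumps: tuple | None = field(default=None, repr=False)
    _trees: list[RegressionTree] | None = field(default=None, repr=False)

    @property
    def ntrees(self) -> int:
        if self._stumps is not None:
            return self._stumps[0].shape[0]
        return len(self._trees or [])

    @property
    def trees(self) -> list[RegressionTree]:
        """Tree objects (materialised lazily from the stump arrays)."""
        if self._trees is None:
            feat, thr, lv, rv = self._stumps
            trees = []
            for j in range(feat.shape[0]):
                if feat[j] < 0:
                    trees.append(RegressionTree(leaf_value=float(lv[j])))
                else:
                    trees.append(
                        RegressionTree(
                            split_feature=self.feature_names[feat[j]],
                            split_threshold=float(thr[j]),
                            left=RegressionTree(leaf_value=float(lv[j])),
                            right=RegressionTree(leaf_value=float(rv[j])),
                        )
                    )
            self._trees = trees
        return self._trees

    def predict(self, rows) -> np.ndarray:
        """Evaluate the ensemble on a DataFrame or (n, p) array."""
        if isinstance(rows, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in rows.columns]
            if missing:
                raise ValueError(f"missing feature columns: {missing}")
            X = np.ascontiguousarray(
                rows[self.feature_names].to_numpy(dtype=np.float64)
            )
        else:
            X = np.ascontiguousarray(np.asarray(rows, dtype=np.float64))
            if X.ndim == 1:
                X = X[None, :]
            if X.shape[1] != len(self.feature_names):
                raise ValueError("row width does not match model features")
        if self._stumps is not None:
            feat, thr, lv, rv = self._stumps
            return _predict_stumps(X, feat, thr, lv, rv, self.baseline, self.shrinkage)
        out = np.full(X.shape[0], self.baseline)
        fidx = {name: j for j, name in enumerate(self.feature_names)}
        for tree in self.trees:
            out += self.shrinkage * tree.predict(X, fidx)
        return out

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline,
            "shrinkage": self.shrinkage,
            "feature_names": list(self.feature_names),
            "trees": [t.to_dict() for t in self.trees],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "BoostedModel":
        return cls(
            baseline=float(d["baseline"]),
            shrinkage=float(d["shrinkage"]),
            feature_names=list(d["feature_names"]),
            _trees=[RegressionTree.from_dict(td) for td in d["trees"]],
        )

    @classmethod
    def from_json(cls, path) -> "BoostedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _bag_matrix(seed: int, ntrees: int, n: int, bag_fraction: float) -> np.ndarray:
    """Per-tree without-replacement row masks, (ntrees, n) bool.

    Row m is a pure function of (seed, m, n): the uniform draws are
    generated row-major, so adding trees never changes earlier bags.
    """
    if bag_fraction >= 1.0:
        return np.ones((ntrees, n), dtype=bool)
    nbag = max(1, int(np.floor(bag_fraction * n)))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, n]))
    u = rng.random((ntrees, n))
    keep = np.argsort(u, axis=1, kind="stable")[:, :nbag]
    mask = np.zeros((ntrees, n), dtype=bool)
    np.put_along_axis(mask, keep, True, axis=1)
    return mask


def _fit_arrays(X: np.ndarray, y: np.ndarray, params: BoostParams, names: list[str]) -> BoostedModel:
    """Array-level fit shared by the DataFrame API and the LOO hot loop."""
    n = X.shape[0]
    if params.ntrees == 0:
        baseline = float(np.mean(y))
        return BoostedModel(
            baseline=baseline,
            shrinkage=params.shrinkage,
            feature_names=names,
            fitted_values=np.full(n, baseline),
            _trees=[],
        )
    in_bag = _bag_matrix(params.seed, params.ntrees, n, params.bag_fraction)
    if params.depth == 1:
        sort_idx = np.ascontiguousarray(np.argsort(X, axis=0, kind="stable").T)
        baseline, feat, thr, lv, rv, fitted = _fit_stump_ensemble(
            X, y, sort_idx, in_bag, params.minobs, params.shrinkage
        )
        return BoostedModel(
            baseline=float(baseline),
            shrinkage=params.shrinkage,
            feature_names=names,
            fitted_values=fitted,
            _stumps=(feat, thr, lv, rv),
        )
    baseline = float(np.mean(y))
    fitted = np.full(n, baseline)
    fidx = {name: j for j, name in enumerate(names)}
    trees: list[RegressionTree] = []
    for m in range(params.ntrees):
        rows = np.flatnonzero(in_bag[m])
        resid = y[rows] - fitted[rows]
        tree = fit_tree(
            X[rows], resid, depth=params.depth, minobs=params.minobs,
            feature_names=names,
        )
        trees.append(tree)
        fitted += params.shrinkage * tree.predict(X, fidx)
    return BoostedModel(
        baseline=baseline,
        shrinkage=params.shrinkage,
        feature_names=names,
        fitted_values=fitted,
        _trees=trees,
    )


def fit_boosted_model(
    table: pd.DataFrame,
    response_name: str,
    predictor_names: Sequence[str],
    params: BoostParams,
) -> BoostedModel:
    """Fit the boosted ensemble on untransformed response values.

    The baseline is the training-response mean; each stage fits a tree to
    current residuals on a ``bag_fraction`` row subsample and every fitted
    value is updated by ``shrinkage *`` the tree's output.
    """
    predictor_names = list(predictor_names)
    missing = [c for c in [response_name, *predictor_names] if c not in table.columns]
    if missing:
        raise ValueError(f"columns not in table: {missing}")
    X = np.ascontiguousarray(table[predictor_names].to_numpy(dtype=np.float64))
    y = np.ascontiguousarray(table[response_name].to_numpy(dtype=np.float64))
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite response or predictor values")
    if X.shape[0] == 0:
        raise ValueError("empty training table")
    return _fit_arrays(X, y, params, predictor_names)


def predict_model(model: BoostedModel, rows) -> np.ndarray:
    """Row-wise ensemble prediction (functional alias of ``model.predict``)."""
    return model.predict(rows)


def partial_dependence(
    model: BoostedModel,
    table: pd.DataFrame,
    feature: str,
    grid: Sequence[float],
):
    """Average prediction with one feature clamped to each grid value.

    For each grid value v, every row of ``table`` has ``feature`` forced
    to v and the model's predictions are averaged — the effect of one
    explanatory variable with all the others held at their observed
    values.
    """
    if feature not in model.feature_names:
        raise ValueError(f"unknown feature {feature!r}")
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    work = table[model.feature_names].copy()
    curve = np.empty(grid.size)
    for i, v in enumerate(grid):
        work[feature] = v
        curve[i] = float(np.mean(model.predict(work)))
    return grid, curve
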