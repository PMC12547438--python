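"""Replicated leave-one-out model selection for the boosted ensembles.

The selection procedure scores a candidate predictor subset by the
leave-one-out mean absolute error

    LOOMAE = (1/N) * sum_j | MP_j - MP̂_j |,

where MP̂_j is the prediction for case j from a model fitted on the other
N-1 cases. Absolute error avoids giving undue weight to isolated badly
predicted stations. Because boosting with row subsampling is stochastic,
the LOOMAE is averaged over replicate runs (100 in the original analysis).
Variables are ranked once by permutation importance on the full model and
added in that order; the subset size minimising the replicated LOOMAE is
the best model.

The permutation-importance estimator used here is the training-set MAE
increase when one predictor column is shuffled, averaged over replicate
refits — one member of the standard permutation-importance family, chosen
for determinism and desk-scale cost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_seed, rng_from
from .boosting import BoostParams, _fit_arrays

__all__ = [
    "LooResult",
    "SelectionCurve",
    "loo_predictions",
    "replicated_loomae",
    "permutation_importance",
    "selection_curve",
    "select_best_model",
    "tune_parameters",
]

_MOD = 2**31


@dataclass
class LooResult:
    """Per-case leave-one-out predictions and their mean absolute error."""

    per_case_prediction: np.ndarray
    abs_error: np.ndarray
    loomae: float


def _maybe_log(y: np.ndarray, log_transform: bool) -> np.ndarray:
    return np.log1p(y) if log_transform else y


def loo_predictions(
    table: pd.DataFrame,
    predictors: Sequence[str],
    params: BoostParams,
    response_name: str = "mp_count",
    log_transform: bool = False,
) -> LooResult:
    """Leave-one-out predictions: case j predicted by a fit on the rest.

    The per-case fit seed is the params seed offset by j. With
    ``log_transform`` the model is fitted on log1p counts and predictions
    are back-transformed before the (original-scale) absolute error; the
    switch is off by default — the analysis uses untransformed counts.
    """
    n = len(table)
    if n < 2:
        raise ValueError("leave-one-out needs at least 2 cases")
    predictors = list(predictors)
    y = table[response_name].to_numpy(dtype=np.float64)
    X = np.ascontiguousarray(table[predictors].to_numpy(dtype=np.float64))
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite response or predictor values")
    resp = _maybe_log(y, log_transform)

    preds = np.empty(n)
    keep = np.ones(n, dtype=bool)
    for j in range(n):
        keep[j] = False
        model = _fit_arrays(
            X[keep], resp[keep], params.with_seed((params.seed + j) % _MOD), predictors
        )
        keep[j] = True
        pred = float(model.predict(X[j : j + 1])[0])
        preds[j] = np.expm1(pred) if log_transform else pred
    abs_err = np.abs(y - preds)
    return LooResult(per_case_prediction=preds, abs_error=abs_err, loomae=float(abs_err.mean()))


def replicated_loomae(
    table: pd.DataFrame,
    predictors: Sequence[str],
    params: BoostParams,
    reps: int = 100,
    response_name: str = "mp_count",
    log_transform: bool = False,
    seed: int | None = None,
) -> tuple[float, float | None]:
    """Mean and sd of the LOOMAE over replicate runs with derived seeds.

    A run is a full leave-one-out pass with a fresh seed. The sd is None
    for a single rep (not 0: one run carries no spread information).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    base = params.seed if seed is None else seed
    vals = np.empty(reps)
    for r in range(reps):
        p_r = params.with_seed(derive_seed(base, "rep", r))
        vals[r] = loo_predictions(
            table, predictors, p_r, response_name=response_name,
            log_transform=log_transform,
        ).loomae
    sd = float(vals.std(ddof=1)) if reps > 1 else None
    return float(vals.mean()), sd


def permutation_importance(
    table: pd.DataFrame,
    predictors: Sequence[str],
    params: BoostParams,
    reps: int = 100,
    response_name: str = "mp_count",
    log_transform: bool = False,
) -> pd.DataFrame:
    """Permutation importance of each predictor under the full model.

    Per rep: refit the full model with a fresh seed, record its training
    MAE, then for each predictor shuffle that column and recompute the MAE
    with the *fitted* model; the importance contribution is the MAE
    increase. Returned as a DataFrame (predictor, mean_importance, sd,
    reps) — sampling noise can make individual values negative, so only
    ranking properties should be relied on.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    predictors = list(predictors)
    missing = [c for c in predictors if c not in table.columns]
    if missing:
        raise ValueError(f"predictors not in table: {missing}")
    y = table[response_name].to_numpy(dtype=np.float64)
    X = np.ascontiguousarray(table[predictors].to_numpy(dtype=np.float64))
    resp = _maybe_log(y, log_transform)

    contrib = np.empty((reps, len(predictors)))
    for r in range(reps):
        p_r = params.with_seed(derive_seed(params.seed, "pi", r))
        model = _fit_arrays(X, resp, p_r, predictors)

        def mae_of(pred_transformed: np.ndarray) -> float:
            pred = np.expm1(pred_transformed) if log_transform else pred_transformed
            return float(np.mean(np.abs(y - pred)))

        base_mae = mae_of(model.predict(X))
        for k in range(len(predictors)):
            rng = rng_from(params.seed, "piperm", r, k)
            Xp = X.copy()
            Xp[:, k] = Xp[rng.permutation(len(Xp)), k]
            contrib[r, k] = mae_of(model.predict(Xp)) - base_mae

    return pd.DataFrame(
        {
            "predictor": predictors,
            "mean_importance": contrib.mean(axis=0),
            "sd": contrib.std(axis=0, ddof=1) if reps > 1 else np.nan,
            "reps": reps,
        }
    )


@dataclass
class SelectionCurve:
    """Replicated LOOMAE as a function of model size.

    ``variable_order`` is the permutation-importance ranking (descending);
    entry k-1 of ``mean_loomae_by_size`` scores the model on the first k
    variables.
    """

    variable_order: list[str]
    mean_loomae_by_size: np.ndarray
    sd_loomae_by_size: np.ndarray
    reps: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": np.arange(1, len(self.variable_order) + 1),
                "added_variable": self.variable_order,
                "mean_loomae": self.mean_loomae_by_size,
                "sd_loomae": self.sd_loomae_by_size,
            }
        )


def selection_curve(
    table: pd.DataFrame,
    predictors: Sequence[str],
    params: BoostParams,
    reps: int = 100,
    response_name: str = "mp_count",
    log_transform: bool = False,
    importance: pd.DataFrame | None = None,
) -> SelectionCurve:
    """Importance-ordered forward selection scored by replicated LOOMAE.

    Variables enter by descending mean permutation importance (computed
    here unless a precomputed table is passed); each size 1..p is scored
    with its own derived seed stream.
    """
    predictors = list(predictors)
    if not predictors:
        raise ValueError("need at least one predictor")
    if importance is None:
        importance = permutation_importance(
            table, predictors, params, reps=reps,
            response_name=response_name, log_transform=log_transform,
        )
    order = (
        importance.sort_values("mean_importance", ascending=False, kind="stable")[
            "predictor"
        ].tolist()
    )
    means = np.empty(len(order))
    sds = np.empty(len(order))
    for k in range(1, len(order) + 1):
        m, s = replicated_loomae(
            table, order[:k], params, reps=reps, response_name=response_name,
            log_transform=log_transform, seed=derive_seed(params.seed, "curve", k),
        )
        means[k - 1] = m
        sds[k - 1] = np.nan if s is None else s
    return SelectionCurve(
        variable_order=order, mean_loomae_by_size=means,
        sd_loomae_by_size=sds, reps=reps,
    )


def select_best_model(curve: SelectionCurve) -> list[str]:
    """First k variables at the LOOMAE minimum; ties go to the smaller model."""
    if len(curve.variable_order) == 0:
        raise ValueError("empty selection curve")
    k = int(np.argmin(curve.mean_loomae_by_size)) + 1
    return curve.variable_order[:k]


def tune_parameters(
    table: pd.DataFrame,
    predictors: Sequence[str],
    grid: Sequence[BoostParams],
    reps: int = 100,
    response_name: str = "mp_count",
    log_transform: bool = False,
) -> BoostParams:
    """Pick the grid entry minimising replicated LOOMAE on all predictors.

    Ties are broken toward the earlier grid entry.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("parameter grid must be non-empty")
    best = None
    best_score = np.inf
    for i, p in enumerate(grid):
        if not isinstance(p, BoostParams):
            raise ValueError(f"grid entry {i} is not a BoostParams")
        score, _ = replicated_loomae(
            table, predictors, p, reps=reps, response_name=response_name,
            log_transform=log_transform, seed=derive_seed(p.seed, "tune", i),
        )
        if score < best_score:
            best_score = score
            best = p
    return best
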