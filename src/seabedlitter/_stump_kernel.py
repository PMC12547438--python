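"""Compiled inner loop for depth-1 boosted stump ensembles.

The replicated leave-one-out selection procedure refits hundreds of
thousands of small ensembles, so the stump search is written as plain
loops and compiled with numba. If numba is unavailable the same function
runs as pure Python (slow but identical arithmetic).

Split semantics (shared with :func:`seabedlitter.boosting.fit_tree`):
candidate thresholds are midpoints between consecutive distinct sorted
values; a row goes right iff ``x > threshold``; both children must hold at
least ``minobs`` in-bag rows; the best split maximises
``SL^2/nL + SR^2/nR`` (equivalent to squared-error reduction, since the
node total is constant); ties are broken toward the lowest feature index,
then the lowest threshold, by strict-improvement scanning order.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _fit_stump_ensemble(X, y, sort_idx, in_bag, minobs, shrinkage):
    """Fit a sequence of depth-1 trees to running residuals.

    Parameters
    ----------
    X : (n, p) float64
    y : (n,) float64
    sort_idx : (p, n) int64
        argsort of each feature column (precomputed once per dataset).
    in_bag : (ntrees, n) bool
        Row-subsample mask per tree; a tree with no legal split becomes a
        single leaf holding the bag-residual mean, so ntrees is honoured.
    minobs : int
        Minimum in-bag rows per terminal node.
    shrinkage : float

    Returns
    -------
    baseline, feat (ntrees; -1 for a single-leaf tree), thr, left_val,
    right_val, fitted (n,) training predictions.
    """
    n = X.shape[0]
    p = X.shape[1]
    ntrees = in_bag.shape[0]

    baseline = 0.0
    for i in range(n):
        baseline += y[i]
    baseline /= n

    resid = np.empty(n)
    for i in range(n):
        resid[i] = y[i] - baseline

    feat = np.full(ntrees, -1, dtype=np.int64)
    thr = np.full(ntrees, np.nan)
    left_val = np.zeros(ntrees)
    right_val = np.zeros(ntrees)

    vv = np.empty(n)
    rr = np.empty(n)

    for m in range(ntrees):
        # bag totals
        nb = 0
        S = 0.0
        for i in range(n):
            if in_bag[m, i]:
                nb += 1
                S += resid[i]

        best_gain = -np.inf
        best_f = -1
        best_thr = 0.0
        best_left = 0.0
        best_right = 0.0

        if nb >= 2 * minobs:
            for f in range(p):
                # in-bag rows in sorted order of feature f
                k = 0
                for s in range(n):
                    i = sort_idx[f, s]
                    if in_bag[m, i]:
                        vv[k] = X[i, f]
                        rr[k] = resid[i]
                        k += 1
                SL = 0.0
                for s in range(nb - 1):
                    SL += rr[s]
                    nL = s + 1
                    nR = nb - nL
                    if vv[s] == vv[s + 1]:
                        continue
                    if nL < minobs or nR < minobs:
                        continue
                    SR = S - SL
                    gain = SL * SL / nL + SR * SR / nR
                    if gain > best_gain:
                        best_gain = gain
                        best_f = f
                        best_thr = (vv[s] + vv[s + 1]) / 2.0
                        best_left = SL / nL
                        best_right = SR / nR

        if best_f < 0:
            # degenerate tree: single leaf of the bag-residual mean
            leaf = S / nb if nb > 0 else 0.0
            left_val[m] = leaf
            right_val[m] = leaf
            for i in range(n):
                resid[i] -= shrinkage * leaf
        else:
            feat[m] = best_f
            thr[m] = best_thr
            left_val[m] = best_left
            right_val[m] = best_right
            for i in range(n):
                if X[i, best_f] > best_thr:
                    resid[i] -= shrinkage * best_right
                else:
                    resid[i] -= shrinkage * best_left

    fitted = np.empty(n)
    for i in range(n):
        fitted[i] = y[i] - resid[i]
    return baseline, feat, thr, left_val, right_val, fitted


@njit(cache=True)
def _predict_stumps(X, feat, thr, left_val, right_val, baseline, shrinkage):
    """Evaluate a stump ensemble row-wise."""
    n = X.shape[0]
    m = feat.shape[0]
    out = np.full(n, baseline)
    for j in range(m):
        f = feat[j]
        if f < 0:
            for i in range(n):
                out[i] += shrinkage * left_val[j]
        else:
            t = thr[j]
            for i in range(n):
                if X[i, f] > t:
                    out[i] += shrinkage * right_val[j]
                else:
                    out[i] += shrinkage * left_val[j]
    return out
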