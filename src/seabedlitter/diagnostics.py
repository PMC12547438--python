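"""Residual spatial-autocorrelation diagnostics.

Leave-one-out error estimates are optimistic when the response is
spatially autocorrelated, so the analysis checks an empirical
semivariogram of model residuals: a flat curve indicates no obvious
spatial structure. The Matheron estimator is used,

    gamma(h) = (1 / (2 |N(h)|)) * sum_{(i,j) in N(h)} (z_i - z_j)^2,

with pairs binned by great-circle distance (a planar metric is available
for synthetic tests). Whether a curve is "flat" is a judgement call; the
module therefore also provides a Monte-Carlo permutation envelope rather
than a pass/fail verdict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geo import pairwise_distances
from ._seeds import rng_from
from .boosting import BoostedModel

__all__ = [
    "Semivariogram",
    "model_residuals",
    "empirical_semivariogram",
    "permutation_envelope",
    "plot_semivariogram",
]


@dataclass
class Semivariogram:
    """Binned Matheron semivariance; empty bins carry count 0 and NaN."""

    bin_edges: np.ndarray
    bin_centers: np.ndarray
    semivariance: np.ndarray
    pair_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "bin_center": self.bin_centers,
                "semivariance": self.semivariance,
                "pair_count": self.pair_counts,
            }
        )


def model_residuals(model: BoostedModel, table: pd.DataFrame, response_name: str = "mp_count") -> np.ndarray:
    """Observed minus predicted, in table row order."""
    missing = [c for c in model.feature_names if c not in table.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    return table[response_name].to_numpy(dtype=np.float64) - model.predict(table)


def _pair_arrays(coords, values, metric):
    coords = np.asarray(coords, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if coords.shape[0] != values.size:
        raise ValueError("coords and values disagree on length")
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 points")
    d = pairwise_distances(coords, metric=metric)
    iu = np.triu_indices(len(d), k=1)
    return d[iu], values


def empirical_semivariogram(
    coords,
    values,
    n_bins: int = 10,
    max_dist: float | None = None,
    metric: str = "haversine",
) -> Semivariogram:
    """Binned Matheron semivariogram of a point-referenced variable.

    ``max_dist`` defaults to half the maximum pairwise distance, the usual
    variography convention; bins are equal-width on [0, max_dist].
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    dist, values = _pair_arrays(coords, values, metric)
    if max_dist is None:
        max_dist = float(dist.max()) / 2.0
    if max_dist <= 0:
        raise ValueError("max_dist must be > 0")

    iu = np.triu_indices(values.size, k=1)
    sqdiff = (values[iu[0]] - values[iu[1]]) ** 2

    edges = np.linspace(0.0, max_dist, n_bins + 1)
    which = np.digitize(dist, edges[1:], right=True)  # bin index; > n_bins-1 = beyond
    gamma = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=np.int64)
    for b in range(n_bins):
        sel = which == b
        sel &= dist <= max_dist
        m = int(sel.sum())
        counts[b] = m
        if m > 0:
            gamma[b] = float(sqdiff[sel].sum() / (2.0 * m))
    return Semivariogram(
        bin_edges=edges,
        bin_centers=(edges[:-1] + edges[1:]) / 2.0,
        semivariance=gamma,
        pair_counts=counts,
    )


def permutation_envelope(
    coords,
    values,
    n_bins: int = 10,
    max_dist: float | None = None,
    metric: str = "haversine",
    n_perm: int = 199,
    seed: int = 0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Monte-Carlo envelope for the no-autocorrelation null.

    Values are permuted over locations ``n_perm`` times; per bin the
    (1-level)/2 and (1+level)/2 quantiles of the permuted semivariances
    bracket what a spatially unstructured field would produce. The
    observed curve is reported alongside; no pass/fail claim is made.
    """
    obs = empirical_semivariogram(coords, values, n_bins, max_dist, metric)
    if max_dist is None:
        max_dist = float(obs.bin_edges[-1])
    rng = rng_from(seed, "variogram-envelope")
    values = np.asarray(values, dtype=np.float64)
    sims = np.empty((n_perm, n_bins))
    for r in range(n_perm):
        sims[r] = empirical_semivariogram(
            coords, values[rng.permutation(values.size)], n_bins, max_dist, metric
        ).semivariance
    lo = (1.0 - level) / 2.0
    return pd.DataFrame(
        {
            "bin_center": obs.bin_centers,
            "pair_count": obs.pair_counts,
            "observed": obs.semivariance,
            "envelope_low": np.nanquantile(sims, lo, axis=0),
            "envelope_high": np.nanquantile(sims, 1.0 - lo, axis=0),
        }
    )


def plot_semivariogram(sv: Semivariogram, path=None, envelope: pd.DataFrame | None = None):
    """Render the semivariogram (and optional envelope) to an axes or file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(sv.bin_centers, sv.semivariance, "o-", label="residual semivariance")
    if envelope is not None:
        ax.fill_between(
            envelope["bin_center"], envelope["envelope_low"], envelope["envelope_high"],
            alpha=0.25, label="permutation envelope",
        )
    ax.set_xlabel("separation distance")
    ax.set_ylabel("semivariance")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax
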