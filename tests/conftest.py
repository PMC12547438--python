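"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths: the
stump oracle enumerates every (feature, midpoint) candidate and computes
node sums directly; the geometry oracle uses the shoelace formula and a
ray-casting point-in-polygon test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import seabedlitter as sl

#: Each informative effect below has marginal sd ~500 over standard-normal
#: predictors (step at 0 with jump A: sd A/2; linear slope b: sd b; the
#: logistic and off-centre step amplitudes are scaled to match), so a
#: gaussian noise sd of 500/3 puts every effect at effect-to-noise ~3.
RECOVERY_NOISE_SD = 500.0 / 3.0


def make_recovery_dataset(seed: int, n: int = 56):
    """Survey-size dataset: 5 informative + 5 pure-noise predictors,
    every informative effect at effect-to-noise ratio ~3."""
    spec = sl.TrueModelSpec(
        informative_set=sl.DEFAULT_PREDICTORS[:5],
        component_functions={
            "salinity_range": {"kind": "logistic", "amplitude": 1300.0, "center": 0.0, "scale": 0.5},
            "wave_orbital_velocity": {"kind": "step", "threshold": 0.0, "low": 0.0, "high": 1000.0},
            "silt_fraction": {"kind": "linear", "slope": 500.0},
            "seafloor_curvature": {"kind": "step", "threshold": 0.5, "low": 0.0, "high": 1080.0},
            "nitrogen_content": {"kind": "linear", "slope": -500.0},
        },
        baseline=2000.0,
        noise_family="gaussian",
        noise_scale=RECOVERY_NOISE_SD,
    )
    return sl.generate_station_dataset(n=n, spec=spec, seed=seed)


@pytest.fixture(scope="session")
def station_table():
    """A survey-like table: 56 stations, negative-binomial counts."""
    table, spec = sl.generate_station_dataset(56, seed=7)
    return table


@pytest.fixture(scope="session")
def fast_params():
    """Small ensemble for tests where 400 trees add nothing."""
    return sl.BoostParams(ntrees=40, seed=11)


# --- independent oracles ----------------------------------------------


def enumerate_stump_candidates(X: np.ndarray, y: np.ndarray, minobs: int = 1):
    """Exhaustive enumeration of every legal (feature, midpoint) split.

    Returns a list of (feature_idx, threshold, sse_reduction) computed by
    direct within-child SSE sums — an arithmetic route independent of the
    implementation's prefix-sum search.
    """
    n, p = X.shape
    total_sse = float(np.sum((y - y.mean()) ** 2))
    out = []
    for f in range(p):
        uniq = np.unique(X[:, f])
        for a, b in zip(uniq[:-1], uniq[1:]):
            thr = (a + b) / 2.0
            right = X[:, f] > thr
            n_r = int(right.sum())
            n_l = n - n_r
            if n_l < minobs or n_r < minobs:
                continue
            sse = float(np.sum((y[~right] - y[~right].mean()) ** 2)) + float(
                np.sum((y[right] - y[right].mean()) ** 2)
            )
            out.append((f, thr, total_sse - sse))
    return out


def oracle_best_stump(X: np.ndarray, y: np.ndarray, minobs: int = 1):
    """Best exhaustive split: (feature_idx, threshold, sse_reduction) or
    None; ties broken toward the lowest feature index, then threshold."""
    best = None
    for cand in enumerate_stump_candidates(X, y, minobs):
        if best is None or cand[2] > best[2] + 1e-12:
            best = cand
    return best


def shoelace_area(coords: np.ndarray) -> float:
    """Polygon area by the shoelace formula (positive for CCW rings)."""
    x, y = coords[:, 0], coords[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def point_in_polygon(px: float, py: float, ring: np.ndarray) -> bool:
    """Ray-casting containment test (boundary treatment approximate)."""
    inside = False
    n = len(ring)
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_int:
                inside = not inside
    return inside


def make_surface(values, lons=None, lats=None):
    """Assemble a PredictionSurface from raw vectors (test convenience)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    return sl.PredictionSurface(
        cells=pd.DataFrame(
            {
                "cell_id": [f"c{i:05d}" for i in range(n)],
                "lon": np.zeros(n) if lons is None else np.asarray(lons, float),
                "lat": np.zeros(n) if lats is None else np.asarray(lats, float),
                "value": values,
            }
        )
    )
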