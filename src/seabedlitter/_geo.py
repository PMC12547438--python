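"""Small geographic helpers shared by the generators and diagnostics."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(coords: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (km) for an (n, 2) lon/lat array."""
    c = np.asarray(coords, dtype=np.float64)
    lon = np.radians(c[:, 0])
    lat = np.radians(c[:, 1])
    dlon = lon[:, None] - lon[None, :]
    dlat = lat[:, None] - lat[None, :]
    a = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(lat[:, None]) * np.cos(lat[None, :]) * np.sin(dlon / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_distances(coords: np.ndarray, metric: str = "haversine") -> np.ndarray:
    """Distance matrix under either great-circle (km) or planar metric."""
    c = np.asarray(coords, dtype=np.float64)
    if metric == "haversine":
        return haversine_km(c)
    if metric == "planar":
        diff = c[:, None, :] - c[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))
    raise ValueError(f"unknown metric {metric!r}")
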