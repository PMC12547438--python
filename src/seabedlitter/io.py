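"""Readers, writers and configuration for the pipeline's file formats.

Formats: CSV (stations, grids, reports; comma-separated, UTF-8, "."
decimal, header mandatory), GeoJSON (layers, surfaces; WGS84 lon/lat,
counter-clockwise exterior rings), JSON (model, selection record), YAML
(pipeline configuration). Everything written here is re-readable by the
package's own readers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon, mapping, shape
from shapely.geometry.polygon import orient

from .boosting import BoostParams
from .risk import PredictionSurface
from .synthetic import RiskLayer

logger = logging.getLogger("seabedlitter")

__all__ = [
    "ParseError",
    "PipelineConfig",
    "read_station_csv",
    "write_station_csv",
    "read_grid_csv",
    "write_grid_csv",
    "read_layers_geojson",
    "write_layers_geojson",
    "read_surface_csv",
    "write_surface_csv",
    "write_surface_geojson",
]

_META_COLS = ("station_id", "lon", "lat")


class ParseError(ValueError):
    """A malformed input file (message carries the offending line)."""


def read_station_csv(path, response_name: str = "mp_count") -> pd.DataFrame:
    """Read a station observation table, dropping incomplete rows.

    Rows with any empty field are dropped with a logged count (the model
    uses complete observations only). A non-empty field that fails numeric
    parsing is a hard error naming the line; so is a missing header.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, skip_blank_lines=False)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    required = [c for c in _META_COLS if c != "station_id"] + [response_name]
    missing = [c for c in ("station_id", *required) if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: header missing columns {missing}")

    numeric_cols = [c for c in raw.columns if c != "station_id"]
    out = pd.DataFrame({"station_id": raw["station_id"]})
    for col in numeric_cols:
        cell = raw[col].astype(object)
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() & cell.notna() & (cell.astype(str).str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ParseError(
                f"{path}:{line}: cannot parse {col}={cell[bad.idxmax()]!r} as a number"
            )
        out[col] = parsed

    complete = out.notna().all(axis=1) & raw["station_id"].notna()
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("read_station_csv: dropped %d incomplete rows from %s", n_dropped, path)
    out = out[complete].reset_index(drop=True)
    if out.empty:
        raise ParseError(f"{path}: no complete observations")
    return out


def write_station_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_grid_csv(path) -> pd.DataFrame:
    grid = pd.read_csv(path)
    missing = [c for c in ("cell_id", "lon", "lat") if c not in grid.columns]
    if missing:
        raise ParseError(f"{path}: grid missing columns {missing}")
    return grid


def write_grid_csv(grid: pd.DataFrame, path) -> None:
    grid.to_csv(path, index=False)


# --- GeoJSON layers ----------------------------------------------------


def write_layers_geojson(layers: list[RiskLayer], path) -> None:
    """Layers as one FeatureCollection; properties carry {name, kind}."""
    features = []
    for layer in layers:
        for i, poly in enumerate(layer.polygons):
            features.append(
                {
                    "type": "Feature",
                    "properties": {
                        "name": layer.name,
                        "kind": layer.kind,
                        "polygon_id": f"{layer.name}_{i:03d}",
                    },
                    "geometry": mapping(orient(poly, sign=1.0)),
                }
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, sort_keys=True)


def read_layers_geojson(path) -> list[RiskLayer]:
    """Read risk layers grouped by name; geometry and kind are validated."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ParseError(f"{path}: not a GeoJSON FeatureCollection")
    grouped: dict[str, RiskLayer] = {}
    for idx, feature in enumerate(doc.get("features", [])):
        props = feature.get("properties") or {}
        name = props.get("name")
        kind = props.get("kind")
        if name is None or kind not in ("source", "receptor"):
            raise ParseError(
                f"{path}: feature {idx} ({name!r}) needs properties name and "
                f"kind in {{source, receptor}}, got kind={kind!r}"
            )
        geom = shape(feature["geometry"])
        if not isinstance(geom, Polygon):
            raise ParseError(f"{path}: feature {idx} ({name!r}) is not a Polygon")
        if not geom.is_valid:
            raise ParseError(f"{path}: feature {idx} ({name!r}) has an invalid (self-intersecting?) ring")
        if name in grouped:
            if grouped[name].kind != kind:
                raise ParseError(f"{path}: layer {name!r} has conflicting kinds")
            grouped[name].polygons.append(geom)
        else:
            grouped[name] = RiskLayer(name=name, kind=kind, polygons=[geom])
    return list(grouped.values())


# --- surfaces ----------------------------------------------------------


def write_surface_csv(surface: PredictionSurface, path) -> None:
    surface.cells.to_csv(path, index=False)


def read_surface_csv(path) -> PredictionSurface:
    return PredictionSurface(cells=pd.read_csv(path))


def write_surface_geojson(surface: PredictionSurface, path) -> None:
    """Surface as a GeoJSON point FeatureCollection (cell centres)."""
    features = [
        {
            "type": "Feature",
            "properties": {"cell_id": row.cell_id, "value": float(row.value)},
            "geometry": {"type": "Point", "coordinates": [float(row.lon), float(row.lat)]},
        }
        for row in surface.cells.itertuples()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, sort_keys=True)


# --- configuration -----------------------------------------------------


@dataclass
class PipelineConfig:
    """Declarative configuration of a full pipeline run.

    When ``stations`` is None the run is synthetic: the generator draws a
    survey-like dataset (n stations, clustered coordinates, 10 predictors,
    negative-binomial counts), a prediction grid and overlay layers under
    the master seed. Boosting defaults follow the survey configuration
    (ntrees=400, depth=1, minobs=10); ``reps`` replicates the stochastic
    LOO evaluation (100 in the original analysis; smaller values trade
    precision for speed).
    """

    output_dir: str = "runs/latest"
    stations: str | None = None
    grid: str | None = None
    layers: str | None = None
    seed: int = 0
    boost: BoostParams = field(default_factory=BoostParams)
    reps: int = 100
    log_transform: bool = False
    thresholds: tuple[float, float, float] = (1000.0, 2000.0, 3000.0)
    tune_grid: list[BoostParams] | None = None
    synthetic_n: int = 56
    synthetic_cluster_count: int = 6
    synthetic_noise_family: str = "negative_binomial"
    synthetic_noise_scale: float = 0.3
    grid_nx: int = 20
    grid_ny: int = 20
    layer_kinds: list[str] = field(
        default_factory=lambda: ["MPA", "disposal_sites", "wind_farms"]
    )
    polygons_per_layer: int = 8

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if len(self.thresholds) != 3 or list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("thresholds must be three increasing band edges")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        boost = BoostParams(**doc.pop("boost", {}))
        tune = doc.pop("tune_grid", None)
        if tune is not None:
            tune = [BoostParams(**entry) for entry in tune]
        if "thresholds" in doc:
            doc["thresholds"] = tuple(doc["thresholds"])
        return cls(boost=boost, tune_grid=tune, **doc)

    def to_canonical_dict(self) -> dict:
        # output_dir is where results land, not what they are: keep it out
        # of the hash so identical runs in different folders match
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
            if k not in ("boost", "tune_grid", "output_dir")
        }
        d["boost"] = vars(self.boost).copy()
        d["tune_grid"] = (
            None if self.tune_grid is None else [vars(p).copy() for p in self.tune_grid]
        )
        return d

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(self.to_canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_json(obj, path) -> None:
    """Canonical JSON: sorted keys, numpy scalars coerced."""

    def coerce(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, default=coerce)
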