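"""File formats and pipeline configuration.

CSV for cells/landmarks/survival, GeoJSON for region annotations and
compartment polygons, JSON for transforms and cutpoints, YAML for config,
TSV for statistics tables.  Every output directory gets a copy of the
config (with its hash) for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping as shapely_mapping

from .celltable import ALL_CLASSES, CellTableError, validate_cell_table


def read_cell_table(path, vocabulary=ALL_CLASSES) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CellTableError(f"{path}: empty file") from exc
    return validate_cell_table(df, vocabulary)


def write_cell_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_survival_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_survival_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_geojson(geometries: dict, path, properties: dict | None = None) -> None:
    """Write named shapely geometries as a GeoJSON FeatureCollection."""
    features = []
    for name, geom in geometries.items():
        if geom is None or geom.is_empty:
            continue
        props = {"name": name}
        if properties and name in properties:
            props.update(properties[name])
        features.append(
            {"type": "Feature", "properties": props, "geometry": shapely_mapping(geom)}
        )
    obj = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(obj))


def read_geojson(path) -> dict:
    return json.loads(Path(path).read_text())


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


@dataclass
class PipelineConfig:
    """Parameter registry for the full pipeline.

    Defaults mirror the analysis parameters: 50 um grids, 4th-order queen
    neighborhoods, alpha 0.05, 250 um Delaunay edge cap, 8-connectivity.
    """

    grid_um: float = 50.0
    neighbor_order: int = 4
    include_self: bool = True
    alpha: float = 0.05
    max_edge_um: float = 250.0
    connectivity: int = 8
    um_per_pixel: float | None = None
    seed: int = 0
    run_interactions: bool = True
    run_components: bool = True
    shannon_base: float | None = None  # None = natural log

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_yaml(Path(path).read_text())

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def dump(self, out_dir) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "config.yaml"
        path.write_text(f"# config_hash: {self.config_hash()}\n" + self.to_yaml())
        return path
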