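"""Minimal GeoJSON FeatureCollection I/O backed by shapely.

Vector layers (lake polygons, stream polylines, zone polygons, land-cover
tilings) travel as GeoJSON with a declared coordinate reference system in
``crs`` (a free-form string; all layers of one pipeline must agree). A
layer is a list of features, each a dict with ``geometry`` (shapely) and
``properties`` (plain dict).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry


class Layer:
    """An ordered collection of (geometry, properties) features with a CRS."""

    def __init__(self, features: list[dict[str, Any]], crs: str):
        self.features = features
        self.crs = crs

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def geometries(self) -> list[BaseGeometry]:
        return [f["geometry"] for f in self.features]


def feature(geometry: BaseGeometry, **properties: Any) -> dict[str, Any]:
    return {"geometry": geometry, "properties": dict(properties)}


def read_layer(path: str | Path) -> Layer:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    crs = doc.get("crs", "")
    if isinstance(crs, dict):  # legacy named-CRS object
        crs = crs.get("properties", {}).get("name", "")
    feats = [
        {"geometry": shape(f["geometry"]), "properties": f.get("properties") or {}}
        for f in doc.get("features", [])
    ]
    return Layer(feats, crs)


def write_layer(layer: Layer, path: str | Path) -> None:
    doc = {
        "type": "FeatureCollection",
        "crs": layer.crs,
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(f["geometry"]),
                "properties": f["properties"],
            }
            for f in layer.features
        ],
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, separators=(",", ":"))
        fh.write("\n")
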