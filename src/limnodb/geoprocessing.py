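"""Vector geoprocessing for the census/geospatial module.

Covers the toolbox steps that characterize every lake in the census
population: filtering candidate waterbodies against the census definition
(perennial, >= 4 ha, not entirely artificial), carving spatial extents
(political zones, hydrologic units, near-shore buffer rings) with unique
ZoneIDs, summarizing categorical and continuous themes over any extent, and
classifying each lake's hydrologic connectivity from its position on the
directed stream network.

All layers are vector (polygons / polylines) in one shared projected CRS;
continuous themes arrive as polygonal value layers, so zonal statistics are
exact area-weighted intersections rather than raster approximations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import networkx as nx
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .models import (
    EXCLUDED_ARTIFICIAL,
    EXCLUDED_NON_PERENNIAL,
    EXCLUDED_TOO_SMALL,
    ZoneDef,
    ZoneMetric,
)

DEFAULT_MIN_AREA_HA = 4.0
DEFAULT_EXCLUDED_CLASSES = frozenset({"sewage treatment", "aquaculture"})
DEFAULT_SNAP_TOLERANCE_M = 50.0
_AREA_EPS = 1e-9


class GeoprocessingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Census filter

def census_filter(
    waterbodies: Iterable[dict],
    min_area_ha: float = DEFAULT_MIN_AREA_HA,
    excluded_classes: frozenset[str] = DEFAULT_EXCLUDED_CLASSES,
) -> tuple[list[dict], list[tuple[dict, str]]]:
    """Split candidate waterbodies into the census set and labeled exclusions.

    A census lake is a perennial body of relatively still water whose surface
    area meets the threshold (boundary-inclusive: exactly ``min_area_ha``
    qualifies), excluding entirely artificial waterbodies such as sewage
    treatment or aquaculture ponds. Each waterbody is a GeoJSON-style feature
    whose properties carry ``area_ha``, ``fclass`` and ``perennial``.
    """
    census: list[dict] = []
    excluded: list[tuple[dict, str]] = []
    for wb in waterbodies:
        props = wb["properties"]
        if "area_ha" not in props or props["area_ha"] is None:
            raise GeoprocessingError(
                f"waterbody {props.get('id', '?')!r} lacks an area attribute"
            )
        fclass = str(props.get("fclass", "")).strip().lower()
        if fclass in excluded_classes:
            excluded.append((wb, EXCLUDED_ARTIFICIAL))
        elif not props.get("perennial", True):
            excluded.append((wb, EXCLUDED_NON_PERENNIAL))
        elif float(props["area_ha"]) < min_area_ha:
            excluded.append((wb, EXCLUDED_TOO_SMALL))
        else:
            census.append(wb)
    return census, excluded


# ---------------------------------------------------------------------------
# Zones

@dataclass
class ZoneGeometry:
    """A zone definition together with its polygon."""

    zone: ZoneDef
    geometry: BaseGeometry


def build_buffer_zones(
    lakes: Iterable[tuple[int, BaseGeometry]],
    distances_m: Iterable[float],
) -> list[ZoneGeometry]:
    """Near-shore buffer rings: (lake dilated by d) minus the lake itself."""
    distances = list(distances_m)
    if any(d <= 0 for d in distances):
        raise GeoprocessingError("buffer distances must be positive")
    zones: list[ZoneGeometry] = []
    for lake_id, geom in lakes:
        if geom.geom_type not in {"Polygon", "MultiPolygon"}:
            raise GeoprocessingError(
                f"lake {lake_id}: buffer zones require polygonal geometry,"
                f" got {geom.geom_type}"
            )
        for d in distances:
            ring = geom.buffer(d).difference(geom)
            zones.append(
                ZoneGeometry(
                    ZoneDef(
                        zone_id=f"buffer{d:g}_{lake_id}",
                        zone_type="buffer",
                        buffer_distance_m=float(d),
                        lake_id=lake_id,
                    ),
                    ring,
                )
            )
    return zones


def assign_zone_membership(
    lakes: Iterable[tuple[int, BaseGeometry]],
    zones: Iterable[ZoneGeometry],
) -> list[tuple[int, str, Optional[str]]]:
    """Assign each lake to at most one zone per non-buffer zone type.

    Membership is by lake centroid; a lake whose centroid falls in no zone
    (or ambiguously on a shared boundary) falls back to largest intersection
    area, so e.g. a lake straddling two states still receives exactly one
    state. Lakes matching no zone of a type are reported with zone_id None
    (membership MISSING).
    """
    by_type: dict[str, list[ZoneGeometry]] = {}
    for zg in zones:
        if zg.zone.zone_type != "buffer":
            by_type.setdefault(zg.zone.zone_type, []).append(zg)

    rows: list[tuple[int, str, Optional[str]]] = []
    for lake_id, geom in lakes:
        centroid = geom.centroid
        for zone_type, zgs in sorted(by_type.items()):
            containing = [zg for zg in zgs if zg.geometry.covers(centroid)]
            if len(containing) == 1:
                rows.append((lake_id, zone_type, containing[0].zone.zone_id))
                continue
            # boundary tie or centroid outside all: largest intersection
            best_id, best_area = None, 0.0
            for zg in sorted(zgs, key=lambda z: z.zone.zone_id):
                a = zg.geometry.intersection(geom).area
                if a > best_area + _AREA_EPS:
                    best_id, best_area = zg.zone.zone_id, a
            rows.append((lake_id, zone_type, best_id))
    return rows


# ---------------------------------------------------------------------------
# Zonal summaries

def zonal_summary_categorical(
    zone_geometry: BaseGeometry,
    landcover: Iterable[dict],
    class_attribute: str = "class",
) -> tuple[dict[str, float], Optional[str]]:
    """Per-class area proportions of a categorical layer within a zone.

    proportion_c = area(zone ∩ class c) / area(zone ∩ all classes). Returns
    ({}, "NO_DATA") when the layer does not cover the zone at all, and flags
    PARTIAL_COVERAGE when it covers only part of it. Invariant to how class
    polygons are split, because areas are additive.
    """
    zone_area = zone_geometry.area
    if zone_area <= _AREA_EPS:
        raise GeoprocessingError("zero-area zone")
    by_class: dict[str, float] = {}
    for f in landcover:
        a = zone_geometry.intersection(f["geometry"]).area
        if a > 0:
            cls = str(f["properties"][class_attribute])
            by_class[cls] = by_class.get(cls, 0.0) + a
    covered = sum(by_class.values())
    if covered <= _AREA_EPS:
        return {}, "NO_DATA"
    proportions = {c: a / covered for c, a in sorted(by_class.items())}
    flag = "PARTIAL_COVERAGE" if covered < zone_area * (1 - 1e-9) else None
    return proportions, flag


def zonal_summary_continuous(
    zone_geometry: BaseGeometry,
    value_layer: Iterable[dict],
    value_attribute: str,
    statistic: str = "mean",
) -> tuple[Optional[float], Optional[str]]:
    """Area-weighted statistic of a polygonal value layer within a zone."""
    if statistic not in {"mean", "min", "max"}:
        raise GeoprocessingError(f"unknown statistic {statistic!r}")
    zone_area = zone_geometry.area
    if zone_area <= _AREA_EPS:
        raise GeoprocessingError("zero-area zone")
    pairs: list[tuple[float, float]] = []  # (value, intersection area)
    for f in value_layer:
        a = zone_geometry.intersection(f["geometry"]).area
        if a > 0:
            pairs.append((float(f["properties"][value_attribute]), a))
    if not pairs:
        return None, "NO_DATA"
    covered = sum(a for _, a in pairs)
    if statistic == "mean":
        value = sum(v * a for v, a in pairs) / covered
    elif statistic == "min":
        value = min(v for v, _ in pairs)
    else:
        value = max(v for v, _ in pairs)
    flag = "PARTIAL_COVERAGE" if covered < zone_area * (1 - 1e-9) else None
    return value, flag


def categorical_zone_metrics(
    zone: ZoneDef,
    zone_geometry: BaseGeometry,
    landcover: Iterable[dict],
    class_attribute: str = "class",
    theme: str = "landcover",
) -> list[ZoneMetric]:
    proportions, flag = zonal_summary_categorical(
        zone_geometry, landcover, class_attribute
    )
    if not proportions:
        return [
            ZoneMetric(
                zone_id=zone.zone_id, theme=theme, metric_name="proportion",
                value=None, flag="NO_DATA",
            )
        ]
    return [
        ZoneMetric(
            zone_id=zone.zone_id, theme=theme,
            metric_name=f"proportion_{cls}", value=p, units="fraction", flag=flag,
        )
        for cls, p in proportions.items()
    ]


# ---------------------------------------------------------------------------
# Flow network and connectivity

class FlowNetwork:
    """Directed stream graph with lakes collapsed onto single nodes."""

    def __init__(self, graph: nx.DiGraph, lake_nodes: dict[int, str]):
        self.graph = graph
        self.lake_nodes = lake_nodes

    def upstream_lakes(self, lake_id: int) -> set[int]:
        node = self._node(lake_id)
        ancestors = nx.ancestors(self.graph, node)
        return {
            self.graph.nodes[n]["lake_id"]
            for n in ancestors
            if self.graph.nodes[n].get("lake_id") is not None
        }

    def _node(self, lake_id: int) -> str:
        if lake_id not in self.lake_nodes:
            raise GeoprocessingError(f"lake {lake_id} is not in the flow network")
        return self.lake_nodes[lake_id]


def build_flow_network(
    streams: Iterable[dict],
    lakes: Iterable[tuple[int, BaseGeometry]],
    snap_tolerance_m: float = DEFAULT_SNAP_TOLERANCE_M,
) -> FlowNetwork:
    """Build the directed flow graph from stream polylines and lake polygons.

    Stream segments flow from their first to their last vertex. A segment
    endpoint within ``snap_tolerance_m`` of a lake polygon snaps onto that
    lake's (collapsed) node; ambiguous endpoints snap to the nearest lake.
    The collapsed graph must be acyclic — surface flow has no loops — and a
    cycle is reported as an error naming its nodes.
    """
    lake_list = sorted(lakes, key=lambda t: t[0])
    graph = nx.DiGraph()
    lake_nodes: dict[int, str] = {}
    for lake_id, _ in lake_list:
        node = f"lake:{lake_id}"
        lake_nodes[lake_id] = node
        graph.add_node(node, lake_id=lake_id)

    def snap(x: float, y: float) -> str:
        p = Point(x, y)
        best: Optional[tuple[float, int]] = None
        for lake_id, geom in lake_list:
            d = geom.distance(p)
            if d <= snap_tolerance_m and (best is None or d < best[0]):
                best = (d, lake_id)
        if best is not None:
            return lake_nodes[best[1]]
        node = f"J:{x:.3f}_{y:.3f}"
        if node not in graph:
            graph.add_node(node, lake_id=None)
        return node

    for seg in streams:
        coords = list(seg["geometry"].coords)
        u = snap(*coords[0][:2])
        v = snap(*coords[-1][:2])
        if u != v:
            graph.add_edge(u, v)

    try:
        cycle = nx.find_cycle(graph)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        raise GeoprocessingError(
            f"flow network contains a cycle: {[e[0] for e in cycle]}"
        )
    return FlowNetwork(graph, lake_nodes)


def classify_connectivity(lake_id: int, network: FlowNetwork) -> str:
    """Position of a lake in the hydrologic flowpath.

    ISOLATED — no stream connections; HEADWATER — outflow only; DRAINAGE —
    stream inflow but no census lake upstream; DRAINAGE_UPSTREAM_LAKES —
    stream inflow fed by at least one upstream census lake.
    """
    node = network._node(lake_id)
    indeg = network.graph.in_degree(node)
    outdeg = network.graph.out_degree(node)
    if indeg == 0 and outdeg == 0:
        return "ISOLATED"
    if indeg == 0:
        return "HEADWATER"
    if network.upstream_lakes(lake_id):
        return "DRAINAGE_UPSTREAM_LAKES"
    return "DRAINAGE"
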