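"""Seeded synthetic landscape and heterogeneous source-dataset generator.

Every pipeline stage is testable offline against generated inputs with a
known-truth ledger: a packed landscape of square lakes whose areas straddle
the 4-ha census threshold (a known fraction artificial or non-perennial), a
directed stream network with connectivity classes fixed by construction,
nested zone layers and a categorical land-cover tiling aligned to the zone
grid (so per-zone class proportions are exact cell counts), and source
tables in three provider dialects — a wide state-agency table, a long
citizen-monitoring table, and an idiosyncratic university table — with
mixed units, date formats, detection-limit codes, seeded site-coordinate
offsets, and seeded QAQC violations. The ledger records every true value,
displacement, and injected violation, so recovery can be checked exactly.

Generation is fully reproducible from (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon, box

from .georeference import LakeCandidate, local_to_lonlat
from .geoprocessing import ZoneGeometry, census_filter
from .models import (
    LakeRecord,
    MetadataChecklist,
    ProgramRecord,
    SourceDataset,
    ZoneDef,
)
from .vocabulary import ControlledVocabulary, SourceMapping

LOCAL_CRS = "LOCAL_EQUIRECT_M"
GEO_CRS = "GEOGRAPHIC_DD"
ORIGIN_LON, ORIGIN_LAT = -89.5, 45.5  # declared origin of the local projection

LANDCOVER_CLASSES = ("forest", "agriculture", "wetland", "urban")
STYLES = ("wide_state", "long_citizen", "odd_university")


class FixtureError(ValueError):
    pass


@dataclass
class Landscape:
    crs: str
    extent_m: float
    lakes: list[dict]              # waterbody features, file order
    streams: list[dict]            # LineString features, flow first->last
    zones: dict[str, list[ZoneGeometry]]
    landcover: list[dict]
    ledger: dict = field(default_factory=dict)

    def lake_records(self, min_area_ha: float = 4.0) -> list[LakeRecord]:
        """Surrogate lake_ids in polygon-file order, census flags applied."""
        census, excluded = census_filter(self.lakes, min_area_ha)
        census_ids = {f["properties"]["id"] for f in census}
        reasons = {f["properties"]["id"]: r for f, r in excluded}
        records = []
        for i, f in enumerate(self.lakes, start=1):
            p = f["properties"]
            c = f["geometry"].centroid
            records.append(
                LakeRecord(
                    lake_id=i, source_polygon_id=p["id"], name=p.get("name"),
                    centroid_x=c.x, centroid_y=c.y, area_ha=p["area_ha"],
                    geometry_ref=p["id"], is_census=p["id"] in census_ids,
                    excluded_reason=reasons.get(p["id"]),
                )
            )
        return records

    def census_candidates(self) -> list[LakeCandidate]:
        return [
            LakeCandidate(r.lake_id, self.lakes[r.lake_id - 1]["geometry"], r.name)
            for r in self.lake_records()
            if r.is_census
        ]

    def lake_attributes(self) -> pd.DataFrame:
        rows = [
            {
                "lake_id": i,
                "mean_depth_m": f["properties"]["mean_depth_m"],
                "max_depth_m": f["properties"]["max_depth_m"],
            }
            for i, f in enumerate(self.lakes, start=1)
        ]
        return pd.DataFrame(rows)


def gen_landscape(
    n_lakes: int = 30, extent_m: float = 20000.0, seed: int = 0
) -> Landscape:
    """Generate the synthetic landscape with its known-truth ledger."""
    if n_lakes < 1:
        raise FixtureError("n_lakes must be >= 1")
    rng = np.random.default_rng(seed)

    ncell = math.ceil(math.sqrt(n_lakes))
    if ncell % 2:
        ncell += 1
    s = extent_m / ncell
    max_side = math.sqrt(60.0 * 10000.0)
    if s < max_side * 1.3:
        raise FixtureError(
            f"cells of {s:.0f} m cannot pack lakes up to {max_side:.0f} m wide;"
            " increase extent_m"
        )

    cells = [(i, j) for j in range(ncell) for i in range(ncell)][:n_lakes]
    lakes: list[dict] = []
    connectivity_truth: dict[int, str] = {}
    for idx, (i, j) in enumerate(cells):
        if idx == 0:
            area_ha = 4.0  # census boundary case, inclusive by definition
        elif rng.random() < 0.2:
            area_ha = float(rng.uniform(1.0, 3.9))
        else:
            area_ha = float(rng.uniform(4.5, 60.0))
        side = math.sqrt(area_ha * 10000.0)
        # jitter keeps centroids strictly off every zone-grid boundary
        jx = float(rng.uniform(0.02, 0.06) * s) * (1 if rng.random() < 0.5 else -1)
        jy = float(rng.uniform(0.02, 0.06) * s) * (1 if rng.random() < 0.5 else -1)
        cx, cy = (i + 0.5) * s + jx, (j + 0.5) * s + jy
        r = rng.random()
        if idx != 0 and r < 0.10:
            fclass = "sewage treatment" if r < 0.05 else "aquaculture"
            perennial = True
        elif idx != 0 and r < 0.15:
            fclass, perennial = "natural", False
        else:
            fclass = "reservoir" if r > 0.85 else "natural"
            perennial = True
        max_depth = float(rng.uniform(4.0, 40.0))
        lakes.append(
            {
                "geometry": box(cx - side / 2, cy - side / 2,
                                cx + side / 2, cy + side / 2),
                "properties": {
                    "id": f"P{idx + 1:03d}",
                    "name": f"Lake {idx + 1:03d}",
                    "area_ha": area_ha,
                    "fclass": fclass,
                    "perennial": perennial,
                    "mean_depth_m": float(rng.uniform(0.3, 0.6)) * max_depth,
                    "max_depth_m": max_depth,
                },
            }
        )

    census, excluded = census_filter(lakes)
    census_lake_ids = sorted(
        i + 1 for i, f in enumerate(lakes)
        if f["properties"]["id"] in {c["properties"]["id"] for c in census}
    )

    # stream network: classes fixed by construction among census lakes
    streams: list[dict] = []
    order = list(census_lake_ids)
    rng.shuffle(order)
    n = len(order)
    n_du = n // 5
    n_hw = min(n_du + max(1, n // 10), max(n - n_du, 0))
    n_dr = n // 5
    du = order[:n_du]
    hw = order[n_du:n_du + n_hw]
    dr = order[n_du + n_hw:n_du + n_hw + n_dr]
    iso = order[n_du + n_hw + n_dr:]

    def centroid(lake_id: int) -> tuple[float, float]:
        c = lakes[lake_id - 1]["geometry"].centroid
        return c.x, c.y

    def junction_near(lake_id: int, dx: float, dy: float) -> tuple[float, float]:
        cx, cy = centroid(lake_id)
        side = math.sqrt(lakes[lake_id - 1]["properties"]["area_ha"] * 10000.0)
        return cx + (side / 2 + abs(dx)) * math.copysign(1, dx), cy + dy

    for k, lake_id in enumerate(hw):
        if k < len(du):
            # paired headwater: its outflow feeds a downstream lake
            streams.append(
                {"geometry": LineString([centroid(lake_id), centroid(du[k])]),
                 "properties": {"id": f"S_hw{lake_id}"}}
            )
        else:
            streams.append(
                {"geometry": LineString(
                    [centroid(lake_id), junction_near(lake_id, 300.0, 80.0)]),
                 "properties": {"id": f"S_hw{lake_id}"}}
            )
    for k, lake_id in enumerate(du[len(hw):], start=len(hw)):
        # leftover downstream lakes chain off earlier downstream lakes
        streams.append(
            {"geometry": LineString([centroid(du[k - 1]), centroid(lake_id)]),
             "properties": {"id": f"S_du{lake_id}"}}
        )
    for lake_id in dr:
        streams.append(
            {"geometry": LineString(
                [junction_near(lake_id, 300.0, -90.0), centroid(lake_id)]),
             "properties": {"id": f"S_in{lake_id}"}}
        )
        streams.append(
            {"geometry": LineString(
                [centroid(lake_id), junction_near(lake_id, -320.0, 70.0)]),
             "properties": {"id": f"S_out{lake_id}"}}
        )

    for lake_id in iso:
        connectivity_truth[lake_id] = "ISOLATED"
    for lake_id in hw:
        connectivity_truth[lake_id] = "HEADWATER"
    for lake_id in dr:
        connectivity_truth[lake_id] = "DRAINAGE"
    for lake_id in du:
        connectivity_truth[lake_id] = "DRAINAGE_UPSTREAM_LAKES"

    # nested zone layers aligned to the E/8 grid
    E = extent_m

    def grid_zones(zone_type: str, nx: int, ny: int, prefix: str) -> list[ZoneGeometry]:
        zones = []
        k = 1
        for jj in range(ny):
            for ii in range(nx):
                zones.append(
                    ZoneGeometry(
                        ZoneDef(zone_id=f"{prefix}_{k}", zone_type=zone_type),
                        box(ii * E / nx, jj * E / ny,
                            (ii + 1) * E / nx, (jj + 1) * E / ny),
                    )
                )
                k += 1
        return zones

    zones = {
        "state": grid_zones("state", 2, 1, "State"),
        "county": grid_zones("county", 2, 2, "County"),
        "hu4": grid_zones("hu4", 1, 2, "HU4"),
        "hu8": grid_zones("hu8", 4, 2, "HU8"),
    }

    # land cover: 8x8 class tiling aligned with all zone boundaries
    m = 8
    lc_classes = rng.integers(0, len(LANDCOVER_CLASSES), size=(m, m))
    landcover = [
        {
            "geometry": box(ii * E / m, jj * E / m, (ii + 1) * E / m, (jj + 1) * E / m),
            "properties": {"class": LANDCOVER_CLASSES[lc_classes[jj, ii]]},
        }
        for jj in range(m)
        for ii in range(m)
    ]

    # ledger proportions by cell counting (independent of any geometry code)
    landcover_proportions: dict[str, dict[str, float]] = {}
    for zone_type, zgs in zones.items():
        for zg in zgs:
            minx, miny, maxx, maxy = zg.geometry.bounds
            counts: dict[str, int] = {}
            total = 0
            for jj in range(m):
                for ii in range(m):
                    x0, y0 = ii * E / m, jj * E / m
                    if x0 >= minx - 1 and x0 < maxx - 1 and y0 >= miny - 1 and y0 < maxy - 1:
                        cls = LANDCOVER_CLASSES[lc_classes[jj, ii]]
                        counts[cls] = counts.get(cls, 0) + 1
                        total += 1
            landcover_proportions[zg.zone.zone_id] = {
                c: k / total for c, k in sorted(counts.items())
            }

    # zone membership truth from centroid arithmetic
    membership: dict[int, dict[str, str]] = {}
    for i, f in enumerate(lakes, start=1):
        c = f["geometry"].centroid
        sx = 1 if c.x < E / 2 else 2
        sy = 1 if c.y < E / 2 else 2
        qx = min(int(c.x // (E / 4)), 3)
        hy = 1 if c.y < E / 2 else 2
        membership[i] = {
            "state": f"State_{sx}",
            "county": f"County_{(sy - 1) * 2 + sx}",
            "hu4": f"HU4_{sy}",
            "hu8": f"HU8_{(hy - 1) * 4 + qx + 1}",
        }

    ledger = {
        "census_lake_ids": census_lake_ids,
        "excluded": {f["properties"]["id"]: r for f, r in excluded},
        "connectivity": connectivity_truth,
        "landcover_proportions": landcover_proportions,
        "zone_membership": membership,
    }
    return Landscape(
        crs=LOCAL_CRS, extent_m=extent_m, lakes=lakes, streams=streams,
        zones=zones, landcover=landcover, ledger=ledger,
    )


# ---------------------------------------------------------------------------
# Source datasets

@dataclass
class SourceFixture:
    table: pd.DataFrame
    mapping: SourceMapping
    source: SourceDataset
    program: ProgramRecord
    sites: pd.DataFrame  # site_ref, x, y, crs, reported_name
    ledger: dict


_STYLE_SPECS = {
    # column name -> (canonical variable, reported unit, text format, to-canonical factor)
    "wide_state": {
        "provider_type": "state",
        "date_format": "%m/%d/%Y",
        "vars": {
            "TP_MGL": ("total_phosphorus", "mg/L", 4, 1000.0),
            "TN_MGL": ("total_nitrogen", "mg/L", 3, 1000.0),
            "CHLA_UGL": ("chlorophyll_a", "ug/L", 2, 1.0),
            "SECCHI_M": ("secchi_depth", "m", 2, 1.0),
        },
    },
    "long_citizen": {
        "provider_type": "citizen",
        "date_format": "%Y-%m-%d",
        "vars": {
            "Total Phosphorus": ("total_phosphorus", "ug/L", 1, 1.0),
            "Secchi": ("secchi_depth", "m", 2, 1.0),
            "Chlorophyll": ("chlorophyll_a", "ug/L", 1, 1.0),
        },
    },
    "odd_university": {
        "provider_type": "university",
        "date_format": "%d.%m.%Y",
        "vars": {
            "Tot. Phosphorus": ("total_phosphorus", "ug/L", 1, 1.0),
            "NO3-NO2": ("nitrate_nitrite", "mg/L", 3, 1000.0),
            "DOC": ("dissolved_organic_carbon", "mg/L", 2, 1.0),
        },
    },
}


def _truth_value(rng, vdef, decimals: int, factor: float) -> tuple[str, float]:
    """Reported text in source units plus the exact canonical value."""
    lo = max(vdef.valid_min, 1e-3)
    hi = 0.5 * vdef.valid_max
    reported = round(float(rng.uniform(lo / factor, hi / factor)), decimals)
    if reported <= 0:
        reported = 10.0 ** -decimals  # smallest positive at this precision
    return f"{reported:.{decimals}f}", float(f"{reported:.{decimals}f}") * factor


def gen_source_dataset(
    landscape: Landscape,
    vocab: ControlledVocabulary,
    style: str,
    n_samples: int = 60,
    error_rate: float = 0.0,
    n_egregious: int = 0,
    censored_rate: float = 0.0,
    seed: int = 0,
) -> SourceFixture:
    """Generate one heterogeneous source table with mapping and truth ledger.

    ``error_rate`` is the fraction of value cells replaced by questionable-
    range violations (each triggers exactly one plausible-range flag);
    ``n_egregious`` additionally injects values above the egregious deletion
    threshold; ``censored_rate`` renders cells as below-detection codes.
    """
    if style not in _STYLE_SPECS:
        raise FixtureError(f"unknown style {style!r}; choose from {STYLES}")
    if not (0.0 <= error_rate <= 1.0):
        raise FixtureError("error_rate must be in [0, 1]")
    spec = _STYLE_SPECS[style]
    rng = np.random.default_rng(seed)

    records = landscape.lake_records()
    census = [r for r in records if r.is_census]
    n_sites = min(len(census), max(4, n_samples // 5))
    chosen = sorted(
        rng.choice(len(census), size=n_sites, replace=False).tolist()
    )

    geographic = style == "long_citizen"
    site_rows = []
    site_truth = []
    for k, ci in enumerate(chosen):
        rec = census[ci]
        side = math.sqrt(rec.area_ha * 10000.0)
        u = rng.random()
        if u < 0.60:
            offset, category, expected = 0.0, "inside", "CONTAINS"
            x, y = rec.centroid_x, rec.centroid_y
        elif u < 0.85:
            offset = float(rng.uniform(10.0, 80.0))
            category, expected = "shoreline", "BUFFER"
            x, y = rec.centroid_x + side / 2 + offset, rec.centroid_y
        else:
            offset = float(rng.uniform(120.0, 500.0))
            category, expected = "access_point", "UNMATCHED"
            x, y = rec.centroid_x + side / 2 + offset, rec.centroid_y
        site_ref = f"{style[:2].upper()}-{k + 1:03d}"
        if geographic:
            lon, lat = local_to_lonlat(x, y, ORIGIN_LON, ORIGIN_LAT)
            site_rows.append(
                {"site_ref": site_ref, "x": lon, "y": lat, "crs": GEO_CRS,
                 "reported_name": rec.name}
            )
        else:
            site_rows.append(
                {"site_ref": site_ref, "x": x, "y": y, "crs": landscape.crs,
                 "reported_name": rec.name}
            )
        site_truth.append(
            {"site_ref": site_ref, "lake_id": rec.lake_id, "category": category,
             "displacement_m": offset, "expected_method": expected}
        )

    var_cols = list(spec["vars"])
    start = date(2004, 1, 15)
    dates = [
        (start + timedelta(days=int(d))).strftime(spec["date_format"])
        for d in rng.integers(0, 3650, size=n_samples)
    ]
    site_for_row = [site_rows[int(i)]["site_ref"]
                    for i in rng.integers(0, n_sites, size=n_samples)]

    cells: list[dict] = []
    if style == "wide_state":
        table_rows = []
        for r in range(n_samples):
            row = {
                "STATION_ID": site_for_row[r],
                "SAMPLE_DATE": dates[r],
                "DEPTH_FT": f"{rng.uniform(1.0, 20.0):.1f}",
            }
            for col in var_cols:
                canonical, unit, decimals, factor = spec["vars"][col]
                vdef = vocab.definition(canonical)
                text, canon = _truth_value(rng, vdef, decimals, factor)
                row[col] = text
                cells.append(
                    {"row": r, "column": col, "variable": canonical,
                     "unit": unit, "text": text, "canonical_value": canon,
                     "kind": "clean", "factor": factor, "decimals": decimals}
                )
            table_rows.append(row)
        table = pd.DataFrame(table_rows, dtype=object)
        mapping = SourceMapping(
            source_id=f"src_{style}", orientation="wide",
            site_id_column="STATION_ID", date_column="SAMPLE_DATE",
            date_format=spec["date_format"], depth_column="DEPTH_FT",
            depth_unit="ft", depth_code_default="point",
            variable_columns={
                col: {"variable": v[0], "unit": v[1]}
                for col, v in spec["vars"].items()
            },
        )
        value_column = None
    else:
        param_col = "parameter" if style == "long_citizen" else "analyte"
        value_col = "reading" if style == "long_citizen" else "result"
        site_col = "lake" if style == "long_citizen" else "site.code"
        date_col = "date" if style == "long_citizen" else "sampled_on"
        unit_col = "units" if style == "long_citizen" else None
        table_rows = []
        for r in range(n_samples):
            col = var_cols[int(rng.integers(0, len(var_cols)))]
            canonical, unit, decimals, factor = spec["vars"][col]
            vdef = vocab.definition(canonical)
            text, canon = _truth_value(rng, vdef, decimals, factor)
            row = {site_col: site_for_row[r], date_col: dates[r], param_col: col,
                   value_col: text}
            if unit_col:
                row[unit_col] = unit
            table_rows.append(row)
            cells.append(
                {"row": r, "column": value_col, "variable": canonical,
                 "unit": unit, "text": text, "canonical_value": canon,
                 "kind": "clean", "factor": factor, "decimals": decimals}
            )
        table = pd.DataFrame(table_rows, dtype=object)
        mapping = SourceMapping(
            source_id=f"src_{style}", orientation="long",
            site_id_column=site_col, date_column=date_col,
            date_format=spec["date_format"],
            variable_name_column=param_col, value_column=value_col,
            unit_column=unit_col,
            unit_defaults={v[0]: v[1] for v in spec["vars"].values()},
            censor_conventions={"<": "below_detection"},
        )
        value_column = value_col

    # seeded injections: questionable range violations, egregious values,
    # below-detection codes — on disjoint cell sets
    n_cells = len(cells)
    idx = rng.permutation(n_cells)
    n_q = round(error_rate * n_cells)
    n_e = min(n_egregious, n_cells - n_q)
    n_c = 0
    if censored_rate > 0 and style != "wide_state":
        n_c = min(round(censored_rate * n_cells), n_cells - n_q - n_e)
    q_set, e_set = set(idx[:n_q].tolist()), set(idx[n_q:n_q + n_e].tolist())
    c_set = set(idx[n_q + n_e:n_q + n_e + n_c].tolist())

    def rewrite(cell: dict, canonical_value: float, kind: str, prefix: str = "") -> None:
        factor, decimals = cell["factor"], cell["decimals"]
        reported = canonical_value / factor
        text = f"{prefix}{reported:.{decimals}f}"
        numeric = float(f"{reported:.{decimals}f}") * factor
        cell.update(text=text, kind=kind)
        if kind == "censored":
            cell["canonical_value"] = None
            cell["detection_limit_canonical"] = numeric
        else:
            cell["canonical_value"] = numeric
        r, col = cell["row"], cell["column"]
        table.iat[r, table.columns.get_loc(col)] = text

    for i, cell in enumerate(cells):
        vdef = vocab.definition(cell["variable"])
        if i in q_set:
            rewrite(cell, vdef.valid_max * 1.5, "questionable")
        elif i in e_set:
            rewrite(cell, vdef.egregious_max * 2.0, "egregious")
        elif i in c_set:
            rewrite(cell, max(vdef.valid_min, 1e-3) + 1.0, "censored", prefix="<")

    provider_type = spec["provider_type"]
    source = SourceDataset(
        source_id=mapping.source_id, provider_type=provider_type,
        provider_name=f"Synthetic {provider_type} provider",
        metadata_checklist=MetadataChecklist(True, True, True, True),
    )
    program = ProgramRecord(
        program_id=f"prog_{style}", source_id=source.source_id,
        sampling_type="long_term" if style == "long_citizen" else "survey",
        temporal_resolution="irregular",
    )
    sites = pd.DataFrame(site_rows)
    ledger = {
        "style": style,
        "sites": site_truth,
        "cells": cells,
        "n_value_cells": n_cells,
        "n_questionable": n_q,
        "n_egregious": n_e,
        "n_censored": n_c,
        "expected_review_sites": sorted(
            t["site_ref"] for t in site_truth if t["category"] != "inside"
        ),
        "expected_unmatched_sites": sorted(
            t["site_ref"] for t in site_truth if t["category"] == "access_point"
        ),
    }
    return SourceFixture(table, mapping, source, program, sites, ledger)
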