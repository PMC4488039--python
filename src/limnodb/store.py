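"""Embedded single-file relational store joining the two database modules.

The vertical observation module (sources, programs, observations with cell
provenance) and the horizontal geospatial module (zones, zone metrics, zone
membership) are joined through the aggregated-lakes table, which holds the
unique lake identifier and spatial location. Referential integrity is both
declared in the SQLite schema and re-checkable via :func:`validate_integrity`,
which reports — rather than raises on — every dangling reference, duplicate
key, and metadata-checklist failure.

Deleted observations are never physically removed: they keep their row and
provenance, marked ``deleted = 1`` with an audit flag, so

    count(ever ingested) = count(live) + count(flags with disposition=deleted).
"""

from __future__ import annotations

import sqlite3
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .models import (
    ExportVersion,
    FlagRecord,
    LakeRecord,
    Observation,
    ProgramRecord,
    SourceDataset,
    VariableDef,
    version_components,
)

SCHEMA_SQL = """
CREATE TABLE lake (
    lake_id INTEGER PRIMARY KEY,
    source_polygon_id TEXT NOT NULL,
    name TEXT,
    centroid_x REAL NOT NULL,
    centroid_y REAL NOT NULL,
    area_ha REAL NOT NULL CHECK (area_ha > 0),
    geometry_ref TEXT NOT NULL,
    is_census INTEGER NOT NULL,
    excluded_reason TEXT,
    CHECK (NOT (is_census = 1 AND excluded_reason IS NOT NULL))
);
CREATE TABLE source (
    source_id TEXT PRIMARY KEY,
    provider_type TEXT NOT NULL,
    provider_name TEXT NOT NULL,
    provenance_uri TEXT,
    methods_metadata_present INTEGER NOT NULL,
    sample_depth_reported INTEGER NOT NULL,
    location_reported INTEGER NOT NULL,
    unaggregated_values INTEGER NOT NULL
);
CREATE TABLE program (
    program_id TEXT PRIMARY KEY,
    source_id TEXT NOT NULL REFERENCES source(source_id),
    sampling_type TEXT NOT NULL,
    temporal_resolution TEXT
);
CREATE TABLE variable (
    canonical_name TEXT PRIMARY KEY,
    long_name TEXT NOT NULL,
    canonical_units TEXT NOT NULL,
    category TEXT NOT NULL,
    valid_min REAL NOT NULL,
    valid_max REAL NOT NULL,
    egregious_max REAL NOT NULL,
    CHECK (valid_min <= valid_max AND valid_max <= egregious_max)
);
CREATE TABLE observation (
    obs_id INTEGER PRIMARY KEY,
    lake_id INTEGER NOT NULL REFERENCES lake(lake_id),
    program_id TEXT NOT NULL REFERENCES program(program_id),
    variable TEXT NOT NULL REFERENCES variable(canonical_name),
    value REAL,
    sample_date TEXT NOT NULL,
    sample_depth_m REAL,
    depth_code TEXT NOT NULL,
    censor_code TEXT NOT NULL,
    detection_limit REAL,
    method_code TEXT,
    site_ref TEXT NOT NULL,
    source_id TEXT NOT NULL,
    source_row_ref TEXT NOT NULL,
    source_column_ref TEXT NOT NULL,
    original_value_text TEXT NOT NULL,
    original_units TEXT NOT NULL,
    deleted INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE flag (
    flag_id INTEGER PRIMARY KEY,
    target TEXT NOT NULL,
    rule_id TEXT NOT NULL,
    severity TEXT NOT NULL,
    disposition TEXT NOT NULL,
    note TEXT,
    UNIQUE (target, rule_id)
);
CREATE TABLE zone (
    zone_id TEXT PRIMARY KEY,
    zone_type TEXT NOT NULL,
    buffer_distance_m REAL,
    lake_id INTEGER REFERENCES lake(lake_id),
    geometry_ref TEXT
);
CREATE TABLE zone_metric (
    zone_id TEXT NOT NULL REFERENCES zone(zone_id),
    theme TEXT NOT NULL,
    metric_name TEXT NOT NULL,
    value REAL,
    units TEXT,
    year INTEGER,
    flag TEXT,
    PRIMARY KEY (zone_id, theme, metric_name)
);
CREATE TABLE lake_zone (
    lake_id INTEGER NOT NULL REFERENCES lake(lake_id),
    zone_type TEXT NOT NULL,
    zone_id TEXT,
    PRIMARY KEY (lake_id, zone_type)
);
CREATE TABLE lake_attribute (
    lake_id INTEGER NOT NULL REFERENCES lake(lake_id),
    name TEXT NOT NULL,
    value,
    PRIMARY KEY (lake_id, name)
);
CREATE TABLE export_version (
    version_string TEXT PRIMARY KEY,
    created_date TEXT NOT NULL,
    dataset_count INTEGER NOT NULL,
    observation_count INTEGER NOT NULL,
    change_notes TEXT
);
"""


class StoreError(RuntimeError):
    pass


class Store:
    """Handle on the opened relational store."""

    def __init__(self, conn: sqlite3.Connection, path: str):
        self.conn = conn
        self.path = path
        self.conn.execute("PRAGMA foreign_keys = ON")

    # -- loading ----------------------------------------------------------

    def add_lakes(self, lakes: Iterable[LakeRecord]) -> None:
        rows = [
            (
                l.lake_id, l.source_polygon_id, l.name, l.centroid_x, l.centroid_y,
                l.area_ha, l.geometry_ref, int(l.is_census), l.excluded_reason,
            )
            for l in lakes
        ]
        with self.conn:
            self.conn.executemany(
                "INSERT INTO lake VALUES (?,?,?,?,?,?,?,?,?)", rows
            )

    def add_source(self, src: SourceDataset) -> None:
        c = src.metadata_checklist
        with self.conn:
            self.conn.execute(
                "INSERT OR REPLACE INTO source VALUES (?,?,?,?,?,?,?,?)",
                (
                    src.source_id, src.provider_type, src.provider_name,
                    src.provenance_uri, int(c.methods_metadata_present),
                    int(c.sample_depth_reported), int(c.location_reported),
                    int(c.unaggregated_values),
                ),
            )

    def add_program(self, prog: ProgramRecord) -> None:
        with self.conn:
            self.conn.execute(
                "INSERT OR REPLACE INTO program VALUES (?,?,?,?)",
                (prog.program_id, prog.source_id, prog.sampling_type,
                 prog.temporal_resolution),
            )

    def add_variables(self, variables: Iterable[VariableDef]) -> None:
        with self.conn:
            self.conn.executemany(
                "INSERT OR REPLACE INTO variable VALUES (?,?,?,?,?,?,?)",
                [
                    (v.canonical_name, v.long_name, v.canonical_units, v.category,
                     v.valid_min, v.valid_max, v.egregious_max)
                    for v in variables
                ],
            )

    def add_observations(
        self, observations: Iterable[Observation], program_id: str
    ) -> list[int]:
        """Insert georeferenced observations; returns assigned obs_ids.

        Re-ingesting the identical provenance cell is a no-op (idempotence):
        a cell of a source file yields at most one stored observation.
        """
        ids: list[int] = []
        with self.conn:
            for o in observations:
                if o.lake_id is None:
                    raise StoreError(
                        f"observation from site {o.site_ref!r} has no lake_id; "
                        "georeference before loading"
                    )
                p = o.provenance
                dup = self.conn.execute(
                    "SELECT obs_id FROM observation WHERE source_id=? AND "
                    "source_row_ref=? AND source_column_ref=?",
                    (p.source_id, p.source_row_ref, p.source_column_ref),
                ).fetchone()
                if dup:
                    ids.append(dup[0])
                    continue
                cur = self.conn.execute(
                    "INSERT INTO observation (lake_id, program_id, variable, value,"
                    " sample_date, sample_depth_m, depth_code, censor_code,"
                    " detection_limit, method_code, site_ref, source_id,"
                    " source_row_ref, source_column_ref, original_value_text,"
                    " original_units) VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
                    (
                        o.lake_id, program_id, o.variable, o.value, o.sample_date,
                        o.sample_depth_m, o.depth_code, o.censor_code,
                        o.detection_limit, o.method_code, o.site_ref,
                        p.source_id, p.source_row_ref, p.source_column_ref,
                        p.original_value_text, p.original_units,
                    ),
                )
                ids.append(cur.lastrowid)
        return ids

    def add_zones(self, zones) -> None:
        with self.conn:
            self.conn.executemany(
                "INSERT OR REPLACE INTO zone VALUES (?,?,?,?,?)",
                [
                    (z.zone_id, z.zone_type, z.buffer_distance_m, z.lake_id,
                     z.geometry_ref)
                    for z in zones
                ],
            )

    def add_zone_metrics(self, metrics) -> None:
        with self.conn:
            self.conn.executemany(
                "INSERT OR REPLACE INTO zone_metric VALUES (?,?,?,?,?,?,?)",
                [
                    (m.zone_id, m.theme, m.metric_name, m.value, m.units, m.year,
                     m.flag)
                    for m in metrics
                ],
            )

    def add_zone_membership(self, rows: Iterable[tuple[int, str, Optional[str]]]) -> None:
        with self.conn:
            self.conn.executemany(
                "INSERT OR REPLACE INTO lake_zone VALUES (?,?,?)", list(rows)
            )

    def add_lake_attributes(self, rows: Iterable[tuple[int, str, object]]) -> None:
        with self.conn:
            self.conn.executemany(
                "INSERT OR REPLACE INTO lake_attribute VALUES (?,?,?)", list(rows)
            )

    def lake_attributes(self) -> pd.DataFrame:
        long = pd.read_sql_query(
            "SELECT lake_id, name, value FROM lake_attribute ORDER BY lake_id",
            self.conn,
        )
        if long.empty:
            return pd.DataFrame(columns=["lake_id"])
        return long.pivot(index="lake_id", columns="name", values="value").reset_index()

    def add_flags(self, flags: Iterable[FlagRecord]) -> int:
        """Record flags; duplicates on (target, rule_id) are ignored (idempotent)."""
        n = 0
        with self.conn:
            for f in flags:
                cur = self.conn.execute(
                    "INSERT OR IGNORE INTO flag (target, rule_id, severity,"
                    " disposition, note) VALUES (?,?,?,?,?)",
                    (f.target, f.rule_id, f.severity, f.disposition, f.note),
                )
                n += cur.rowcount
        return n

    def delete_observation(self, obs_id: int, flag: FlagRecord) -> None:
        """Egregious-value deletion: mark deleted, retain row + audit flag."""
        if flag.disposition != "deleted":
            raise StoreError("deletion requires a flag with disposition=deleted")
        with self.conn:
            self.conn.execute(
                "UPDATE observation SET deleted = 1 WHERE obs_id = ?", (obs_id,)
            )
            self.conn.execute(
                "INSERT OR IGNORE INTO flag (target, rule_id, severity, disposition,"
                " note) VALUES (?,?,?,?,?)",
                (flag.target, flag.rule_id, flag.severity, flag.disposition, flag.note),
            )

    def record_version(self, v: ExportVersion) -> None:
        latest = self.latest_version()
        if latest is not None and not (
            version_components(v.version_string) > version_components(latest)
        ):
            raise StoreError(
                f"version {v.version_string} does not increase over {latest}"
            )
        with self.conn:
            self.conn.execute(
                "INSERT INTO export_version VALUES (?,?,?,?,?)",
                (v.version_string, v.created_date, v.dataset_count,
                 v.observation_count, v.change_notes),
            )

    # -- queries ----------------------------------------------------------

    def latest_version(self) -> Optional[str]:
        rows = self.conn.execute(
            "SELECT version_string FROM export_version"
        ).fetchall()
        if not rows:
            return None
        return max((r[0] for r in rows), key=version_components)

    def counts(self) -> dict[str, int]:
        q = lambda sql: self.conn.execute(sql).fetchone()[0]
        return {
            "lakes": q("SELECT COUNT(*) FROM lake"),
            "census_lakes": q("SELECT COUNT(*) FROM lake WHERE is_census = 1"),
            "sources": q("SELECT COUNT(*) FROM source"),
            "observations": q("SELECT COUNT(*) FROM observation"),
            "live_observations": q(
                "SELECT COUNT(*) FROM observation WHERE deleted = 0"
            ),
            "deleted_observations": q(
                "SELECT COUNT(*) FROM observation WHERE deleted = 1"
            ),
            "flags": q("SELECT COUNT(*) FROM flag"),
            "zones": q("SELECT COUNT(*) FROM zone"),
        }

    def live_observations(self) -> pd.DataFrame:
        return pd.read_sql_query(
            "SELECT * FROM observation WHERE deleted = 0 ORDER BY obs_id", self.conn
        )

    def all_observations(self) -> pd.DataFrame:
        return pd.read_sql_query(
            "SELECT * FROM observation ORDER BY obs_id", self.conn
        )

    def flags(self) -> pd.DataFrame:
        return pd.read_sql_query("SELECT * FROM flag ORDER BY flag_id", self.conn)

    def zone_metrics(self) -> pd.DataFrame:
        return pd.read_sql_query(
            "SELECT * FROM zone_metric ORDER BY zone_id, theme, metric_name",
            self.conn,
        )

    def close(self) -> None:
        self.conn.close()


def init_store(path: str | Path, overwrite: bool = False) -> Store:
    """Create an empty store with all tables and constraint checks.

    Refuses to clobber an existing store unless ``overwrite`` is requested.
    """
    path = Path(path)
    if path.exists():
        if not overwrite:
            raise StoreError(f"{path} exists; pass overwrite=True to replace it")
        path.unlink()
    path.parent.mkdir(parents=True, exist_ok=True)
    conn = sqlite3.connect(path)
    conn.executescript(SCHEMA_SQL)
    return Store(conn, str(path))


def open_store(path: str | Path) -> Store:
    path = Path(path)
    if not path.exists():
        raise StoreError(f"no store at {path}")
    return Store(sqlite3.connect(path), str(path))


def schema_ddl() -> str:
    """The schema as plain SQL text, for documentation."""
    return SCHEMA_SQL


def validate_integrity(store: Store, census_min_area_ha: float = 4.0) -> list[str]:
    """Report every dangling reference, duplicate key, checklist failure,
    and flag-contract violation; empty list iff the store is consistent."""
    v: list[str] = []
    conn = store.conn

    for obs_id, lake_id in conn.execute(
        "SELECT obs_id, lake_id FROM observation WHERE lake_id NOT IN"
        " (SELECT lake_id FROM lake)"
    ):
        v.append(f"observation {obs_id} references absent lake_id {lake_id}")
    for obs_id, pid in conn.execute(
        "SELECT obs_id, program_id FROM observation WHERE program_id NOT IN"
        " (SELECT program_id FROM program)"
    ):
        v.append(f"observation {obs_id} references absent program {pid}")
    for obs_id, var in conn.execute(
        "SELECT obs_id, variable FROM observation WHERE variable NOT IN"
        " (SELECT canonical_name FROM variable)"
    ):
        v.append(f"observation {obs_id} references unknown variable {var}")
    for pid, sid in conn.execute(
        "SELECT program_id, source_id FROM program WHERE source_id NOT IN"
        " (SELECT source_id FROM source)"
    ):
        v.append(f"program {pid} references absent source {sid}")
    for (spid,) in conn.execute(
        "SELECT source_polygon_id FROM lake GROUP BY source_polygon_id"
        " HAVING COUNT(*) > 1"
    ):
        v.append(f"duplicate source_polygon_id {spid} in lake table")
    for sid, *checks in conn.execute(
        "SELECT s.source_id, s.methods_metadata_present, s.sample_depth_reported,"
        " s.location_reported, s.unaggregated_values FROM source s WHERE EXISTS"
        " (SELECT 1 FROM observation o WHERE o.source_id = s.source_id)"
    ):
        names = [
            "methods_metadata_present", "sample_depth_reported",
            "location_reported", "unaggregated_values",
        ]
        for name, ok in zip(names, checks):
            if not ok:
                v.append(
                    f"source {sid} has loaded observations but checklist item"
                    f" {name} is false"
                )
    for fid, sev, disp in conn.execute(
        "SELECT flag_id, severity, disposition FROM flag WHERE"
        " (severity = 'egregious') != (disposition = 'deleted')"
    ):
        v.append(f"flag {fid}: severity {sev} inconsistent with disposition {disp}")
    for (obs_id,) in conn.execute(
        "SELECT obs_id FROM observation WHERE deleted = 1 AND NOT EXISTS"
        " (SELECT 1 FROM flag WHERE target = 'obs:' || obs_id"
        "  AND disposition = 'deleted')"
    ):
        v.append(f"deleted observation {obs_id} lacks its audit flag")
    for zid, mzid in conn.execute(
        "SELECT zone_id, zone_id FROM zone_metric WHERE zone_id NOT IN"
        " (SELECT zone_id FROM zone)"
    ):
        v.append(f"zone metric references absent zone {zid}")
    for lake_id, area, census in conn.execute(
        "SELECT lake_id, area_ha, is_census FROM lake WHERE is_census = 1"
        " AND area_ha < ?", (census_min_area_ha,)
    ):
        v.append(
            f"lake {lake_id}: census flag with area {area} ha below the minimum"
        )
    return v
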