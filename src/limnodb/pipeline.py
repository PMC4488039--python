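"""Stage-by-stage pipeline orchestration.

Mirrors the database-construction workflow: generate (or receive) inputs,
initialize the store, harmonize each source into staged vertical
observations, georeference sites to census lakes and load attachable
observations, characterize lakes and zones, screen with two-tier QAQC, and
emit the versioned flat-file export with user documentation. Each stage
reads and writes files under one working directory, so stages are
individually resumable and idempotent on identical inputs; every stage
appends a provenance record to ``runlog.txt``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import export as export_mod
from . import fixtures as fx
from . import geojson
from .georeference import (
    LakeCandidate,
    apply_review_decisions,
    georeference_dataset,
    lonlat_to_local,
    matches_to_dataframe,
)
from .geoprocessing import (
    ZoneGeometry,
    build_buffer_zones,
    build_flow_network,
    assign_zone_membership,
    categorical_zone_metrics,
    classify_connectivity,
)
from .models import (
    ExportVersion,
    FlagRecord,
    MetadataChecklist,
    Observation,
    ProgramRecord,
    Provenance,
    SiteLocation,
    SourceDataset,
    ZoneDef,
    ZoneMetric,
    make_version_string,
)
from .qaqc import apply_geo_rules, apply_limno_rules, load_rules, qaqc_report
from .store import Store, init_store, open_store, validate_integrity
from .vocabulary import SourceMapping, harmonize_table, load_vocabulary


class StageOrderError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    workdir: str = "limnodb_run"
    seed: int = 1
    n_lakes: int = 30
    extent_m: float = 20000.0
    styles: list[str] = field(
        default_factory=lambda: ["wide_state", "long_citizen", "odd_university"]
    )
    n_samples: int = 60
    error_rate: float = 0.01
    n_egregious: int = 0
    censored_rate: float = 0.05
    tolerance_m: float = 100.0
    min_area_ha: float = 4.0
    buffer_distances_m: list[float] = field(default_factory=lambda: [100.0])
    clock: str = "2026-01-01"
    auto_accept_review: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _log(cfg: PipelineConfig, stage: str, message: str) -> None:
    path = Path(cfg.workdir) / "runlog.txt"
    path.parent.mkdir(parents=True, exist_ok=True)
    stamp = datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")
    with open(path, "a", encoding="utf-8") as fh:
        fh.write(f"{stamp} stage={stage} config={cfg.digest()} {message}\n")


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise StageOrderError(
            f"missing prerequisite {path.name}; run the {producer!r} stage first"
        )
    return path


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# Stages

def stage_fixtures(cfg: PipelineConfig) -> dict:
    """Generate the synthetic landscape and source datasets onto disk."""
    work = Path(cfg.workdir)
    fix = work / "fixtures"
    fix.mkdir(parents=True, exist_ok=True)

    vocab = load_vocabulary()
    land = fx.gen_landscape(cfg.n_lakes, cfg.extent_m, cfg.seed)
    geojson.write_layer(
        geojson.Layer(land.lakes, land.crs), fix / "waterbodies.geojson"
    )
    geojson.write_layer(geojson.Layer(land.streams, land.crs), fix / "streams.geojson")
    geojson.write_layer(
        geojson.Layer(land.landcover, land.crs), fix / "landcover.geojson"
    )
    for zone_type, zgs in land.zones.items():
        geojson.write_layer(
            geojson.Layer(
                [
                    geojson.feature(z.geometry, zone_id=z.zone.zone_id,
                                    zone_type=zone_type)
                    for z in zgs
                ],
                land.crs,
            ),
            fix / f"zones_{zone_type}.geojson",
        )
    land.lake_attributes().to_csv(fix / "lake_depths.csv", index=False)

    ledgers = {"landscape": land.ledger}
    for k, style in enumerate(cfg.styles):
        sf = fx.gen_source_dataset(
            land, vocab, style, n_samples=cfg.n_samples,
            error_rate=cfg.error_rate, n_egregious=cfg.n_egregious,
            censored_rate=cfg.censored_rate, seed=cfg.seed + 1000 + k,
        )
        sf.table.to_csv(fix / f"{sf.mapping.source_id}.csv", index=False)
        sf.mapping.to_yaml(fix / f"{sf.mapping.source_id}_mapping.yaml")
        sf.sites.to_csv(fix / f"{sf.mapping.source_id}_sites.csv", index=False)
        with open(fix / f"{sf.mapping.source_id}_meta.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "source": {
                        "source_id": sf.source.source_id,
                        "provider_type": sf.source.provider_type,
                        "provider_name": sf.source.provider_name,
                        "checklist": asdict(sf.source.metadata_checklist),
                    },
                    "program": asdict(sf.program),
                },
                fh,
            )
        ledgers[sf.mapping.source_id] = sf.ledger
    with open(fix / "ledger.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(ledgers), fh)
    _log(cfg, "fixtures", f"n_lakes={cfg.n_lakes} styles={cfg.styles}")
    return {"fixtures_dir": str(fix), "n_sources": len(cfg.styles)}


def stage_init(cfg: PipelineConfig, overwrite: bool = True) -> dict:
    work = Path(cfg.workdir)
    _require(work / "fixtures" / "waterbodies.geojson", "fixtures")
    store = init_store(work / "store.sqlite", overwrite=overwrite)
    vocab = load_vocabulary()
    store.add_variables(vocab.variables.values())

    land = _landscape_from_files(cfg)
    store.add_lakes(land.lake_records(cfg.min_area_ha))
    depths = pd.read_csv(work / "fixtures" / "lake_depths.csv")
    store.add_lake_attributes(
        (int(r["lake_id"]), name, float(r[name]))
        for _, r in depths.iterrows()
        for name in ("mean_depth_m", "max_depth_m")
    )
    counts = store.counts()
    store.close()
    _log(cfg, "init", f"lakes={counts['lakes']} census={counts['census_lakes']}")
    return counts


def _landscape_from_files(cfg: PipelineConfig) -> fx.Landscape:
    fix = Path(cfg.workdir) / "fixtures"
    lakes = geojson.read_layer(fix / "waterbodies.geojson")
    streams = geojson.read_layer(fix / "streams.geojson")
    landcover = geojson.read_layer(fix / "landcover.geojson")
    zones: dict[str, list[ZoneGeometry]] = {}
    for path in sorted(fix.glob("zones_*.geojson")):
        layer = geojson.read_layer(path)
        zone_type = path.stem.replace("zones_", "")
        zones[zone_type] = [
            ZoneGeometry(
                ZoneDef(zone_id=f["properties"]["zone_id"], zone_type=zone_type),
                f["geometry"],
            )
            for f in layer
        ]
    return fx.Landscape(
        crs=lakes.crs, extent_m=cfg.extent_m, lakes=lakes.features,
        streams=streams.features, zones=zones, landcover=landcover.features,
    )


_OBS_COLUMNS = [
    "variable", "value", "sample_date", "site_ref", "sample_depth_m",
    "depth_code", "censor_code", "detection_limit", "method_code",
    "source_id", "source_row_ref", "source_column_ref",
    "original_value_text", "original_units",
]


def stage_ingest(cfg: PipelineConfig) -> dict:
    """Harmonize every source table into staged vertical observations."""
    work = Path(cfg.workdir)
    fix = _require(work / "fixtures" / "ledger.json", "fixtures").parent
    _require(work / "store.sqlite", "init")
    staging = work / "staging"
    staging.mkdir(exist_ok=True)
    vocab = load_vocabulary()

    totals = {"observations": 0, "issues": 0}
    for mapping_path in sorted(fix.glob("*_mapping.yaml")):
        mapping = SourceMapping.from_yaml(mapping_path)
        table = pd.read_csv(
            fix / f"{mapping.source_id}.csv", dtype=str, keep_default_na=False
        )
        observations, issues = harmonize_table(table, mapping, vocab)
        rows = []
        for o in observations:
            p = o.provenance
            rows.append(
                {
                    "variable": o.variable, "value": o.value,
                    "sample_date": o.sample_date, "site_ref": o.site_ref,
                    "sample_depth_m": o.sample_depth_m, "depth_code": o.depth_code,
                    "censor_code": o.censor_code,
                    "detection_limit": o.detection_limit,
                    "method_code": o.method_code, "source_id": p.source_id,
                    "source_row_ref": p.source_row_ref,
                    "source_column_ref": p.source_column_ref,
                    "original_value_text": p.original_value_text,
                    "original_units": p.original_units,
                }
            )
        pd.DataFrame(rows, columns=_OBS_COLUMNS).to_csv(
            staging / f"obs_{mapping.source_id}.csv", index=False
        )
        pd.DataFrame(
            issues, columns=["row", "column", "reason", "text", "cell_attributable"]
        ).to_csv(staging / f"issues_{mapping.source_id}.csv", index=False)
        totals["observations"] += len(observations)
        totals["issues"] += len(issues)
    _log(cfg, "ingest", f"staged={totals['observations']} issues={totals['issues']}")
    return totals


def _staged_observations(path: Path) -> list[Observation]:
    frame = pd.read_csv(path, dtype={"site_ref": str, "source_row_ref": str})
    out = []
    for _, r in frame.iterrows():
        out.append(
            Observation(
                variable=r["variable"],
                value=None if pd.isna(r["value"]) else float(r["value"]),
                sample_date=str(r["sample_date"]),
                site_ref=str(r["site_ref"]),
                sample_depth_m=None if pd.isna(r["sample_depth_m"])
                else float(r["sample_depth_m"]),
                depth_code=str(r["depth_code"]),
                censor_code=str(r["censor_code"]),
                detection_limit=None if pd.isna(r["detection_limit"])
                else float(r["detection_limit"]),
                method_code=None if pd.isna(r["method_code"])
                else str(r["method_code"]),
                provenance=Provenance(
                    source_id=str(r["source_id"]),
                    source_row_ref=str(r["source_row_ref"]),
                    source_column_ref=str(r["source_column_ref"]),
                    original_value_text=str(r["original_value_text"]),
                    original_units=str(r["original_units"]),
                ),
            )
        )
    return out


def stage_georef(cfg: PipelineConfig) -> dict:
    """Match sites to census lakes, apply review, load attachable observations."""
    work = Path(cfg.workdir)
    staging = _require(work / "staging", "ingest")
    store = open_store(_require(work / "store.sqlite", "init"))
    fix = work / "fixtures"
    georef_dir = work / "georef"
    georef_dir.mkdir(exist_ok=True)

    land = _landscape_from_files(cfg)
    candidates = [
        LakeCandidate(r.lake_id, land.lakes[r.lake_id - 1]["geometry"], r.name)
        for r in land.lake_records(cfg.min_area_ha)
        if r.is_census
    ]

    loaded = unattached = 0
    for meta_path in sorted(fix.glob("*_meta.yaml")):
        with open(meta_path, encoding="utf-8") as fh:
            meta = yaml.safe_load(fh)
        src = SourceDataset(
            source_id=meta["source"]["source_id"],
            provider_type=meta["source"]["provider_type"],
            provider_name=meta["source"]["provider_name"],
            metadata_checklist=MetadataChecklist(**meta["source"]["checklist"]),
        )
        prog = ProgramRecord(**meta["program"])
        store.add_source(src)
        store.add_program(prog)

        site_table = pd.read_csv(fix / f"{src.source_id}_sites.csv", dtype=str)
        sites = []
        for _, r in site_table.iterrows():
            x, y, crs = float(r["x"]), float(r["y"]), str(r["crs"])
            if crs == fx.GEO_CRS:  # declared geographic: project before matching
                x, y = lonlat_to_local(x, y, fx.ORIGIN_LON, fx.ORIGIN_LAT)
                crs = land.crs
            sites.append(
                SiteLocation(
                    source_id=src.source_id, site_ref=str(r["site_ref"]),
                    x=x, y=y, reported_crs=crs,
                    reported_name=r.get("reported_name"),
                )
            )
        matches, review = georeference_dataset(
            sites, candidates, cfg.tolerance_m, lakes_crs=land.crs
        )
        matches_to_dataframe(review).to_csv(
            georef_dir / f"review_queue_{src.source_id}.csv", index=False
        )
        if cfg.auto_accept_review:
            decisions = pd.DataFrame(
                [
                    {
                        "site_ref": m.site_ref, "proposed_lake_id": m.lake_id,
                        "decision": "accept", "reviewer": "demo-reviewer",
                        "note": "distance within tolerance",
                    }
                    for m in review
                    if m.method in {"BUFFER", "NAME_ASSISTED"}
                ]
            )
            decisions.to_csv(
                georef_dir / f"decisions_{src.source_id}.csv", index=False
            )
            if not decisions.empty:
                matches = apply_review_decisions(matches, decisions)
        matches_to_dataframe(matches).to_csv(
            georef_dir / f"matches_{src.source_id}.csv", index=False
        )

        site_to_lake = {m.site_ref: m.lake_id for m in matches if m.attachable}
        observations = _staged_observations(staging / f"obs_{src.source_id}.csv")
        attach = []
        for o in observations:
            lake_id = site_to_lake.get(o.site_ref)
            if lake_id is None:
                unattached += 1
            else:
                attach.append(o.with_(lake_id=lake_id))
        store.add_observations(attach, prog.program_id)
        loaded += len(attach)

    problems = validate_integrity(store, cfg.min_area_ha)
    store.close()
    if problems:
        raise RuntimeError(f"integrity violations after load: {problems[:5]}")
    _log(cfg, "georef", f"loaded={loaded} unattached={unattached}")
    return {"loaded": loaded, "unattached": unattached}


def stage_geo(cfg: PipelineConfig) -> dict:
    """Zone construction, membership, zonal summaries, connectivity."""
    work = Path(cfg.workdir)
    store = open_store(_require(work / "store.sqlite", "init"))
    land = _landscape_from_files(cfg)
    records = land.lake_records(cfg.min_area_ha)
    census = [(r.lake_id, land.lakes[r.lake_id - 1]["geometry"])
              for r in records if r.is_census]

    buffers = build_buffer_zones(census, cfg.buffer_distances_m)
    all_zones = [zg for zgs in land.zones.values() for zg in zgs] + buffers
    store.add_zones([zg.zone for zg in all_zones])

    membership = assign_zone_membership(census, all_zones)
    store.add_zone_membership(membership)

    metrics = []
    for zg in all_zones:
        metrics.extend(
            categorical_zone_metrics(zg.zone, zg.geometry, land.landcover)
        )
    store.add_zone_metrics(metrics)

    network = build_flow_network(land.streams, census)
    connectivity = {
        lake_id: classify_connectivity(lake_id, network)
        for lake_id, _ in census
    }
    store.add_lake_attributes(
        (lake_id, "connectivity_class", cls)
        for lake_id, cls in sorted(connectivity.items())
    )
    counts = store.counts()
    store.close()
    _log(cfg, "geo", f"zones={counts['zones']} metrics={len(metrics)}")
    from collections import Counter

    return {
        "zones": counts["zones"],
        "metrics": len(metrics),
        "connectivity_counts": dict(Counter(connectivity.values())),
    }


def stage_qaqc(cfg: PipelineConfig) -> dict:
    work = Path(cfg.workdir)
    store = open_store(_require(work / "store.sqlite", "init"))
    if store.counts()["observations"] == 0:
        store.close()
        raise StageOrderError(
            "store holds no observations; run the 'georef' stage first"
        )
    vocab = load_vocabulary()
    rules = load_rules()

    metrics_frame = store.zone_metrics()
    zone_metrics = [
        ZoneMetric(
            zone_id=r["zone_id"], theme=r["theme"], metric_name=r["metric_name"],
            value=r["value"], units=r["units"], flag=r["flag"],
        )
        for _, r in metrics_frame.iterrows()
    ]
    lake_attrs = store.lake_attributes()
    geo_flags = apply_geo_rules(zone_metrics, lake_attrs, rules)

    live = store.live_observations()
    limno_flags, deletions = apply_limno_rules(live, vocab, rules)
    store.add_flags(geo_flags + [f for f in limno_flags if f.disposition == "flagged"])
    for f in limno_flags:
        if f.disposition == "deleted":
            obs_id = int(f.target.split(":")[1])
            store.delete_observation(obs_id, f)

    counts = store.counts()
    table, text = qaqc_report(geo_flags + limno_flags, counts["live_observations"])
    qdir = work / "qaqc"
    qdir.mkdir(exist_ok=True)
    table.to_csv(qdir / "flag_summary.csv", index=False)
    (qdir / "report.txt").write_text(text, encoding="utf-8")
    store.close()
    _log(cfg, "qaqc", f"flags={len(geo_flags) + len(limno_flags)}"
                      f" deleted={len(deletions)}")
    obs_flags = [f for f in limno_flags if f.disposition == "flagged"]
    return {
        "geo_flags": len(geo_flags),
        "limno_flags": len(obs_flags),
        "deleted": len(deletions),
        "flag_rate": len(obs_flags) / counts["live_observations"]
        if counts["live_observations"] else 0.0,
    }


def stage_export(cfg: PipelineConfig) -> dict:
    work = Path(cfg.workdir)
    store = open_store(_require(work / "store.sqlite", "init"))
    if not (Path(cfg.workdir) / "qaqc" / "report.txt").exists():
        store.close()
        raise StageOrderError("no QAQC report found; run the 'qaqc' stage first")
    vocab = load_vocabulary()
    counts = store.counts()
    version = ExportVersion(
        version_string=make_version_string(1, counts["sources"], 0),
        created_date=cfg.clock,
        dataset_count=counts["sources"],
        observation_count=counts["live_observations"],
        change_notes="initial export of the synthetic demonstration store",
    )
    out_dir = work / "export"
    manifest = export_mod.export_flat(store, out_dir, version)
    doc = export_mod.write_user_doc(
        version, manifest, vocab, out_dir / f"user_doc_{version.version_string}.txt"
    )
    if store.latest_version() != version.version_string:
        store.record_version(version)
    store.close()
    _log(cfg, "export", f"version={version.version_string} files={len(manifest)}")
    return {
        "version": version.version_string,
        "files": {k: str(v) for k, v in manifest.items()},
        "user_doc": str(doc),
    }


def run_all(cfg: PipelineConfig) -> dict:
    """fixtures -> init -> ingest -> georef -> geo -> qaqc -> export."""
    summary = {"config_digest": cfg.digest()}
    summary["fixtures"] = stage_fixtures(cfg)
    summary["init"] = stage_init(cfg)
    summary["ingest"] = stage_ingest(cfg)
    summary["georef"] = stage_georef(cfg)
    summary["geo"] = stage_geo(cfg)
    summary["qaqc"] = stage_qaqc(cfg)
    summary["export"] = stage_export(cfg)
    return summary
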