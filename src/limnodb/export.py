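"""Versioned flat-file export of the vertical store.

Statistical users work from horizontal tables, so each export transposes
the vertical observation store into one water-quality file — one row per
(lake, sample date, depth code), one column per selected variable — plus
one geospatial file per (theme, zone type) keyed by ZoneID, re-joinable to
lakes through the zone-membership table. Deleted values never appear;
flagged values appear alongside a parallel ``<variable>_flag`` column.

Collisions — two programs sampling the same lake/date/depth for the same
variable — are exported as the median with a MULTI marker in the flag
column; the raw duplicates stay in the vertical store.

Every export carries a three-component version string
(MAJOR.DATASETCOUNT zero-padded to 3.PATCH, e.g. 1.040.0 for a major
version holding 40 source datasets) and a user-documentation file listing
every exported file, every column, and its units and description from the
controlled vocabulary. Given the same store, selection, and clock, the
export is byte-identical.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .models import ExportVersion
from .store import Store
from .vocabulary import ControlledVocabulary

NA = "NA"


class ExportError(ValueError):
    pass


def _limno_frame(
    store: Store,
    variables: list[str],
    date_range: Optional[tuple[str, str]],
    flagged_targets: dict[str, str],
) -> pd.DataFrame:
    obs = store.live_observations()
    if date_range is not None:
        lo, hi = date_range
        obs = obs[(obs["sample_date"] >= lo) & (obs["sample_date"] <= hi)]
    obs = obs[obs["variable"].isin(variables)]

    key = ["lake_id", "sample_date", "depth_code"]
    rows: dict[tuple, dict] = {}
    for k, group in obs.groupby(key):
        record = dict(zip(key, k))
        for var in variables:
            vals = group[group["variable"] == var]
            present = vals[vals["value"].notna()]
            if len(present) == 0:
                continue
            flags = sorted(
                {
                    flagged_targets[f"obs:{int(i)}"]
                    for i in present["obs_id"]
                    if f"obs:{int(i)}" in flagged_targets
                }
            )
            if len(present) > 1:
                record[var] = float(present["value"].median())
                flags = ["MULTI"] + flags
            else:
                record[var] = float(present["value"].iloc[0])
            if flags:
                record[f"{var}_flag"] = ";".join(flags)
        rows[k] = record

    columns = key + [c for v in variables for c in (v, f"{v}_flag")]
    frame = pd.DataFrame(
        [rows[k] for k in sorted(rows)], columns=columns
    )
    return frame


def export_flat(
    store: Store,
    out_dir: str | Path,
    version: ExportVersion,
    variables: Optional[list[str]] = None,
    date_range: Optional[tuple[str, str]] = None,
    zone_types: Optional[list[str]] = None,
    themes: Optional[list[str]] = None,
) -> dict[str, Path]:
    """Write the horizontal flat files; returns the manifest {name: path}.

    Selection defaults to every variable, theme, and zone type present in
    the store. Unknown variables in an explicit selection are refused before
    anything is written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    known_vars = [
        r[0]
        for r in store.conn.execute(
            "SELECT canonical_name FROM variable ORDER BY canonical_name"
        )
    ]
    if variables is None:
        variables = known_vars
    else:
        unknown = [v for v in variables if v not in known_vars]
        if unknown:
            raise ExportError(f"unknown variables in selection: {unknown}")
    if not variables:
        raise ExportError("empty variable selection")

    flags = store.flags()
    flagged_targets = {
        str(r["target"]): str(r["rule_id"])
        for _, r in flags.iterrows()
        if r["disposition"] == "flagged"
    }

    manifest: dict[str, Path] = {}
    ver = version.version_string

    limno = _limno_frame(store, variables, date_range, flagged_targets)
    limno_path = out_dir / f"limno_values_all_{ver}.csv"
    _write_csv(limno, limno_path)
    manifest["limno_values_all"] = limno_path

    metrics = store.zone_metrics()
    zones = pd.read_sql_query("SELECT zone_id, zone_type FROM zone", store.conn)
    metrics = metrics.merge(zones, on="zone_id", how="left")
    if themes is not None:
        metrics = metrics[metrics["theme"].isin(themes)]
    if zone_types is not None:
        metrics = metrics[metrics["zone_type"].isin(zone_types)]
    for (theme, zone_type), group in sorted(
        metrics.groupby(["theme", "zone_type"]), key=lambda t: t[0]
    ):
        wide = group.pivot_table(
            index="zone_id", columns="metric_name", values="value", aggfunc="first"
        ).sort_index()
        wide = wide.reindex(sorted(wide.columns), axis=1).reset_index()
        name = f"geo_{theme}_{zone_type}"
        path = out_dir / f"{name}_{ver}.csv"
        _write_csv(wide, path)
        manifest[name] = path

    membership = pd.read_sql_query(
        "SELECT lake_id, zone_type, zone_id FROM lake_zone"
        " ORDER BY lake_id, zone_type",
        store.conn,
    )
    if not membership.empty:
        path = out_dir / f"geo_zone_membership_all_{ver}.csv"
        _write_csv(membership, path)
        manifest["geo_zone_membership_all"] = path

    return manifest


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    # RFC-4180 quoting, UTF-8, "NA" missing-value token, LF line endings
    frame.to_csv(
        path, index=False, na_rep=NA, quoting=csv.QUOTE_MINIMAL,
        lineterminator="\n", encoding="utf-8",
    )


_STRUCTURAL_COLUMNS = {
    "lake_id": ("surrogate lake identifier", "integer"),
    "sample_date": ("calendar date of sampling", "ISO-8601"),
    "depth_code": ("depth semantics: point/integrated/surface/unknown", "code"),
    "zone_id": ("ZoneID of the spatial extent", "text"),
    "zone_type": ("zone type (state/county/hu4/hu8/buffer/...)", "code"),
}


def write_user_doc(
    version: ExportVersion,
    manifest: dict[str, Path],
    vocab: ControlledVocabulary,
    out_path: str | Path,
) -> Path:
    """Emit the per-version user documentation file.

    Lists the version string and change notes, every exported file, and —
    for each column — units and a description drawn from the controlled
    vocabulary. A data column without a vocabulary entry is a completeness
    error: undocumented exports are not allowed.
    """
    lines = [
        f"Database export {version.version_string}",
        f"Created: {version.created_date}",
        f"Source datasets: {version.dataset_count}",
        f"Observations: {version.observation_count}",
        f"Changes: {version.change_notes or '(none)'}",
        "",
        "Files",
        "-----",
    ]
    for name in sorted(manifest):
        path = manifest[name]
        header = (
            Path(path).open(encoding="utf-8").readline().rstrip("\n").split(",")
        )
        lines.append(f"{Path(path).name}")
        for col in header:
            base = col[:-5] if col.endswith("_flag") else col
            if base in _STRUCTURAL_COLUMNS:
                desc, units = _STRUCTURAL_COLUMNS[base]
            elif base in vocab.variables:
                vdef = vocab.definition(base)
                desc, units = vdef.long_name, vdef.canonical_units
            elif base.startswith("proportion"):
                desc, units = "areal proportion of the named class", "fraction"
            else:
                raise ExportError(
                    f"column {col!r} in {Path(path).name} lacks a vocabulary"
                    " description; documentation must be complete"
                )
            if col.endswith("_flag"):
                desc = f"QAQC flag codes for {desc}"
                units = "codes"
            lines.append(f"  {col}: {desc} [{units}]")
        lines.append("")
    out_path = Path(out_path)
    out_path.write_text("\n".join(lines), encoding="utf-8")
    return out_path


def vertical_roundtrip(
    limno_path: str | Path, variables: Iterable[str]
) -> set[tuple]:
    """Reconstruct (lake_id, date, depth_code, variable, value) tuples from
    the horizontal water-quality file — the inverse of the transposition,
    used to verify that the export conserves every live value."""
    frame = pd.read_csv(
        limno_path, na_values=[NA], keep_default_na=False,
        float_precision="round_trip",
    )
    tuples: set[tuple] = set()
    for _, row in frame.iterrows():
        for var in variables:
            if var in frame.columns and pd.notna(row[var]):
                tuples.add(
                    (
                        int(row["lake_id"]), str(row["sample_date"]),
                        str(row["depth_code"]), var, float(row[var]),
                    )
                )
    return tuples


def expected_tuples(store: Store, variables: Iterable[str]) -> set[tuple]:
    """The tuple set the export should contain: live observations collapsed
    by the median-on-collision policy."""
    obs = store.live_observations()
    variables = list(variables)
    obs = obs[obs["variable"].isin(variables) & obs["value"].notna()]
    tuples: set[tuple] = set()
    for (lake_id, date, depth_code, var), group in obs.groupby(
        ["lake_id", "sample_date", "depth_code", "variable"]
    ):
        tuples.add(
            (int(lake_id), str(date), str(depth_code), var,
             float(group["value"].median()))
        )
    return tuples
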