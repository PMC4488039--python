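"""Two-tier QAQC rule engine.

Geo tier — verification of zone metrics and lake attributes against four
error families: values that make no ecological sense, values beyond prior
studies, values that are not technically feasible (e.g. lake mean depth
greater than maximum depth), and values reported as not-available although
source data exist. The geo tier only ever flags.

Limno tier — screening of harmonized observations: values above a
variable's deliberately extreme ``egregious_max`` are deleted (with an
audit flag and retained provenance); values outside the plausible range, or
internally inconsistent within one (lake, date, depth) sample — a dissolved
fraction exceeding its total form — are flagged QUESTIONABLE/INCONSISTENT
and kept. Rule application is scripted, order-independent, and idempotent,
so repeated screening never duplicates flags.

All thresholds live in configuration (the vocabulary's per-variable ranges
and the rule file's parameters), never in code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

from .models import FlagRecord, ZoneMetric
from .vocabulary import ControlledVocabulary


class QaqcConfigError(ValueError):
    pass


@dataclass
class QaqcRule:
    rule_id: str
    tier: str  # geo | limno
    category: str
    description: str = ""
    severity: str = "questionable"
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category == "EGREGIOUS" and self.severity != "egregious":
            raise QaqcConfigError(f"{self.rule_id}: EGREGIOUS rules must delete")
        if self.category != "EGREGIOUS" and self.severity == "egregious":
            raise QaqcConfigError(f"{self.rule_id}: only EGREGIOUS rules delete")

    @property
    def disposition(self) -> str:
        return "deleted" if self.severity == "egregious" else "flagged"


def load_rules(path: str | Path | None = None) -> list[QaqcRule]:
    """Load the rule configuration; default is the packaged rule set."""
    if path is None:
        text = (resources.files("limnodb") / "data/qaqc_rules.yaml").read_text(
            encoding="utf-8"
        )
        doc = yaml.safe_load(text)
    else:
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    rules: list[QaqcRule] = []
    for tier, key in (("geo", "geo_rules"), ("limno", "limno_rules")):
        for entry in doc.get(key, []):
            rules.append(QaqcRule(tier=tier, **entry))
    return rules


def _dedupe(flags: Iterable[FlagRecord]) -> list[FlagRecord]:
    seen: set[tuple[str, str]] = set()
    out: list[FlagRecord] = []
    for f in sorted(flags, key=lambda f: (f.target, f.rule_id)):
        key = (f.target, f.rule_id)
        if key not in seen:
            seen.add(key)
            out.append(f)
    return out


# ---------------------------------------------------------------------------
# Geo tier

def apply_geo_rules(
    zone_metrics: Iterable[ZoneMetric],
    lake_attributes: pd.DataFrame,
    rules: list[QaqcRule],
    zone_has_source_data: Optional[dict[str, bool]] = None,
) -> list[FlagRecord]:
    """Flag geo-tier violations; never alters or deletes any value.

    ``lake_attributes`` needs a ``lake_id`` column and, where available,
    ``mean_depth_m`` / ``max_depth_m``. ``zone_has_source_data`` says, per
    zone_id, whether the source layer actually covers the zone (used by the
    false-not-available rule).
    """
    by_cat = {r.category: r for r in rules if r.tier == "geo"}
    metrics = list(zone_metrics)
    known_metrics = {m.metric_name for m in metrics} | {"mean_depth_m", "max_depth_m"}
    beyond = by_cat.get("BEYOND_PRIOR")
    if beyond:
        for metric_name in beyond.parameters or {}:
            if metric_name not in known_metrics:
                raise QaqcConfigError(
                    f"{beyond.rule_id} references unknown metric {metric_name!r}"
                )

    flags: list[FlagRecord] = []

    rule = by_cat.get("NOT_FEASIBLE")
    if rule is not None and {"mean_depth_m", "max_depth_m"} <= set(
        lake_attributes.columns
    ):
        bad = lake_attributes[
            lake_attributes["mean_depth_m"] > lake_attributes["max_depth_m"]
        ]
        for _, row in bad.iterrows():
            flags.append(
                FlagRecord(
                    target=f"lake:{int(row['lake_id'])}:mean_depth_m",
                    rule_id=rule.rule_id, severity=rule.severity,
                    disposition=rule.disposition,
                    note=(
                        f"mean depth {row['mean_depth_m']} m exceeds max depth"
                        f" {row['max_depth_m']} m"
                    ),
                )
            )

    rule = by_cat.get("NOT_ECOLOGICAL")
    if rule is not None:
        for m in metrics:
            if (
                m.metric_name.startswith("proportion")
                and m.value is not None
                and not (0.0 <= m.value <= 1.0)
            ):
                flags.append(
                    FlagRecord(
                        target=f"zone:{m.zone_id}:{m.metric_name}",
                        rule_id=rule.rule_id, severity=rule.severity,
                        disposition=rule.disposition,
                        note=f"proportion {m.value} outside [0, 1]",
                    )
                )

    rule = by_cat.get("FALSE_NA")
    if rule is not None and zone_has_source_data:
        for m in metrics:
            if m.flag == "NO_DATA" and zone_has_source_data.get(m.zone_id, False):
                flags.append(
                    FlagRecord(
                        target=f"zone:{m.zone_id}:{m.metric_name}",
                        rule_id=rule.rule_id, severity=rule.severity,
                        disposition=rule.disposition,
                        note="reported not-available but source data cover the zone",
                    )
                )

    if beyond is not None:
        for m in metrics:
            prior_max = (beyond.parameters or {}).get(m.metric_name)
            if prior_max is not None and m.value is not None and m.value > prior_max:
                flags.append(
                    FlagRecord(
                        target=f"zone:{m.zone_id}:{m.metric_name}",
                        rule_id=beyond.rule_id, severity=beyond.severity,
                        disposition=beyond.disposition,
                        note=f"value {m.value} beyond prior maximum {prior_max}",
                    )
                )

    return _dedupe(flags)


# ---------------------------------------------------------------------------
# Limno tier

def apply_limno_rules(
    observations: pd.DataFrame,
    vocab: ControlledVocabulary,
    rules: list[QaqcRule],
) -> tuple[list[FlagRecord], list[int]]:
    """Screen observations (canonical units); returns (flags, obs_ids to delete).

    Rows need obs_id, lake_id, variable, value, sample_date, sample_depth_m,
    depth_code. Application is independent of row order.
    """
    limno = {r.category: r for r in rules if r.tier == "limno"}
    flags: list[FlagRecord] = []
    deletions: list[int] = []

    for var in observations["variable"].unique():
        if var not in vocab.variables:
            raise QaqcConfigError(
                f"no thresholds configured for variable {var!r} under the"
                " egregious rule"
            )

    egregious = limno.get("EGREGIOUS")
    questionable = limno.get("QUESTIONABLE")
    for _, row in observations.iterrows():
        if row["value"] is None or pd.isna(row["value"]):
            continue
        vdef = vocab.definition(row["variable"])
        value = float(row["value"])
        target = f"obs:{int(row['obs_id'])}"
        if egregious is not None and value > vdef.egregious_max:
            flags.append(
                FlagRecord(
                    target=target, rule_id=egregious.rule_id,
                    severity="egregious", disposition="deleted",
                    note=f"{row['variable']} = {value} > egregious_max"
                         f" {vdef.egregious_max}",
                )
            )
            deletions.append(int(row["obs_id"]))
        elif questionable is not None and not (
            vdef.valid_min <= value <= vdef.valid_max
        ):
            flags.append(
                FlagRecord(
                    target=target, rule_id=questionable.rule_id,
                    severity="questionable", disposition="flagged",
                    note=f"{row['variable']} = {value} outside plausible range"
                         f" [{vdef.valid_min}, {vdef.valid_max}]",
                )
            )

    inconsistent = limno.get("INCONSISTENT")
    if inconsistent is not None:
        pairs = inconsistent.parameters.get("pairs", [])
        key_cols = ["lake_id", "sample_date", "sample_depth_m", "depth_code"]
        grouped = observations.groupby(key_cols, dropna=False)
        for _, group in grouped:
            by_var = {
                r["variable"]: r
                for _, r in group.iterrows()
                if r["value"] is not None and not pd.isna(r["value"])
            }
            for dissolved, total in pairs:
                if dissolved in by_var and total in by_var:
                    dv, tv = by_var[dissolved], by_var[total]
                    if float(dv["value"]) > float(tv["value"]):
                        note = (
                            f"{dissolved} = {dv['value']} exceeds {total}"
                            f" = {tv['value']} in the same sample"
                        )
                        for r in (dv, tv):
                            flags.append(
                                FlagRecord(
                                    target=f"obs:{int(r['obs_id'])}",
                                    rule_id=inconsistent.rule_id,
                                    severity="questionable",
                                    disposition="flagged", note=note,
                                )
                            )

    return _dedupe(flags), sorted(set(deletions))


# ---------------------------------------------------------------------------
# Reporting

def qaqc_report(
    flags: Iterable[FlagRecord], live_observation_count: int
) -> tuple[pd.DataFrame, str]:
    """Per-rule counts, total flag rate over live observations, deletions."""
    flag_list = list(flags)
    rows = []
    for rule_id in sorted({f.rule_id for f in flag_list}):
        of_rule = [f for f in flag_list if f.rule_id == rule_id]
        rows.append(
            {
                "rule_id": rule_id,
                "count": len(of_rule),
                "deletions": sum(1 for f in of_rule if f.disposition == "deleted"),
            }
        )
    table = pd.DataFrame(rows, columns=["rule_id", "count", "deletions"])
    obs_flags = [f for f in flag_list if f.target.startswith("obs:")]
    rate = (
        len(obs_flags) / live_observation_count if live_observation_count else 0.0
    )
    deletions = sum(1 for f in flag_list if f.disposition == "deleted")
    text = (
        "QAQC summary\n"
        f"  flags total:          {len(flag_list)}\n"
        f"  observation flags:    {len(obs_flags)}\n"
        f"  deletions (egregious): {deletions}\n"
        f"  live observations:    {live_observation_count}\n"
        f"  flag rate:            {rate:.6f}\n"
    )
    if not table.empty:
        text += table.to_string(index=False) + "\n"
    return table, text
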