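"""Controlled vocabulary, unit registry, and source-table harmonization.

Heterogeneous source tables arrive in arbitrary wide or long schemas with
their own variable names, units, date formats, and detection-limit codes.
Each source ships with a declarative :class:`SourceMapping` (a structured
YAML file — mappings are data, not code) describing how to transpose it
into canonical vertical observations. Every source term is resolved through
the controlled vocabulary; every value is converted into canonical units;
every produced observation carries a provenance pointer back to the exact
source cell. Cells that cannot be harmonized become *issues*, never
silently dropped: for wide tables,

    count(observations) + count(cell-attributable issues)
        = count(non-null bound value cells).
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from .models import FlagRecord, Observation, Provenance, VariableDef


class VocabularyError(ValueError):
    pass


class DimensionError(ValueError):
    """Units of incompatible physical dimension (e.g. m -> ug/L)."""


class MappingError(ValueError):
    pass


class AggregatedDataError(ValueError):
    """Pre-aggregated sources violate the minimum dataset requirements."""


_PUNCT = str.maketrans({c: " " for c in string.punctuation})


def normalize_term(term: str) -> str:
    """Case-insensitive matching after whitespace/punctuation folding."""
    return re.sub(r"\s+", " ", str(term).translate(_PUNCT)).strip().lower()


def normalize_unit(symbol: str) -> str:
    return str(symbol).replace("µ", "u").replace("μ", "u").strip().lower()


class UnitRegistry:
    """Symbol -> (dimension, factor-to-base) with alias folding."""

    def __init__(self) -> None:
        self._units: dict[str, tuple[str, float]] = {}

    def register(
        self, symbol: str, dimension: str, factor: float, aliases: list[str] = ()
    ) -> None:
        if factor <= 0:
            raise VocabularyError(f"unit {symbol!r}: conversion factor must be positive")
        for sym in [symbol, *aliases]:
            key = normalize_unit(sym)
            if key in self._units and self._units[key] != (dimension, factor):
                raise VocabularyError(f"unit symbol {sym!r} registered twice")
            self._units[key] = (dimension, factor)

    def lookup(self, symbol: str) -> tuple[str, float]:
        key = normalize_unit(symbol)
        if key not in self._units:
            raise VocabularyError(f"unknown unit {symbol!r}")
        return self._units[key]

    def convert(self, value: float, from_unit: str, to_unit: str) -> float:
        """Scale ``value`` from one unit to another of the same dimension.

        Exact identity when the (normalized) units are equal.
        """
        if normalize_unit(from_unit) == normalize_unit(to_unit):
            self.lookup(from_unit)
            return value
        dim_f, fac_f = self.lookup(from_unit)
        dim_t, fac_t = self.lookup(to_unit)
        if dim_f != dim_t:
            raise DimensionError(
                f"cannot convert {from_unit!r} ({dim_f}) to {to_unit!r} ({dim_t})"
            )
        return value * fac_f / fac_t


class ControlledVocabulary:
    """Canonical variable definitions, synonym map, and unit registry."""

    def __init__(
        self,
        variables: list[VariableDef],
        synonym_map: dict[str, str],
        units: UnitRegistry,
    ):
        self.variables: dict[str, VariableDef] = {}
        for v in variables:
            key = normalize_term(v.canonical_name)
            if key in {normalize_term(k) for k in self.variables}:
                raise VocabularyError(
                    f"duplicate canonical name {v.canonical_name!r} (case-folded)"
                )
            self.variables[v.canonical_name] = v
        self.synonym_map = synonym_map
        self.units = units

    def resolve(self, term: str) -> Optional[str]:
        """Map a source term to a canonical name, or None if unknown."""
        key = normalize_term(term)
        for name in self.variables:
            if normalize_term(name) == key:
                return name
        return self.synonym_map.get(key)

    def definition(self, canonical_name: str) -> VariableDef:
        return self.variables[canonical_name]

    @property
    def water_quality_variables(self) -> list[VariableDef]:
        return [v for v in self.variables.values() if v.category != "depth"]

    @property
    def depth_variables(self) -> list[VariableDef]:
        return [v for v in self.variables.values() if v.category == "depth"]


def load_vocabulary(path: str | Path | None = None) -> ControlledVocabulary:
    """Parse a vocabulary YAML file; default is the packaged vocabulary.

    Raises :class:`VocabularyError` naming the offending term on duplicate
    canonical names or a synonym bound to two different canonicals.
    """
    if path is None:
        text = (resources.files("limnodb") / "data/vocabulary.yaml").read_text(
            encoding="utf-8"
        )
        doc = yaml.safe_load(text)
    else:
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)

    variables: list[VariableDef] = []
    synonym_map: dict[str, str] = {}
    seen_canon: dict[str, str] = {}
    for entry in doc.get("variables", []):
        entry = dict(entry)
        synonyms = entry.pop("synonyms", [])
        vdef = VariableDef(**entry)
        key = normalize_term(vdef.canonical_name)
        if key in seen_canon:
            raise VocabularyError(
                f"duplicate canonical name {vdef.canonical_name!r} "
                f"(collides with {seen_canon[key]!r} after case-folding)"
            )
        seen_canon[key] = vdef.canonical_name
        variables.append(vdef)
        for syn in synonyms:
            skey = normalize_term(syn)
            if skey in synonym_map and synonym_map[skey] != vdef.canonical_name:
                raise VocabularyError(
                    f"synonym {syn!r} bound to both {synonym_map[skey]!r} "
                    f"and {vdef.canonical_name!r}"
                )
            synonym_map[skey] = vdef.canonical_name

    registry = UnitRegistry()
    for u in doc.get("units", []):
        registry.register(
            u["symbol"], u["dimension"], float(u["factor"]), u.get("aliases", [])
        )
    return ControlledVocabulary(variables, synonym_map, registry)


def convert_units(
    value: float, from_unit: str, to_unit: str, registry: UnitRegistry
) -> float:
    return registry.convert(value, from_unit, to_unit)


# ---------------------------------------------------------------------------
# Source mappings

@dataclass
class SourceMapping:
    """Declarative recipe translating one source table into observations."""

    source_id: str
    orientation: str  # wide | long
    site_id_column: str
    date_column: str
    date_format: str = "%Y-%m-%d"
    aggregated: bool = False
    lat_column: Optional[str] = None
    lon_column: Optional[str] = None
    depth_column: Optional[str] = None
    depth_unit: str = "m"
    depth_code_default: str = "point"
    method_column: Optional[str] = None
    # wide: source column -> {"variable": canonical, "unit": symbol}
    variable_columns: dict[str, dict[str, str]] = field(default_factory=dict)
    # long:
    variable_name_column: Optional[str] = None
    value_column: Optional[str] = None
    unit_column: Optional[str] = None
    unit_defaults: dict[str, str] = field(default_factory=dict)
    # source prefix code -> censor code, e.g. {"<": "below_detection"}
    censor_conventions: dict[str, str] = field(default_factory=dict)
    thousands_separator: Optional[str] = None

    def __post_init__(self) -> None:
        if self.orientation not in {"wide", "long"}:
            raise MappingError(f"unknown orientation {self.orientation!r}")
        if not self.site_id_column:
            raise MappingError("exactly one site_id binding is required")
        if not self.date_column:
            raise MappingError("exactly one date binding is required")
        if self.orientation == "wide" and not self.variable_columns:
            raise MappingError("wide orientation requires >= 1 variable-bound column")
        if self.orientation == "long" and not (
            self.variable_name_column and self.value_column
        ):
            raise MappingError(
                "long orientation requires variable_name and value bindings"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SourceMapping":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        from dataclasses import asdict

        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def bound_columns(self) -> list[str]:
        cols = [self.site_id_column, self.date_column]
        for c in (
            self.lat_column,
            self.lon_column,
            self.depth_column,
            self.method_column,
            self.variable_name_column,
            self.value_column,
            self.unit_column,
        ):
            if c:
                cols.append(c)
        cols.extend(self.variable_columns)
        return cols


def _is_missing(raw: Any) -> bool:
    return raw is None or (isinstance(raw, float) and pd.isna(raw)) or (
        isinstance(raw, str) and raw.strip() == ""
    ) or raw is pd.NA


def _parse_number(text: str, thousands: Optional[str]) -> float:
    t = text.strip()
    if thousands:
        t = t.replace(thousands, "")
    return float(t)


def _issue(row: int, column: str, reason: str, text: str, cell: bool) -> dict:
    return {
        "row": row,
        "column": column,
        "reason": reason,
        "text": text,
        "cell_attributable": cell,
    }


def harmonize_table(
    raw_table: pd.DataFrame,
    mapping: SourceMapping,
    vocab: ControlledVocabulary,
) -> tuple[list[Observation], list[dict]]:
    """Transpose a source table into canonical vertical observations.

    One observation per non-missing harmonizable cell (wide) or row (long),
    values converted to canonical units and censor conventions translated.
    Unparseable cells are reported as issues, never silently dropped.
    """
    if mapping.aggregated:
        raise AggregatedDataError(
            f"source {mapping.source_id!r} is pre-aggregated; the minimum dataset "
            "requirements admit only unaggregated values"
        )
    missing = [c for c in mapping.bound_columns() if c not in raw_table.columns]
    if missing:
        raise MappingError(
            f"source {mapping.source_id!r}: mapping references absent columns {missing}"
        )
    if mapping.orientation == "wide":
        for col, binding in mapping.variable_columns.items():
            if vocab.resolve(binding["variable"]) is None:
                raise MappingError(
                    f"column {col!r} bound to unknown variable {binding['variable']!r}"
                )

    observations: list[Observation] = []
    issues: list[dict] = []

    for i in range(len(raw_table)):
        row = raw_table.iloc[i]

        def value_cells() -> list[tuple[str, Any]]:
            if mapping.orientation == "wide":
                return [
                    (c, row[c])
                    for c in mapping.variable_columns
                    if not _is_missing(row[c])
                ]
            v = row[mapping.value_column]
            return [] if _is_missing(v) else [(mapping.value_column, v)]

        site_raw = row[mapping.site_id_column]
        if _is_missing(site_raw):
            for col, raw in value_cells():
                issues.append(_issue(i, col, "missing_site", str(raw), True))
            continue
        site_ref = str(site_raw).strip()

        date_raw = row[mapping.date_column]
        sample_date: Optional[str] = None
        if not _is_missing(date_raw):
            try:
                sample_date = (
                    pd.to_datetime(str(date_raw).strip(), format=mapping.date_format)
                    .date()
                    .isoformat()
                )
            except (ValueError, TypeError):
                sample_date = None
        if sample_date is None:
            for col, raw in value_cells():
                issues.append(_issue(i, col, "bad_date", str(raw), True))
            continue

        depth_m: Optional[float] = None
        depth_code = "unknown"
        if mapping.depth_column:
            depth_raw = row[mapping.depth_column]
            if not _is_missing(depth_raw):
                try:
                    depth_m = vocab.units.convert(
                        _parse_number(str(depth_raw), mapping.thousands_separator),
                        mapping.depth_unit,
                        "m",
                    )
                    depth_code = mapping.depth_code_default
                except (ValueError, DimensionError):
                    issues.append(
                        _issue(i, mapping.depth_column, "bad_depth", str(depth_raw), False)
                    )

        method_code = None
        if mapping.method_column and not _is_missing(row[mapping.method_column]):
            method_code = str(row[mapping.method_column]).strip()

        for col, raw in value_cells():
            if mapping.orientation == "wide":
                binding = mapping.variable_columns[col]
                canonical = vocab.resolve(binding["variable"])
                unit = binding.get("unit") or vocab.definition(canonical).canonical_units
            else:
                term = row[mapping.variable_name_column]
                if _is_missing(term):
                    issues.append(_issue(i, col, "missing_variable", str(raw), True))
                    continue
                canonical = vocab.resolve(str(term))
                if canonical is None:
                    issues.append(
                        _issue(i, col, f"unknown_variable:{term}", str(raw), True)
                    )
                    continue
                unit = None
                if mapping.unit_column and not _is_missing(row[mapping.unit_column]):
                    unit = str(row[mapping.unit_column]).strip()
                unit = (
                    unit
                    or mapping.unit_defaults.get(canonical)
                    or vocab.definition(canonical).canonical_units
                )

            text = str(raw).strip()
            censor_code = "none"
            numeric_text = text
            for prefix, code in mapping.censor_conventions.items():
                if text.startswith(prefix):
                    censor_code = code
                    numeric_text = text[len(prefix):]
                    break
            try:
                number = _parse_number(numeric_text, mapping.thousands_separator)
            except ValueError:
                issues.append(_issue(i, col, "unparseable_value", text, True))
                continue

            target_unit = vocab.definition(canonical).canonical_units
            try:
                converted = vocab.units.convert(number, unit, target_unit)
            except (VocabularyError, DimensionError) as exc:
                issues.append(_issue(i, col, f"unit_error:{exc}", text, True))
                continue

            value: Optional[float] = converted
            limit: Optional[float] = None
            if censor_code == "below_detection":
                value, limit = None, converted
            elif censor_code == "above_detection":
                limit = converted

            observations.append(
                Observation(
                    variable=canonical,
                    value=value,
                    sample_date=sample_date,
                    site_ref=site_ref,
                    sample_depth_m=depth_m,
                    depth_code=depth_code,
                    censor_code=censor_code,
                    detection_limit=limit,
                    method_code=method_code,
                    provenance=Provenance(
                        source_id=mapping.source_id,
                        source_row_ref=str(i),
                        source_column_ref=col,
                        original_value_text=text,
                        original_units=unit,
                    ),
                )
            )

    return observations, issues


def apply_detection_limit_policy(
    obs: Observation, policy: str = "retain"
) -> tuple[Observation, Optional[FlagRecord]]:
    """Handle censored results.

    ``retain`` (default) leaves the value as reported (or absent) with the
    limit recorded; ``half_limit`` substitutes value = limit/2 and flags the
    substitution so downstream users can see it.
    """
    if obs.censor_code == "none":
        return obs, None
    if policy == "retain":
        return obs, None
    if policy == "half_limit":
        if obs.detection_limit is None:
            raise ValueError(
                "half-limit substitution requires a recorded detection limit"
            )
        substituted = obs.with_(value=obs.detection_limit / 2.0)
        flag = FlagRecord(
            target=f"obs:{obs.obs_id}" if obs.obs_id is not None else "obs:?",
            rule_id="DETECTION_LIMIT_SUBSTITUTION",
            severity="questionable",
            disposition="flagged",
            note=f"value set to limit/2 = {obs.detection_limit / 2.0}",
        )
        return substituted, flag
    raise ValueError(f"unknown detection-limit policy {policy!r}")


def issues_to_dataframe(issues: list[dict]) -> pd.DataFrame:
    cols = ["row", "column", "reason", "text", "cell_attributable"]
    return pd.DataFrame(issues, columns=cols)
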