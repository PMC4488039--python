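"""Domain records shared across the pipeline.

The database couples two modules: a *vertical* observation store (one row
per value of one variable for one lake on one date at one depth, with full
provenance) and a *horizontal* geospatial characterization of every census
lake at multiple spatial extents, joined through the aggregated-lakes table.
These dataclasses are the in-memory shapes of those rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

# Exclusion reasons for waterbodies that fail the census definition.
EXCLUDED_TOO_SMALL = "TOO_SMALL"
EXCLUDED_ARTIFICIAL = "ARTIFICIAL"
EXCLUDED_NON_PERENNIAL = "NON_PERENNIAL"

PROVIDER_TYPES = frozenset(
    {"federal", "state", "tribal", "citizen", "nonprofit", "university", "LTER"}
)

VARIABLE_CATEGORIES = frozenset(
    {"nutrient", "clarity", "carbon", "chlorophyll", "depth"}
)

DEPTH_CODES = frozenset({"point", "integrated", "surface", "unknown"})
CENSOR_CODES = frozenset({"none", "below_detection", "above_detection"})

CONNECTIVITY_CLASSES = (
    "ISOLATED",
    "HEADWATER",
    "DRAINAGE",
    "DRAINAGE_UPSTREAM_LAKES",
)


@dataclass
class LakeRecord:
    """A census or candidate lake polygon with identity and area.

    ``lake_id`` is a surrogate integer key assigned in polygon-file order;
    ``source_polygon_id`` preserves the identity carried by the input layer.
    """

    lake_id: int
    source_polygon_id: str
    name: Optional[str]
    centroid_x: float
    centroid_y: float
    area_ha: float
    geometry_ref: str
    is_census: bool
    excluded_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise ValueError(f"lake {self.lake_id}: area_ha must be positive")
        if self.is_census and self.excluded_reason is not None:
            raise ValueError(
                f"lake {self.lake_id}: census lake cannot carry an exclusion"
            )


@dataclass
class MetadataChecklist:
    """The four minimum requirements every loaded source must meet."""

    methods_metadata_present: bool = False
    sample_depth_reported: bool = False
    location_reported: bool = False
    unaggregated_values: bool = False

    def complete(self) -> bool:
        return (
            self.methods_metadata_present
            and self.sample_depth_reported
            and self.location_reported
            and self.unaggregated_values
        )


@dataclass
class SourceDataset:
    source_id: str
    provider_type: str
    provider_name: str
    provenance_uri: Optional[str] = None
    metadata_checklist: MetadataChecklist = field(default_factory=MetadataChecklist)

    def __post_init__(self) -> None:
        if self.provider_type not in PROVIDER_TYPES:
            raise ValueError(f"unknown provider_type {self.provider_type!r}")


@dataclass
class ProgramRecord:
    program_id: str
    source_id: str
    sampling_type: str  # survey | long_term
    temporal_resolution: str = ""

    def __post_init__(self) -> None:
        if self.sampling_type not in {"survey", "long_term"}:
            raise ValueError(f"unknown sampling_type {self.sampling_type!r}")


@dataclass
class VariableDef:
    """One canonical water-quality (or lake-depth) variable.

    ``valid_min``/``valid_max`` bound the physically plausible range;
    ``egregious_max`` is the deliberately extreme deletion threshold, set far
    above anything observable so that real extremes are never dropped.
    """

    canonical_name: str
    long_name: str
    canonical_units: str
    category: str
    valid_min: float
    valid_max: float
    egregious_max: float

    def __post_init__(self) -> None:
        if self.category not in VARIABLE_CATEGORIES:
            raise ValueError(
                f"{self.canonical_name}: unknown category {self.category!r}"
            )
        if not (self.valid_min <= self.valid_max <= self.egregious_max):
            raise ValueError(
                f"{self.canonical_name}: require valid_min <= valid_max <= egregious_max"
            )


@dataclass(frozen=True)
class Provenance:
    """Pointer from a stored value back to one cell of one source file."""

    source_id: str
    source_row_ref: str
    source_column_ref: str
    original_value_text: str
    original_units: str


@dataclass
class Observation:
    """One value of one variable for one lake on one date at one depth.

    ``lake_id`` is None until the site has been georeferenced; ``site_ref``
    carries the source's own site identifier through harmonization.
    """

    variable: str
    value: Optional[float]
    sample_date: str  # ISO-8601 calendar date
    provenance: Provenance
    site_ref: str = ""
    lake_id: Optional[int] = None
    program_id: Optional[str] = None
    sample_depth_m: Optional[float] = None
    depth_code: str = "unknown"
    censor_code: str = "none"
    detection_limit: Optional[float] = None
    method_code: Optional[str] = None
    obs_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.depth_code not in DEPTH_CODES:
            raise ValueError(f"unknown depth_code {self.depth_code!r}")
        if self.censor_code not in CENSOR_CODES:
            raise ValueError(f"unknown censor_code {self.censor_code!r}")
        if self.value is None and not (
            self.censor_code == "below_detection" and self.detection_limit is not None
        ):
            raise ValueError(
                "value may be absent only for below-detection results with a limit"
            )

    def with_(self, **kw) -> "Observation":
        return replace(self, **kw)


@dataclass
class FlagRecord:
    """One QAQC outcome attached to an observation or a zone metric."""

    target: str  # "obs:<obs_id>" or "zone:<zone_id>:<metric>"
    rule_id: str
    severity: str  # questionable | egregious
    disposition: str  # flagged | deleted
    note: str = ""

    def __post_init__(self) -> None:
        if (self.severity == "egregious") != (self.disposition == "deleted"):
            raise ValueError("egregious severity iff deleted disposition")


@dataclass
class ExportVersion:
    version_string: str
    created_date: str
    dataset_count: int
    observation_count: int
    change_notes: str = ""

    def components(self) -> tuple[int, int, int]:
        return version_components(self.version_string)


def make_version_string(major: int, dataset_count: int, patch: int) -> str:
    """MAJOR.DATASETCOUNT(zero-padded to 3).PATCH, e.g. 1.040.0."""
    return f"{major}.{dataset_count:03d}.{patch}"


def version_components(version_string: str) -> tuple[int, int, int]:
    parts = version_string.split(".")
    if len(parts) != 3:
        raise ValueError(f"version string {version_string!r} is not three-component")
    return tuple(int(p) for p in parts)  # type: ignore[return-value]


@dataclass
class SiteLocation:
    source_id: str
    site_ref: str
    x: float
    y: float
    reported_crs: str
    reported_name: Optional[str] = None

    def __post_init__(self) -> None:
        import math

        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"site {self.site_ref}: coordinates must be finite")
        if not self.reported_crs:
            raise ValueError(f"site {self.site_ref}: reported_crs must be declared")


@dataclass
class MatchResult:
    site_ref: str
    lake_id: Optional[int]
    method: str  # CONTAINS | BUFFER | NAME_ASSISTED | UNMATCHED
    distance_m: float
    needs_review: bool
    note: str = ""

    def __post_init__(self) -> None:
        if self.method == "CONTAINS" and self.distance_m != 0:
            raise ValueError("CONTAINS match must have zero boundary distance")
        if self.method == "UNMATCHED" and self.lake_id is not None:
            raise ValueError("UNMATCHED result cannot carry a lake_id")
        if self.method != "CONTAINS" and not self.needs_review and self.method != "UNMATCHED":
            # BUFFER / NAME_ASSISTED enter life needing review; review approval
            # clears the flag through apply_review_decisions only.
            pass

    @property
    def attachable(self) -> bool:
        """Observations may attach only via containment or approved review."""
        return self.lake_id is not None and not self.needs_review


@dataclass
class ZoneDef:
    zone_id: str
    zone_type: str  # state | county | hu4 | hu8 | hu12 | lake_watershed | buffer
    geometry_ref: str = ""
    buffer_distance_m: Optional[float] = None
    lake_id: Optional[int] = None  # buffer zones reference their lake

    def __post_init__(self) -> None:
        if self.zone_type == "buffer":
            if self.buffer_distance_m is None or self.lake_id is None:
                raise ValueError(
                    f"zone {self.zone_id}: buffer zones need a distance and a lake_id"
                )
        elif self.buffer_distance_m is not None:
            raise ValueError(
                f"zone {self.zone_id}: buffer_distance_m only valid for buffer zones"
            )


@dataclass
class ZoneMetric:
    zone_id: str
    theme: str  # landcover | climate | atmosphere | geology | topography
    metric_name: str
    value: Optional[float]
    units: str = ""
    year: Optional[int] = None
    flag: Optional[str] = None  # NO_DATA | PARTIAL_COVERAGE
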