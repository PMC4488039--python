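"""Link site-level sampling locations to census lake polygons.

Providers almost always report a latitude/longitude per sampling site, but
the reported point frequently falls just outside the lake polygon — on the
shoreline, a dock, or the public access point. Matching is therefore
semi-automated: a point inside exactly one census polygon links directly
(CONTAINS); otherwise the nearest polygon within a tolerance is proposed
(BUFFER) and queued for human review; near-ties between adjacent lakes are
resolved only when the reported site name identifies exactly one candidate
(NAME_ASSISTED), else they stay in the review queue. Observations attach to
lakes only through CONTAINS matches or review items a human has accepted.

All distances are point-to-boundary Euclidean distances in a shared
projected CRS (meters). Geographic (lon/lat) coordinates must be projected
first — :func:`lonlat_to_local` provides an exactly invertible local
equirectangular projection for that purpose; matching with mismatched CRS
strings is refused.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .models import MatchResult, SiteLocation
from .vocabulary import normalize_term

EARTH_RADIUS_M = 6371008.8
AMBIGUITY_WINDOW_M = 1.0
DEFAULT_TOLERANCE_M = 100.0


class CRSError(ValueError):
    pass


class GeoreferenceError(ValueError):
    pass


def lonlat_to_local(
    lon: float, lat: float, origin_lon: float, origin_lat: float
) -> tuple[float, float]:
    """Project geographic degrees to local metric x/y (equirectangular).

    The map is a bijection (scale fixed at the declared origin latitude), so
    round-tripping through :func:`local_to_lonlat` is exact to floating point.
    """
    kx = EARTH_RADIUS_M * math.cos(math.radians(origin_lat)) * math.pi / 180.0
    ky = EARTH_RADIUS_M * math.pi / 180.0
    return (lon - origin_lon) * kx, (lat - origin_lat) * ky


def local_to_lonlat(
    x: float, y: float, origin_lon: float, origin_lat: float
) -> tuple[float, float]:
    kx = EARTH_RADIUS_M * math.cos(math.radians(origin_lat)) * math.pi / 180.0
    ky = EARTH_RADIUS_M * math.pi / 180.0
    return x / kx + origin_lon, y / ky + origin_lat


@dataclass
class LakeCandidate:
    lake_id: int
    geometry: BaseGeometry
    name: Optional[str] = None


def match_site_to_lake(
    site: SiteLocation,
    lakes: list[LakeCandidate],
    tolerance_m: float = DEFAULT_TOLERANCE_M,
    lakes_crs: Optional[str] = None,
) -> MatchResult:
    """Match one site to at most one census lake polygon."""
    if tolerance_m < 0:
        raise ValueError("tolerance_m must be >= 0")
    if lakes_crs is not None and site.reported_crs != lakes_crs:
        raise CRSError(
            f"site {site.site_ref!r} declares CRS {site.reported_crs!r} but lake "
            f"layer is {lakes_crs!r}; project before matching"
        )

    point = Point(site.x, site.y)
    containing = sorted(
        (c.lake_id for c in lakes if c.geometry.covers(point))
    )
    if len(containing) == 1:
        return MatchResult(
            site_ref=site.site_ref, lake_id=containing[0], method="CONTAINS",
            distance_m=0.0, needs_review=False,
        )
    if len(containing) > 1:
        return MatchResult(
            site_ref=site.site_ref, lake_id=None, method="UNMATCHED",
            distance_m=0.0, needs_review=True,
            note=f"OVERLAP: inside lakes {containing}",
        )

    # nearest by boundary distance, sorted (distance, lake_id) for determinism
    dists = sorted(
        ((c.geometry.boundary.distance(point), c.lake_id, c) for c in lakes),
        key=lambda t: (t[0], t[1]),
    )
    within = [t for t in dists if t[0] <= tolerance_m]
    if not within:
        return MatchResult(
            site_ref=site.site_ref, lake_id=None, method="UNMATCHED",
            distance_m=dists[0][0] if dists else float("inf"),
            needs_review=True, note="beyond tolerance",
        )
    d_best = within[0][0]
    ties = [t for t in within if t[0] - d_best < AMBIGUITY_WINDOW_M]
    if len(ties) == 1:
        d, lake_id, _ = ties[0]
        return MatchResult(
            site_ref=site.site_ref, lake_id=lake_id, method="BUFFER",
            distance_m=d, needs_review=True, note="nearest within tolerance",
        )
    if site.reported_name:
        key = normalize_term(site.reported_name)
        named = [t for t in ties if t[2].name and normalize_term(t[2].name) == key]
        if len(named) == 1:
            d, lake_id, _ = named[0]
            return MatchResult(
                site_ref=site.site_ref, lake_id=lake_id, method="NAME_ASSISTED",
                distance_m=d, needs_review=True,
                note="ambiguous distance resolved by reported name",
            )
    return MatchResult(
        site_ref=site.site_ref, lake_id=None, method="UNMATCHED",
        distance_m=d_best, needs_review=True,
        note=f"AMBIGUOUS: lakes {[t[1] for t in ties]} within {AMBIGUITY_WINDOW_M} m",
    )


def georeference_dataset(
    sites: list[SiteLocation],
    lakes: list[LakeCandidate],
    tolerance_m: float = DEFAULT_TOLERANCE_M,
    lakes_crs: Optional[str] = None,
) -> tuple[list[MatchResult], list[MatchResult]]:
    """Match every site; returns (all matches, review queue).

    The review queue contains every result that needs review, including
    UNMATCHED sites (which a reviewer may resolve against external evidence).
    """
    seen: set[str] = set()
    for s in sites:
        if s.site_ref in seen:
            raise GeoreferenceError(
                f"duplicate site_ref {s.site_ref!r} within source {s.source_id!r}"
            )
        seen.add(s.site_ref)
    matches = [
        match_site_to_lake(s, lakes, tolerance_m, lakes_crs) for s in sites
    ]
    review = [m for m in matches if m.needs_review]
    return matches, review


def matches_to_dataframe(matches: list[MatchResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_ref": m.site_ref, "lake_id": m.lake_id, "method": m.method,
                "distance_m": m.distance_m, "needs_review": m.needs_review,
                "note": m.note,
            }
            for m in matches
        ]
    )


def apply_review_decisions(
    matches: list[MatchResult], decisions: pd.DataFrame
) -> list[MatchResult]:
    """Apply human review outcomes (accept lake_id | reject) to matches.

    ``decisions`` columns: site_ref, proposed_lake_id, decision, reviewer, note.
    The decisions table is itself part of provenance. CONTAINS matches are
    not reviewable; decisions naming them, or unknown sites, are errors.
    """
    by_ref = {m.site_ref: m for m in matches}
    out = {m.site_ref: m for m in matches}
    for _, row in decisions.iterrows():
        ref = str(row["site_ref"])
        if ref not in by_ref:
            raise GeoreferenceError(f"decision references unknown site {ref!r}")
        m = by_ref[ref]
        if m.method == "CONTAINS":
            raise GeoreferenceError(
                f"site {ref!r} matched by containment and is not reviewable"
            )
        decision = str(row["decision"]).strip().lower()
        reviewer = str(row.get("reviewer", ""))
        note = f"review:{decision} by {reviewer}: {row.get('note', '')}"
        if decision == "accept":
            lake_id = int(row["proposed_lake_id"])
            out[ref] = MatchResult(
                site_ref=ref, lake_id=lake_id, method=m.method,
                distance_m=m.distance_m, needs_review=False, note=note,
            )
        elif decision == "reject":
            out[ref] = MatchResult(
                site_ref=ref, lake_id=None, method="UNMATCHED",
                distance_m=m.distance_m, needs_review=False, note=note,
            )
        else:
            raise GeoreferenceError(f"unknown review decision {decision!r}")
    return [out[m.site_ref] for m in matches]
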