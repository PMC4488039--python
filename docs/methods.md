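# Methods

This note documents the models, conventions, and numerical choices behind
`limnodb`, and what the synthetic test fixtures do and do not demonstrate.

## Data model

The store couples two modules through the aggregated-lakes table, which
holds every lake's surrogate integer `lake_id` (assigned in polygon-file
order; the source layer's own identifier is preserved for traceability)
and spatial location.

- The **vertical observation module** stores one row per value of one
  variable for one lake on one date at one depth. Vertical (long) layout
  was chosen over a wide table because new variables can be added without
  schema change and because per-value metadata (censor code, method,
  provenance pointer) attaches naturally at the value level. Provenance is
  a five-tuple (source, row, column, original text, original units)
  resolving to exactly one cell of one input file.
- The **horizontal geospatial module** stores zone definitions (unique
  ZoneIDs across all zone types), per-zone metrics by theme, and the
  lake-to-zone membership table used to re-join metrics to lakes.

Deleted observations are never physically removed: they keep their row and
provenance, marked deleted with an audit flag, so at all times
`ingested = live + deleted`.

Dates are ISO-8601 calendar dates without timezone; time-of-day, when a
source reports it, is dropped from the key but survives in provenance
text. Depth is meters, positive downward; a missing depth is allowed only
with a depth code other than `point`.

Version strings are `MAJOR.NNN.PATCH` with NNN the zero-padded count of
loaded source datasets (so a major version holding 40 datasets is
`1.040.0`); components must strictly increase. This encoding is this
package's convention for the three-component scheme.

## Controlled vocabulary and units

The packaged vocabulary defines 17 water-quality variables — total
phosphorus, total nitrogen, total Kjeldahl nitrogen, nitrate-nitrite,
nitrite, ammonium, soluble reactive phosphorus, total dissolved
phosphorus, total dissolved nitrogen, dissolved Kjeldahl nitrogen,
dissolved organic carbon, total organic carbon, total organic nitrogen,
chlorophyll *a*, Secchi depth, apparent color, true color — plus lake
maximum and mean depth. Canonical units are µg/L for nutrients and
chlorophyll, mg/L for carbon, m for depths, PCU for color.

Term matching is case-insensitive after folding whitespace and
punctuation to single spaces; anything beyond that must be an explicit
synonym entry, to avoid false merges. Unit symbols are normalized (µ → u,
case-folded); each unit carries a dimension and a positive factor to the
dimension's base unit, so conversion is `x · f_from / f_to` with a
dimension check (m → µg/L is an error). Molar nutrient units convert
through atomic mass (P: 30.97, N: 14.01 g/mol). Identity conversions
return the input bit-for-bit; chained conversions agree with direct ones
to < 1e-9 relative.

Harmonization policy: values failing numeric parse become issues, never
coerced; thousands separators are stripped only when the mapping declares
one. Censor conventions are per-source prefix maps (e.g. `<` →
below-detection); a below-detection cell yields an observation with no
value and the converted limit recorded. The default detection-limit policy
is retain-and-qualify; an optional half-limit substitution fills
`value = limit/2` and flags the substitution. Half-limit is not the
default because detection limits are frequently missing or time-varying
in real archives, and substitution is an analysis choice, not a storage
fact.

## Georeferencing

Matching runs in one shared projected CRS; distances are point-to-boundary
Euclidean meters. Because reported coordinates often mark the shoreline or
an access point rather than open water:

- inside exactly one census polygon → CONTAINS (distance 0, no review);
- otherwise nearest polygon within the tolerance (default 100 m, the same
  order as a near-shore buffer) → BUFFER, queued for review;
- candidates within 1 m of the best distance are treated as tied; a tie is
  resolved only when the reported site name matches exactly one candidate
  (case/whitespace-folded, no fuzzy matching) → NAME_ASSISTED, still
  reviewed; unresolved ties and overlapping-polygon hits go to review
  unmatched rather than risking a silent wrong link.

Observations attach to lakes only through CONTAINS matches or review items
a human has accepted; the decisions table is part of provenance. Both the
tolerance and the 1 m ambiguity window are package choices, configurable
per run.

Geographic (lon/lat) inputs must be projected before matching; the package
provides an exactly invertible local equirectangular projection (scale
fixed at a declared origin latitude) for that purpose, and refuses to
match across mismatched CRS declarations. The projection is adequate at
the tens-of-kilometres extents the package targets; continental-scale
users should project externally.

## Census filter and geoprocessing

A census lake is a perennial body of relatively still water with surface
area ≥ 4 ha (boundary-inclusive), excluding entirely artificial
waterbodies (sewage-treatment and aquaculture classes by default).
Exclusions are labeled ARTIFICIAL, NON_PERENNIAL, or TOO_SMALL, checked in
that order.

All geoprocessing is vector-based: continuous themes are polygonal value
layers, so zonal statistics are exact area-weighted intersections rather
than raster approximations. Categorical proportions are normalized by the
covered area; partial coverage and no-data are flagged rather than
imputed. Zone membership is by lake centroid with a largest-intersection
fallback, so a lake straddling two states still receives exactly one
state. Buffer rings are (lake dilated by d) minus the lake.

The flow network snaps stream-segment endpoints to lake polygons within
50 m (default), collapses each lake to one node, and requires the
collapsed graph to be acyclic. The four connectivity classes operationalize
position in the hydrologic flowpath: ISOLATED (no stream edges), HEADWATER
(outflow only), DRAINAGE (inflow, no census lake upstream),
DRAINAGE_UPSTREAM_LAKES (inflow with ≥ 1 census lake upstream, by
transitive reachability).

## QAQC

Thresholds are configuration (the vocabulary's `valid_min`/`valid_max`/
`egregious_max` and the YAML rule file), never code constants. The
`egregious_max` values shipped are deliberately set orders of magnitude
above anything plausibly observable in a lake, so that genuinely extreme
but real values survive; only values above them are deleted, always with
an audit flag. Range violations and cross-variable inconsistencies
(dissolved > total within the same (lake, date, depth) sample key; no
interpolation across samples) are flagged and kept. The geo tier never
deletes. Rule application is order-independent and idempotent — flags are
keyed by (target, rule) — so repeated screening is safe.

## Export

One water-quality flat file (row = lake × date × depth code, column =
variable, `NA` missing token, RFC-4180 CSV) plus one geo file per theme ×
zone type keyed by ZoneID, plus the membership table. Collisions — two
programs sampling the same key — export the median with a `MULTI` marker
in the parallel flag column; raw duplicates remain queryable in the
vertical store. Flagged values export alongside their flag codes; deleted
values never export. Given the same store, selection, and a fixed clock
string, exports are byte-identical. The user-documentation file lists the
version, change notes, and every file and column with units and
descriptions drawn from the vocabulary; a column without a vocabulary
description is an error.

## Synthetic fixtures

The generator emulates the structural properties of real multi-source
compilations: packed square lakes with areas straddling the 4-ha census
threshold (the first lake is exactly 4.0 ha to pin the boundary case, with
~10 % artificial and ~5 % non-perennial classes); a constructed stream
network realizing all four connectivity classes; nested zone grids and an
8×8 land-cover tiling aligned to zone boundaries so that true per-zone
proportions are exact cell counts; and three source dialects (wide state
agency with mg/L units and ft depths, long citizen table in geographic
coordinates with below-detection codes, long university table with
idiosyncratic column names and mixed units). Site coordinates follow a
displacement mixture — 60 % at the lake centroid, 25 % 10–80 m beyond the
shoreline, 15 % 120–500 m away — mirroring typical shoreline/access-point
reporting. Injected violations are questionable-range by construction
(each triggers exactly one rule), with egregious values injected by an
explicit count, so recovered flag rates can be compared to the ledger
exactly.

What the fixtures do **not** emulate: statistical realism of limnological
values beyond plausible ranges, irregular lake shapes, braided or looping
hydrography, datum errors, or free-text chaos in real agency files.
Passing tests demonstrate the correctness of the mechanics (conservation,
conversion, matching, classification, audit), not field performance on
real archives.

Default problem sizes (30-lake landscape, three sources of 60 samples in
the demo; up to 1000 samples and 100 random polygons in the verification
script) were chosen to exercise every code path while keeping any run in
the seconds range.

## Known limitations

- No DEM-based watershed delineation: watershed polygons are accepted as a
  zone layer, not computed.
- No raster I/O; raster themes must be polygonized upstream.
- No fuzzy/phonetic name matching and no geocoding from names alone.
- No statistical outlier detection or imputation — out of scope for
  verification-style QAQC.
- The embedded SQLite store targets single-user pipeline runs, not
  multi-user serving.
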