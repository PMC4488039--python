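# limnodb

Tools for building an integrated, multi-scaled lake water-quality database
from many heterogeneous source datasets — the kind of data infrastructure
needed to study thousands of lakes across sub-continental extents, where
every agency, citizen-monitoring program, and university lab delivers its
measurements in its own schema, units, naming conventions, and
detection-limit codes.

`limnodb` is aimed at ecoinformatics practitioners and landscape
limnologists who need to assemble such a database reproducibly and with
full provenance, rather than through one-off manual edits.

## What it does

The package implements the complete database-construction workflow:

1. **Controlled vocabulary and harmonization.** A packaged vocabulary of 17
   water-quality variables (nutrients, water clarity, carbon, chlorophyll)
   plus lake depth, with synonyms and a unit registry. Each source table is
   described by a declarative YAML mapping (wide or long orientation,
   column bindings, date format, censor conventions); harmonization
   transposes it into *vertical* observations — one row per (lake,
   variable, date, depth, value) — converting units and translating
   below-detection codes. Every observation carries a provenance pointer
   to the exact source cell; unparseable cells become reported issues,
   never silent drops. Pre-aggregated sources are refused (minimum dataset
   requirements).
2. **Census population and georeferencing.** The census is every perennial
   waterbody ≥ 4 ha (boundary-inclusive), excluding entirely artificial
   ponds. Reported site coordinates are matched to census lake polygons:
   containment links directly; near-misses (shorelines, access points)
   within a 100 m tolerance are proposed and queued for human review;
   near-ties are resolved only by an unambiguous reported name.
3. **Multi-scale geospatial characterization.** Zones (states, counties,
   hydrologic units, near-shore buffer rings) carry unique ZoneIDs;
   categorical and continuous themes are summarized over any zone by exact
   vector-intersection areas. Each lake's hydrologic connectivity class —
   ISOLATED, HEADWATER, DRAINAGE, DRAINAGE_UPSTREAM_LAKES — is derived
   from a directed stream-network graph.
4. **Two-tier QAQC.** Geo-tier rules flag (never delete) values that make
   no ecological sense, exceed prior studies, are infeasible (mean depth >
   max depth), or are falsely "not available". Limno-tier rules delete
   values above deliberately extreme per-variable thresholds (with a
   retained audit record) and flag implausible or internally inconsistent
   values (a dissolved fraction exceeding its total form).
5. **Versioned export.** The vertical store is transposed into horizontal
   CSV flat files (one column per variable; one geo file per theme × zone
   type, re-joinable via ZoneIDs), with `MAJOR.NNN.PATCH` version strings
   (NNN = source-dataset count, e.g. `1.040.0` for 40 datasets) and a user
   documentation file describing every file and column.

A seeded synthetic-fixtures module generates a full landscape (lake
polygons, stream network, nested zones, land-cover tiling) and source
tables in three provider dialects, with a known-truth ledger, so the whole
pipeline is testable offline.

## Worked example

```
limnodb demo --workdir demo_run --seed 1
```

runs fixtures → init → ingest → georef → geo → qaqc → export and prints a
JSON summary. With seed 1 the generated landscape has 30 waterbodies of
which 19 pass the census filter; the three synthetic sources harmonize
into 360 observations with 0 issues; 280 attach to lakes (the remainder
report sites displaced beyond the matching tolerance, left in the review
queue); QAQC flags 3 observations as outside plausible ranges
(`flag rate: 0.010714`, matching the 1 % injected violation rate among
attached observations) and deletes none; the export is written as version
`1.003.0` with its user-documentation file.

Individual stages are available as subcommands (`limnodb ingest --config
cfg.yaml`, …); each appends a provenance record to `runlog.txt`, refuses
to run before its prerequisites, and is idempotent on identical inputs.

As a library:

```python
from limnodb import load_vocabulary, harmonize_table, SourceMapping
import pandas as pd

vocab = load_vocabulary()
table = pd.DataFrame({"site": ["A"], "date": ["2010-06-01"],
                      "TP mg/L": ["0.012"]})
mapping = SourceMapping(
    source_id="s1", orientation="wide", site_id_column="site",
    date_column="date",
    variable_columns={"TP mg/L": {"variable": "total_phosphorus",
                                  "unit": "mg/L"}},
)
obs, issues = harmonize_table(table, mapping, vocab)
print(obs[0].variable, obs[0].value)   # total_phosphorus 12.0 (µg/L)
```

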