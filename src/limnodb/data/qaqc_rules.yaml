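# Two-tier QAQC rule set.
#
# Geo tier: verification of the geospatial characterization — flags only,
# never deletes (errors in base layers cannot be ruled out, so values are
# annotated, not destroyed).
# Limno tier: screening of water-quality observations — values beyond the
# per-variable egregious_max (deliberately extreme thresholds from the
# vocabulary) are deleted with an audit record; merely implausible or
# internally inconsistent values are flagged and kept.
geo_rules:
  - rule_id: GEO_DEPTH_FEASIBLE
    category: NOT_FEASIBLE
    description: lake mean depth must not exceed lake maximum depth
  - rule_id: GEO_PROPORTION_RANGE
    category: NOT_ECOLOGICAL
    description: categorical area proportions must lie in [0, 1]
  - rule_id: GEO_FALSE_NA
    category: FALSE_NA
    description: metric reported not-available although source data cover the zone
  - rule_id: GEO_BEYOND_PRIOR
    category: BEYOND_PRIOR
    description: metric beyond the range detected in previous studies
    parameters: {}   # metric_name -> prior maximum; empty by default

limno_rules:
  - rule_id: LIMNO_EGREGIOUS_MAX
    category: EGREGIOUS
    description: value above the variable's egregious deletion threshold
    severity: egregious
  - rule_id: LIMNO_PLAUSIBLE_RANGE
    category: QUESTIONABLE
    description: value outside the variable's physically plausible range
    severity: questionable
  - rule_id: LIMNO_DISSOLVED_EXCEEDS_TOTAL
    category: INCONSISTENT
    description: dissolved fraction exceeds the total form in the same sample
    severity: questionable
    parameters:
      pairs:
        - [total_dissolved_phosphorus, total_phosphorus]
        - [soluble_reactive_phosphorus, total_phosphorus]
        - [total_dissolved_nitrogen, total_nitrogen]
        - [dissolved_organic_carbon, total_organic_carbon]
        - [dissolved_kjeldahl_nitrogen, total_kjeldahl_nitrogen]
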