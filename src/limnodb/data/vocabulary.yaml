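# Packaged controlled vocabulary: 17 water-quality variables (lake nutrients,
# water clarity, carbon, and pelagic chlorophyll) plus lake depth variables.
# valid_min/valid_max bound the physically plausible range in canonical units;
# egregious_max is the deliberately extreme deletion threshold, set far above
# any value ever plausibly observed in a lake so real extremes survive QAQC.
variables:
  - canonical_name: total_phosphorus
    long_name: Total phosphorus
    canonical_units: ug/L
    category: nutrient
    valid_min: 0.0
    valid_max: 5000.0
    egregious_max: 1000000.0
    synonyms: [tp, total p, total phos, phosphorus total, tot phosphorus]
  - canonical_name: total_nitrogen
    long_name: Total nitrogen
    canonical_units: ug/L
    category: nutrient
    valid_min: 0.0
    valid_max: 50000.0
    egregious_max: 10000000.0
    synonyms: [tn, total n, nitrogen total]
  - canonical_name: total_kjeldahl_nitrogen
    long_name: Total Kjeldahl nitrogen
    canonical_units: ug/L
    category: nutrient
    valid_min: 0.0
    valid_max: 50000.0
    egregious_max: 10000000.0
    synonyms: [tkn, kjeldahl nitrogen]
  - canonical_name: nitrate_nitrite
    long_name: Nitrate plus nitrite nitrogen
    canonical_units: ug/L
    category: nutrient
    valid_min: 0.0
    valid_max: 50000.0
    egregious_max: 10000000.0
    synonyms: [no3no2, no2no3, nitrate nitrite, no3 no2]
  - canonical_name: nitrite
    long_name: Nitrite nitrogen
    canonical_units: ug/L
    category: nutrient
    valid_min: 0.0
    valid_max: 20000.0
    egregious_max: 10000000.0
    synonyms: [no2]
  - canonical_name: ammonium
    long_name: Ammonium nitrogen
    canonical_units: ug/L
    category: nutrient
    valid_min: 0.0
    valid_max: 30000.0
    egregious_max: 10000000.0
    synonyms: [nh4, nh4 n, ammonia]
  - canonical_name: soluble_reactive_phosphorus
    long_name: Soluble reactive phosphorus
    canonical_units: ug/L
    category: nutrient
    valid_min: 0.0
    valid_max: 4000.0
    egregious_max: 1000000.0
    synonyms: [srp, ortho p, orthophosphate]
  - canonical_name: total_dissolved_phosphorus
    long_name: Total dissolved phosphorus
    canonical_units: ug/L
    category: nutrient
    valid_min: 0.0
    valid_max: 4000.0
    egregious_max: 1000000.0
    synonyms: [tdp, dissolved p]
  - canonical_name: total_dissolved_nitrogen
    long_name: Total dissolved nitrogen
    canonical_units: ug/L
    category: nutrient
    valid_min: 0.0
    valid_max: 40000.0
    egregious_max: 10000000.0
    synonyms: [tdn, dissolved n]
  - canonical_name: dissolved_kjeldahl_nitrogen
    long_name: Dissolved Kjeldahl nitrogen
    canonical_units: ug/L
    category: nutrient
    valid_min: 0.0
    valid_max: 40000.0
    egregious_max: 10000000.0
    synonyms: [dkn]
  - canonical_name: dissolved_organic_carbon
    long_name: Dissolved organic carbon
    canonical_units: mg/L
    category: carbon
    valid_min: 0.0
    valid_max: 300.0
    egregious_max: 100000.0
    synonyms: [doc]
  - canonical_name: total_organic_carbon
    long_name: Total organic carbon
    canonical_units: mg/L
    category: carbon
    valid_min: 0.0
    valid_max: 300.0
    egregious_max: 100000.0
    synonyms: [toc]
  - canonical_name: total_organic_nitrogen
    long_name: Total organic nitrogen
    canonical_units: ug/L
    category: nutrient
    valid_min: 0.0
    valid_max: 40000.0
    egregious_max: 10000000.0
    synonyms: [ton]
  - canonical_name: chlorophyll_a
    long_name: Chlorophyll a
    canonical_units: ug/L
    category: chlorophyll
    valid_min: 0.0
    valid_max: 3000.0
    egregious_max: 1000000.0
    synonyms: [chla, chl a, chlorophyll]
  - canonical_name: secchi_depth
    long_name: Secchi disk depth
    canonical_units: m
    category: clarity
    valid_min: 0.0
    valid_max: 50.0
    egregious_max: 1000.0
    synonyms: [secchi, sd, secchi disk, transparency]
  - canonical_name: color_apparent
    long_name: Apparent color
    canonical_units: PCU
    category: clarity
    valid_min: 0.0
    valid_max: 1000.0
    egregious_max: 100000.0
    synonyms: [apparent color, colora]
  - canonical_name: color_true
    long_name: True color
    canonical_units: PCU
    category: clarity
    valid_min: 0.0
    valid_max: 1000.0
    egregious_max: 100000.0
    synonyms: [true color, colort]
  - canonical_name: lake_depth_max
    long_name: Lake maximum depth
    canonical_units: m
    category: depth
    valid_min: 0.0
    valid_max: 600.0
    egregious_max: 2000.0
    synonyms: [max depth, maximum depth, zmax]
  - canonical_name: lake_depth_mean
    long_name: Lake mean depth
    canonical_units: m
    category: depth
    valid_min: 0.0
    valid_max: 400.0
    egregious_max: 2000.0
    synonyms: [mean depth, zmean]

# Unit registry: factor converts one unit to the base unit of its dimension
# (mass_concentration base ug/L; length base m; color base PCU). Molar
# concentrations of a named element are mass-convertible via atomic mass.
units:
  - symbol: ug/L
    dimension: mass_concentration
    factor: 1.0
    aliases: [ugl, ppb, mg/m3, ug l-1, ug P/L, ug N/L]
  - symbol: mg/L
    dimension: mass_concentration
    factor: 1000.0
    aliases: [mgl, ppm, mg l-1, g/m3, mg P/L, mg N/L]
  - symbol: g/L
    dimension: mass_concentration
    factor: 1000000.0
    aliases: [gl]
  - symbol: umol P/L
    dimension: mass_concentration
    factor: 30.97
    aliases: [umol p/l, umolp/l]
  - symbol: umol N/L
    dimension: mass_concentration
    factor: 14.01
    aliases: [umol n/l, umoln/l]
  - symbol: m
    dimension: length
    factor: 1.0
    aliases: [meter, meters, metres]
  - symbol: cm
    dimension: length
    factor: 0.01
    aliases: []
  - symbol: ft
    dimension: length
    factor: 0.3048
    aliases: [feet, foot]
  - symbol: in
    dimension: length
    factor: 0.0254
    aliases: [inch, inches]
  - symbol: PCU
    dimension: color
    factor: 1.0
    aliases: [pt-co, platinum cobalt units]
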