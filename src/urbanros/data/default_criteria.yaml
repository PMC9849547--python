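# Default assessment-criteria matrix for the nine recreational nature qualities.
#
# Noise levels name a per-source cap set from `noise_thresholds`; every cap is a
# STRICT upper bound (a component at exactly the cap fails). `min_size_ha` is a
# strict patch-level lower bound (> 25 ha), `min_slope_deg` a strict per-sample
# lower bound (> 10 degrees) combined with the slope_area_fraction rule.
#
# `nature_reserve: admitted` means a polygon flagged as nature reserve qualifies
# for the label regardless of its biotope type.
#
# Rows marked "uncertain" reproduce a best reading of a typographically garbled
# source table; edit and reload if your biotope key differs.
noise_thresholds:
  quiet:     {road: 45, light_rail: 44, rail: 54, aircraft: 40, industry: 45}
  moderate:  {road: 53, light_rail: 54, rail: 54, aircraft: 45, industry: 55}

labels:
  Serene:
    noise: quiet
    biotopes: [forest, heath_grassland, fen_bog, ruderal_meadow, hedges_groves,
               bare_rock, arable_land, beaches_dunes]   # water rows uncertain
    nature_reserve: ignored
  Spacious:
    noise: quiet
    min_size_ha: 25
    min_slope_deg: 10
    biotopes: [forest, heath_grassland, fen_bog, bare_rock]   # uncertain: fen, rock
    nature_reserve: ignored
  Wild:
    noise: quiet
    min_slope_deg: 10
    biotopes: [forest, heath_grassland, inland_water, ruderal_meadow,
               hedges_groves, bare_rock, arable_land, beaches_dunes]   # uncertain: water, arable
    nature_reserve: ignored
  SoughingOpenness:
    noise: moderate
    min_size_ha: 25
    biotopes: [forest, heath_grassland, fen_bog, inland_water, bare_rock]   # uncertain: water, rock
    nature_reserve: ignored
  SoughingWild:
    noise: moderate
    min_slope_deg: 10
    biotopes: [forest, heath_grassland, inland_water]   # uncertain: water
    nature_reserve: ignored
  SoughingOthers:
    noise: moderate
    biotopes: [bare_rock, beaches_dunes]   # uncertain: both
    nature_reserve: admitted
  Lush:
    noise: none
    biotopes: [forest, fen_bog, ruderal_meadow, hedges_groves, arable_land]   # uncertain: arable
    nature_reserve: admitted
  Culture:
    noise: none
    biotopes: [horticultural, urban_park]
    nature_reserve: admitted
  Common:
    noise: none
    biotopes: [heath_grassland, inland_water, horticultural, urban_park]   # uncertain: water
    nature_reserve: ignored
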