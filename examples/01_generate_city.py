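"""Generate a seeded synthetic city and inspect its layers.

The city is a square metric plane with green/blue patches of controlled size,
a jittered street grid (a few edges flagged as motorways), noise emitters for
five immission sources, recreation features, and building blocks populated by
three age cohorts whose totals are conserved exactly.
"""
from urbanros import CityConfig, generate_city

config = CityConfig(seed=1)
city = generate_city(config)

print(f"biotope polygons : {len(city.biotopes)}")
print(f"recreation feats : {len(city.features)}")
print(f"building blocks  : {len(city.blocks)}")
print(f"street edges     : {len(city.road_edges)} "
      f"({sum(e.motorway for e in city.road_edges)} motorway)")
for group, count in city.populations().items():
    print(f"population {group.value:<9}: {count}")

# Counts describe the generated vector layers; cohort totals always sum to
# config.total_population because apportionment uses largest-remainder rounding.
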