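"""Classify recreational nature qualities on a synthetic city.

Green/blue polygons are dissolved into contiguous patches; each patch receives
the qualities whose biotope, noise, size and slope criteria its components
meet. The area table reports per-quality qualifying area and its share of all
green space — shares overlap, so they do not sum to 100%.
"""
from urbanros import CityConfig, classify_rnq, generate_city, rnq_area_table

city = generate_city(CityConfig(seed=1))
result = classify_rnq(city.biotopes)

print(f"patches: {len(result.patches)}, total green space: "
      f"{result.total_area_ha:.1f} ha")
print(rnq_area_table(result).to_string(index=False))

# Quiet-gated qualities (Serene, Spacious, Wild) are rarer than the moderate
# and uncapped ones — raising a noise cap can only ever add labels.
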