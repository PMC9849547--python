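# urbanros

Equity-oriented analysis of urban green and blue space: which residents can
*walk* to green space of which recreational quality?

`urbanros` is a library for landscape planners and environmental-health
researchers. Given vector layers in a projected metric plane — biotope
polygons with per-source noise immissions and slope samples, recreation
features, a street edge list and age-stratified building blocks — it

1. dissolves green/blue biotopes into contiguous patches and classifies each
   patch into **recreational nature qualities (RNQ)** — *Serene, Spacious,
   Wild, Soughing openness, Soughing wild, Soughing others, Lush, Culture,
   Common* — by rule-based criteria on biotope type, noise, patch size and
   slope;
2. filters patches by the **potential demand** of three age cohorts
   (children ≤ 14 y, majority 15–64 y, elderly ≥ 65 y): minimum size 0.5 ha,
   per-source noise caps, and preferred infrastructure such as playgrounds or
   shade;
3. crosses qualities with cohorts into the **recreation opportunity spectrum
   (ROS)** — 27 types bundled into nine (class × group) combinations with
   high = {Serene, Spacious, Wild}, medium = the Soughing trio, low = the
   rest; and
4. computes **walking-network access**: motorway-free street graph, 7.5 m
   patch catchments, access points, block-centroid anchoring, and the share
   of each cohort's population within its walking distance (500 m for
   children and elderly people, 835 m for the majority).

Because municipal source data are rarely shippable, the package includes a
seeded **synthetic city generator** that emulates their statistical/spatial
structure — including *planted ground truth*: patches engineered so the
classifier's correct label set is known in advance.

## The rules at the core

A quality `q` applies to a component polygon of a dissolved patch iff

- the component's biotope type is admissible for `q` (or the polygon is a
  nature reserve and `q` admits the flag),
- every noise source is strictly below `q`'s cap set — quiet
  (road < 45, light rail < 44, rail < 54, aircraft < 40, industry < 45 dB)
  or moderate (< 53, < 54, < 54, < 45, < 55 dB) — where required,
- the dissolved patch exceeds 25 ha where `q` requires size, and
- at least 5% of the component's slope samples exceed 10° where `q` requires
  slopes.

All thresholds are strict and live in an editable YAML matrix
(`src/urbanros/data/default_criteria.yaml`); everything downstream evaluates
the matrix actually loaded. Network access uses the walking distance
`d_walk = 1.66 · d_linear` calibration (the 300 m/500 m pair).

## Worked example

```python
from urbanros import CityConfig, classify_rnq, generate_city, rnq_area_table

city = generate_city(CityConfig(seed=1))
result = classify_rnq(city.biotopes)
print(f"patches: {len(result.patches)}, total green space: {result.total_area_ha:.1f} ha")
print(rnq_area_table(result).to_string(index=False))
```

prints

```
patches: 25, total green space: 134.0 ha
             rnq  area_ha  share_pct
          Serene     42.0       31.3
        Spacious     13.1        9.8
            Wild     20.1       15.0
SoughingOpenness     30.0       22.4
    SoughingWild     20.1       15.0
  SoughingOthers      1.0        0.7
            Lush     57.3       42.8
         Culture     16.5       12.3
          Common     77.0       57.4
```

Each row is one quality's qualifying area and its share of all 134 ha of
green space; qualities overlap spatially, so shares do not sum to 100%. The
quiet-gated qualities are scarcer than the uncapped ones — exactly the
pattern that motivates the equity question. Continuing with the demand filter
(`examples/03_demand_and_spectrum.py`) shows the majority commanding 47.9% of
the green space as suitable against 7.3% for children; the access stage
(`examples/04_walking_access.py`) turns this into population coverage shares
per opportunity class.

The `examples/` directory holds one short script per capability; each prints
the numbers it computes and a line on what they mean. A thin CLI mirrors the
stages:

```bash
urbanros generate --seed 1 --out city/
urbanros rnq --layers city/ --out rnq.csv
urbanros all --seed 1 --out report/
```

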