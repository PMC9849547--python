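# Methods

This note documents the models, parameter choices and numerical conventions
behind `urbanros`, and what its synthetic test beds do and do not show about
real municipal data.

## Unit of assessment

The analysis unit is the **dissolved patch**: the union of all mutually
contiguous green/blue biotope polygons (every biotope type except sealed
surfaces). Two green polygons that touch only via a sealed polygon remain
separate patches. The size criterion ("> 25 ha", strict) is evaluated on the
dissolved patch; biotope, noise and slope criteria are evaluated per
component polygon, because one large patch can mix a quiet forest core with a
loud road-side meadow. A patch carries a quality as soon as one component
qualifies; the quality's *qualifying area* is the area of the union of its
qualifying components, so overlapping evidence inside one quality is never
double counted. Per-quality shares are reported against total dissolved
green-space area and deliberately do not sum to 100% (qualities overlap).

## Quality criteria

The criteria matrix ships as YAML and is validated on load: all nine
qualities present, each with a noise level, and quiet caps dominating
moderate caps per source. Defaults:

- noise: quiet gates Serene/Spacious/Wild, moderate gates the three Soughing
  qualities, the rest are uncapped. Caps are strict per-source upper bounds
  (quiet: road 45, light rail 44, rail 54, aircraft 40, industry 45 dB;
  moderate: 53/54/54/45/55 dB). Strictness follows the "< x dB" reading of
  the criteria; a component at exactly a cap fails.
- size: > 25 ha (strict, patch level) for Spacious and Soughing openness.
- slopes: > 10° for Spacious, Wild and Soughing wild. The source criterion
  names a threshold but not an aggregation over a polygon; we use an **area
  fraction rule**: the criterion holds if at least `slope_area_fraction`
  (default 0.05) of the component's slope samples exceed 10°. A small
  fraction is robust to single outlier samples; it is a keyword argument
  everywhere it matters.
- biotope admissibility per quality, plus a tri-state nature-reserve rule
  (ignored / admitted / required; default matrix uses *admitted* for
  Soughing others, Lush and Culture). Several biotope rows of the historical
  criteria table are typographically ambiguous; the YAML marks those entries
  "uncertain" in comments so users can re-read them for their own biotope
  key without touching code.

Monotonicity is a design invariant: raising any cap or lowering any
size/slope threshold can only add labels (property-tested).

## Potential demand

Cohorts partition the population: children (≤ 14 y), majority (15–64 y),
elderly (≥ 65 y). Defaults per cohort: minimum size 0.5 ha (*inclusive* —
the named value stays usable), noise NONE for children (the source table
places no cap on them), moderate caps for elderly and majority; special
preferences: children need a playground or sports ground in the patch or
within 50 m of it (the adjacency radius is unstated in the planning
literature; 50 m keeps "playground at the park edge" inside, and is
configurable); elderly need *any one* of shade/cool-air biotopes (forest,
urban park, blue space), an allotment garden in/near the patch, or an
accessible path on it (a disjunction, configurable to conjunction); the
majority has none. Benches are deliberately not a criterion (no reliable
municipal data exist for them). The noise-qualifying area of a retained
patch is the union of components passing the cohort's caps; children's is
therefore the whole patch.

Per-cohort summaries report suitable area, its share of overall green space,
and m² per head (`NaN` sentinel for a zero-population cohort).

## Opportunity spectrum

Quality × cohort intersections give up to 27 types; each record's area is
the intersection of the quality's qualifying geometry with the cohort's
demand-qualifying geometry. Bundling maps qualities to classes
(high = Serene/Spacious/Wild, medium = the Soughing trio, low = the rest);
per (cohort, class) the area is the **union** of member-quality regions
within each patch, so co-located qualities are not double counted. A patch
"fulfils" class c for cohort g if it contributes positive area to any member
quality — the patch-level membership the access stage consumes. The area
matrix carries the standing remark that cells must not be summed across
rows.

## Walking access

The street graph is undirected with metric lengths (validated ≥ straight-line
node distance); motorway and non-walkable edges are dropped, parallel edges
keep the shortest representative. The no-U-turn requirement is honoured
trivially: with nonnegative lengths, shortest paths on an undirected simple
graph never immediately backtrack, so no turn-expanded graph is needed —
identical results, far simpler.

Catchments are outward buffers of patch geometry, default width 7.5 m (a
typical two-lane carriageway). Access points are graph nodes covered by a
catchment plus nodes inserted where an edge crosses the catchment boundary;
splits preserve the declared edge length proportionally, so detour factors
survive splitting. Each block is anchored by projecting its centroid to the
nearest walkable edge; the straight-line projection offset is added to every
network distance, which keeps network distance ≥ straight-line distance (a
tested invariant). A block has access when its distance to the nearest access
point of a qualifying patch is within the cohort's walking distance —
children/elderly 500 m, majority 835 m. The 835 m constant is taken verbatim
from planning practice (10 min at ~5 km/h); the companion linear→walking
factor is reported as 1.66, reproduced by *truncating* 500/300 to two
decimals — the quoted convention, noting that half-up rounding would give
1.67.

Coverage is reported two ways: per exact class and cumulatively ("at least
class c"), the reading under which shares are provably nonincreasing in
class rank and nondecreasing in walking distance. District shares are binned
into five 20-point classes on 0.1-rounded percentages.

## Synthetic cities

The generator emulates the *structure* the analysis needs, not any real
city's composition:

- **Geometry** on a jittered grid: axis-aligned rectangles of exact target
  area (default mix spans 0.3–30 ha, bracketing both the 0.5 ha and 25 ha
  thresholds), split into 1–3 abutting components, placed with ≥ 30 m
  clearance so patches never merge accidentally.
- **Noise** from a log-distance decay law: received level
  `emission − 10·k·log10(max(d, d0)/d0)`, floored at 0 dB, maximised over a
  source category's emitters. This is a stand-in surface with controllable
  quiet/moderate/loud regimes — real analyses consume official strategic
  noise maps as *inputs*, so the propagation model is not part of the method
  under test, only the thresholds applied to it are.
- **Populations**: cohort totals by largest-remainder apportionment of
  `total_population` (default 20,000; default fractions 0.13/0.67/0.20
  children/majority/elderly, typical of a German city), then multinomial
  distribution over blocks — totals are conserved exactly.
- **Streets**: a ~250 m grid with jittered nodes, lengths = Euclidean ×
  (1 + U[0, 0.25]), 5% motorway edges, 2% otherwise non-walkable.
- **Planted ground truth**: a plan lists engineered patches (biotope, exact
  area, noise regime, slope regime, features). Regimes are realised by
  assigning archetype immission profiles and slope sample sets directly to
  the planted polygons — legitimate because immissions are input attributes
  regardless of origin. At plan build the expected label set is derived from
  the loaded criteria matrix; a plan declaring an inconsistent expectation,
  or one that cannot be placed, raises a planning error.

What passing on synthetic cities shows: the rule logic, geometry handling,
bookkeeping and network algorithms are correct under known ground truth.
What it does not show: anything about a real city's land-cover composition,
demography, noise field or street topology — synthetic results are not
planning evidence.

## Numerical conventions and degenerate inputs

Areas in hectares (tables rounded to 0.1 ha; shares to 0.1 percentage
points), distances in metres, noise in dB on [0, 120]. Zero total green
space raises an undefined-share error rather than returning 0/0. Unreachable
blocks carry an infinite distance sentinel; zero-population cohorts a `NaN`
per-capita sentinel. A city without blocks skips the access stage with a
warning but still writes all upstream tables. Geometry equality in round
trips is exact at well below 1e-6 m (GeoJSON is written at full float
precision). All randomness flows through one seeded NumPy generator; a fixed
seed and config give byte-identical layer files and tables.

Problem sizes in the shipped tests and the acceptance script — 4 km cities
with ~25 patches and 60 blocks, 20 planted cities, 100 oracle graphs of ≤ 50
nodes — were chosen as the smallest scales at which every property above is
exercised end to end; all run in seconds.

## Known limitations

- The per-component noise profile is evaluated at one representative point
  (the centroid at generation time); intra-polygon noise gradients are not
  modelled.
- "Easily accessible path" is modelled as an on-patch feature flag; whether
  it should describe the approach route instead is an open reading.
- Narrative quality descriptions ("no rubbish, no disturbing people") have
  no data counterpart and are not implemented.
- Access points are not deduplicated or spaced along a catchment boundary;
  with dense crossings this only adds redundant, never wrong, targets.
- The bundling map is taken as the complete three-tier reduction; no
  health-effect weighting of classes is attempted.
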