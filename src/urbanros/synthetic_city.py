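"""Seeded synthetic cities with the spatial structure the analysis assumes.

The generator lays green/blue patches of controlled area on a jittered grid,
synthesises per-source noise immissions with a log-distance decay law, draws
slope samples, places recreation features, builds a walkable street grid with
some motorway edges, and populates building blocks with three age cohorts whose
totals are conserved exactly. A ground-truth plan can additionally plant
patches engineered so the classifier's expected label set is known in advance,
which is the acceptance surface for classifier-recovery tests.

The decay law is a deliberately simple stand-in: real analyses consume official
strategic noise maps as inputs, so the shape of the surface is not part of the
method under test — only its thresholds are.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box

from .criteria import CriteriaMatrix
from .rnq import DEFAULT_SLOPE_AREA_FRACTION, classify_patch
from .types import (
    NOISE_SOURCES,
    AgeGroup,
    BiotopePolygon,
    BiotopeType,
    BuildingBlock,
    ConfigurationError,
    Feature,
    FeatureLayer,
    FeatureType,
    NoiseProfile,
    PlanningError,
    RoadEdge,
    UGSPatch,
)

# ---------------------------------------------------------------------------
# Noise model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseSource:
    """One immission source category with its emitter locations.

    Received level at distance d from an emitter:
    ``emission_db − 10·k·log10(max(d, d0)/d0)`` floored at 0 dB, where d0 is the
    reference distance and k the decay exponent. The profile takes, per source
    category, the maximum over that category's emitters.
    """

    kind: str
    emission_db: float
    ref_distance_m: float
    decay_exponent: float
    emitters: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in NOISE_SOURCES:
            raise ConfigurationError(f"unknown noise source kind {self.kind!r}")
        if self.ref_distance_m <= 0:
            raise ConfigurationError("reference distance must be positive")
        if self.decay_exponent <= 0:
            raise ConfigurationError("decay exponent must be positive")


def noise_at(
    point: tuple[float, float], sources: Sequence[NoiseSource]
) -> NoiseProfile:
    """Synthesise the immission profile at a location from all emitters."""
    x, y = point
    levels = {kind: 0.0 for kind in NOISE_SOURCES}
    for source in sources:
        for ex, ey in source.emitters:
            d = math.hypot(x - ex, y - ey)
            level = source.emission_db - 10.0 * source.decay_exponent * math.log10(
                max(d, source.ref_distance_m) / source.ref_distance_m
            )
            level = min(max(level, 0.0), 120.0)
            levels[source.kind] = max(levels[source.kind], level)
    return NoiseProfile(**levels)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: (kind, emission dB at the reference distance, reference distance m, decay exponent)
DEFAULT_NOISE_SPEC: tuple[tuple[str, float, float, float], ...] = (
    ("road", 75.0, 10.0, 2.5),
    ("light_rail", 68.0, 10.0, 2.5),
    ("rail", 72.0, 10.0, 2.5),
    ("aircraft", 62.0, 200.0, 2.0),
    ("industry", 68.0, 20.0, 2.2),
)

#: Emitter counts per source kind used by the generator.
DEFAULT_EMITTER_COUNTS: Mapping[str, int] = {
    "road": 25,
    "light_rail": 6,
    "rail": 5,
    "aircraft": 2,
    "industry": 4,
}

#: (area_ha, count) patch targets spanning the 0.5 ha and 25 ha thresholds.
DEFAULT_PATCH_MIX: tuple[tuple[float, int], ...] = (
    (0.3, 4),
    (0.8, 6),
    (2.0, 6),
    (5.0, 4),
    (12.0, 3),
    (30.0, 2),
)


@dataclass(frozen=True)
class CityConfig:
    """Parameters of one synthetic city.

    `age_fractions` is (children, majority, elderly) and must sum to 1.
    """

    extent_m: float = 4000.0
    n_blocks: int = 60
    age_fractions: tuple[float, float, float] = (0.13, 0.67, 0.20)
    total_population: int = 20_000
    patch_size_mix: tuple[tuple[float, int], ...] = DEFAULT_PATCH_MIX
    noise_source_spec: tuple[tuple[str, float, float, float], ...] = DEFAULT_NOISE_SPEC
    motorway_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extent_m <= 0:
            raise ConfigurationError("extent_m must be positive")
        if abs(sum(self.age_fractions) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"age fractions must sum to 1, got {sum(self.age_fractions)}"
            )
        if any(f < 0 for f in self.age_fractions):
            raise ConfigurationError("age fractions must be nonnegative")
        if self.n_blocks < 0:
            raise ConfigurationError("n_blocks must be nonnegative")
        if not 0 <= self.motorway_fraction <= 1:
            raise ConfigurationError("motorway_fraction must lie in [0, 1]")

    @property
    def group_fractions(self) -> dict[AgeGroup, float]:
        children, majority, elderly = self.age_fractions
        return {
            AgeGroup.CHILDREN: children,
            AgeGroup.MAJORITY: majority,
            AgeGroup.ELDERLY: elderly,
        }


# ---------------------------------------------------------------------------
# Ground-truth planning
# ---------------------------------------------------------------------------

#: Archetype immission profiles realising the three noise regimes.
REGIME_PROFILES: Mapping[str, NoiseProfile] = {
    # every source well below its quiet cap
    "quiet": NoiseProfile(road=35, light_rail=35, rail=40, aircraft=30, industry=35),
    # passes the moderate caps but fails the quiet caps (road 50 ≥ 45)
    "moderate": NoiseProfile(road=50, light_rail=50, rail=50, aircraft=42, industry=50),
    # fails the moderate caps
    "loud": NoiseProfile(road=60, light_rail=60, rail=60, aircraft=50, industry=60),
}

#: Slope sample sets realising the two slope regimes (degrees).
REGIME_SLOPES: Mapping[str, tuple[float, ...]] = {
    "flat": tuple([1.0, 2.0, 3.0, 4.0] * 5),
    # 30% of samples above 10°, comfortably over the 5% area-fraction rule
    "steep": tuple([3.0, 5.0, 7.0, 8.0, 12.0, 15.0, 18.0] * 3)[:20],
}


@dataclass(frozen=True)
class PlantedPatchSpec:
    """One engineered patch: biotope, area, noise/slope regime and features."""

    biotope_type: BiotopeType
    area_ha: float
    noise_regime: str = "quiet"
    slope_regime: str = "flat"
    features: tuple[FeatureType, ...] = ()
    nature_reserve: bool = False
    expected_labels: frozenset | None = None

    def __post_init__(self) -> None:
        if self.noise_regime not in REGIME_PROFILES:
            raise PlanningError(f"unknown noise regime {self.noise_regime!r}")
        if self.slope_regime not in REGIME_SLOPES:
            raise PlanningError(f"unknown slope regime {self.slope_regime!r}")
        if self.area_ha <= 0:
            raise PlanningError("planted patch area must be positive")


def expected_labels_for(
    spec: PlantedPatchSpec,
    matrix: CriteriaMatrix | None = None,
    slope_area_fraction: float = DEFAULT_SLOPE_AREA_FRACTION,
) -> frozenset:
    """Label set the classifier must assign to a patch built from `spec`."""
    if matrix is None:
        matrix = CriteriaMatrix.default()
    side = math.sqrt(spec.area_ha * 10_000.0)
    geometry = box(0.0, 0.0, side, side)
    component = BiotopePolygon(
        id="plan",
        geometry=geometry,
        biotope_type=spec.biotope_type,
        nature_reserve=spec.nature_reserve,
        noise=REGIME_PROFILES[spec.noise_regime],
        slope_samples=REGIME_SLOPES[spec.slope_regime],
    )
    patch = UGSPatch(id="plan", component_ids=("plan",), geometry=geometry)
    labels = classify_patch(patch, [component], matrix, slope_area_fraction)
    return frozenset(labels)


@dataclass(frozen=True)
class GroundTruthPlan:
    """A set of planted patch specs with their validated expected label sets."""

    specs: tuple[PlantedPatchSpec, ...]

    @classmethod
    def build(
        cls,
        specs: Iterable[PlantedPatchSpec],
        matrix: CriteriaMatrix | None = None,
        slope_area_fraction: float = DEFAULT_SLOPE_AREA_FRACTION,
    ) -> "GroundTruthPlan":
        """Validate specs against the criteria matrix and freeze expectations.

        Raises PlanningError if a spec declares an expected label set that the
        matrix cannot produce for its regimes.
        """
        validated = []
        for i, spec in enumerate(specs):
            derived = expected_labels_for(spec, matrix, slope_area_fraction)
            if spec.expected_labels is not None:
                if frozenset(spec.expected_labels) != derived:
                    raise PlanningError(
                        f"planted spec {i} expects labels "
                        f"{sorted(l.value for l in spec.expected_labels)} but the "
                        f"criteria matrix yields {sorted(l.value for l in derived)}"
                    )
                validated.append(spec)
            else:
                validated.append(replace(spec, expected_labels=derived))
        return cls(specs=tuple(validated))

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for i, spec in enumerate(self.specs):
            rows.append(
                {
                    "patch_id": f"T{i:03d}",
                    "biotope_type": spec.biotope_type.value,
                    "area_ha": spec.area_ha,
                    "noise_regime": spec.noise_regime,
                    "slope_regime": spec.slope_regime,
                    "features": "|".join(f.value for f in spec.features),
                    "expected_labels": "|".join(
                        sorted(l.value for l in spec.expected_labels)
                    ),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "patch_id",
                "biotope_type",
                "area_ha",
                "noise_regime",
                "slope_regime",
                "features",
                "expected_labels",
            ],
        )


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------


@dataclass
class CityDataset:
    """All layers of one generated city."""

    config: CityConfig
    biotopes: list[BiotopePolygon]
    features: FeatureLayer
    blocks: list[BuildingBlock]
    road_nodes: dict[str, tuple[float, float]]
    road_edges: list[RoadEdge]
    noise_sources: list[NoiseSource]
    planted_ids: tuple[str, ...] = ()

    def populations(self) -> dict[AgeGroup, int]:
        totals = {g: 0 for g in AgeGroup}
        for block in self.blocks:
            for group, count in block.population.items():
                totals[group] += count
        return totals


# ---------------------------------------------------------------------------
# Generation helpers
# ---------------------------------------------------------------------------


def _largest_remainder(total: int, fractions: Sequence[float]) -> list[int]:
    """Integer apportionment: floors plus largest-remainder correction."""
    raw = [total * f for f in fractions]
    counts = [int(math.floor(r)) for r in raw]
    shortfall = total - sum(counts)
    order = sorted(
        range(len(raw)), key=lambda i: (raw[i] - counts[i], -i), reverse=True
    )
    for i in order[:shortfall]:
        counts[i] += 1
    return counts


def _place_rect(
    rng: np.random.Generator,
    extent: float,
    width: float,
    height: float,
    placed: list[Polygon],
    margin: float,
    attempts: int = 400,
) -> Polygon:
    """Place an axis-aligned rectangle avoiding existing footprints."""
    for _ in range(attempts):
        x = rng.uniform(margin, max(extent - width - margin, margin + 1e-9))
        y = rng.uniform(margin, max(extent - height - margin, margin + 1e-9))
        candidate = box(x, y, x + width, y + height)
        clearance = candidate.buffer(margin)
        if all(not clearance.intersects(p) for p in placed):
            placed.append(candidate)
            return candidate
    raise PlanningError(
        f"could not place a {width:.0f}×{height:.0f} m rectangle in a "
        f"{extent:.0f} m extent without overlap"
    )


_RANDOM_BIOTOPE_WEIGHTS: tuple[tuple[BiotopeType, float], ...] = (
    (BiotopeType.FOREST, 0.30),
    (BiotopeType.HEATH_GRASSLAND, 0.10),
    (BiotopeType.FEN_BOG, 0.05),
    (BiotopeType.INLAND_WATER, 0.10),
    (BiotopeType.RUDERAL_MEADOW, 0.10),
    (BiotopeType.HEDGES_GROVES, 0.05),
    (BiotopeType.HORTICULTURAL, 0.05),
    (BiotopeType.ARABLE_LAND, 0.05),
    (BiotopeType.URBAN_PARK, 0.20),
)


def _random_slopes(rng: np.random.Generator) -> tuple[float, ...]:
    if rng.random() < 0.25:  # hilly polygon
        samples = np.abs(rng.normal(8.0, 4.0, size=20))
    else:
        samples = np.abs(rng.normal(3.0, 2.0, size=20))
    return tuple(float(min(s, 89.0)) for s in samples)


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------


def generate_city(
    config: CityConfig, plan: GroundTruthPlan | None = None
) -> CityDataset:
    """Generate one deterministic synthetic city (optionally with planted truth)."""
    rng = np.random.default_rng(config.seed)
    extent = config.extent_m

    # noise emitters
    sources: list[NoiseSource] = []
    for kind, emission, d0, k in config.noise_source_spec:
        n_emitters = DEFAULT_EMITTER_COUNTS.get(kind, 4)
        emitters = tuple(
            (float(rng.uniform(0, extent)), float(rng.uniform(0, extent)))
            for _ in range(n_emitters)
        )
        sources.append(
            NoiseSource(
                kind=kind,
                emission_db=emission,
                ref_distance_m=d0,
                decay_exponent=k,
                emitters=emitters,
            )
        )

    placed: list[Polygon] = []
    biotopes: list[BiotopePolygon] = []
    features: list[Feature] = []
    planted_ids: list[str] = []
    feature_counter = 0

    # planted patches first: they take spatial priority
    if plan is not None:
        for i, spec in enumerate(plan.specs):
            area_m2 = spec.area_ha * 10_000.0
            aspect = 1.0
            width = math.sqrt(area_m2 * aspect)
            height = area_m2 / width
            rect = _place_rect(rng, extent, width, height, placed, margin=30.0)
            pid = f"T{i:03d}"
            biotopes.append(
                BiotopePolygon(
                    id=pid,
                    geometry=rect,
                    biotope_type=spec.biotope_type,
                    nature_reserve=spec.nature_reserve,
                    noise=REGIME_PROFILES[spec.noise_regime],
                    slope_samples=REGIME_SLOPES[spec.slope_regime],
                )
            )
            planted_ids.append(pid)
            for ftype in spec.features:
                features.append(
                    Feature(
                        id=f"F{feature_counter:04d}",
                        geometry=rect.centroid,
                        feature_type=ftype,
                    )
                )
                feature_counter += 1

    # random patches per the size mix, split into 1–3 abutting components
    poly_counter = 0
    patch_targets = [
        area_ha for area_ha, count in config.patch_size_mix for _ in range(count)
    ]
    for area_ha in sorted(patch_targets, reverse=True):
        area_m2 = area_ha * 10_000.0
        aspect = float(rng.uniform(0.6, 1.6))
        width = math.sqrt(area_m2 * aspect)
        height = area_m2 / width
        rect = _place_rect(rng, extent, width, height, placed, margin=30.0)
        minx, miny, maxx, maxy = rect.bounds
        n_parts = int(rng.integers(1, 4))
        cuts = sorted(float(c) for c in rng.uniform(0.25, 0.75, size=n_parts - 1))
        xs = [minx] + [minx + c * (maxx - minx) for c in cuts] + [maxx]
        primary = _RANDOM_BIOTOPE_WEIGHTS[
            int(
                rng.choice(
                    len(_RANDOM_BIOTOPE_WEIGHTS),
                    p=[w for _, w in _RANDOM_BIOTOPE_WEIGHTS],
                )
            )
        ][0]
        reserve = bool(rng.random() < 0.08)
        part_types: list[BiotopeType] = []
        for j in range(n_parts):
            part = box(xs[j], miny, xs[j + 1], maxy)
            if j == 0 or rng.random() < 0.7:
                btype = primary
            else:
                btype = _RANDOM_BIOTOPE_WEIGHTS[
                    int(
                        rng.choice(
                            len(_RANDOM_BIOTOPE_WEIGHTS),
                            p=[w for _, w in _RANDOM_BIOTOPE_WEIGHTS],
                        )
                    )
                ][0]
            part_types.append(btype)
            centroid = part.centroid
            biotopes.append(
                BiotopePolygon(
                    id=f"B{poly_counter:04d}",
                    geometry=part,
                    biotope_type=btype,
                    nature_reserve=reserve,
                    noise=noise_at((centroid.x, centroid.y), sources),
                    slope_samples=_random_slopes(rng),
                )
            )
            poly_counter += 1
        # recreation features, preferentially in parks/gardens
        parkish = primary in (BiotopeType.URBAN_PARK, BiotopeType.HORTICULTURAL)
        point_in = Point(
            float(rng.uniform(minx + 1, maxx - 1)), float(rng.uniform(miny + 1, maxy - 1))
        )
        placements = (
            (FeatureType.PLAYGROUND, 0.6 if parkish else 0.15),
            (FeatureType.SPORTS_GROUND, 0.3 if parkish else 0.08),
            (FeatureType.ALLOTMENT_GARDEN, 0.25 if parkish else 0.05),
            (FeatureType.ACCESSIBLE_PATH, 0.35),
        )
        for ftype, prob in placements:
            if rng.random() < prob:
                features.append(
                    Feature(
                        id=f"F{feature_counter:04d}",
                        geometry=point_in,
                        feature_type=ftype,
                    )
                )
                feature_counter += 1
        if BiotopeType.INLAND_WATER in part_types and rng.random() < 0.5:
            features.append(
                Feature(
                    id=f"F{feature_counter:04d}",
                    geometry=point_in,
                    feature_type=FeatureType.BLUE_SPACE,
                )
            )
            feature_counter += 1

    # a few sealed polygons scattered between the green spaces
    for _ in range(5):
        side = float(rng.uniform(60, 140))
        try:
            rect = _place_rect(rng, extent, side, side, placed, margin=20.0)
        except PlanningError:
            continue
        centroid = rect.centroid
        biotopes.append(
            BiotopePolygon(
                id=f"B{poly_counter:04d}",
                geometry=rect,
                biotope_type=BiotopeType.SEALED_OTHER,
                noise=noise_at((centroid.x, centroid.y), sources),
                slope_samples=_random_slopes(rng),
            )
        )
        poly_counter += 1

    # street grid with jittered nodes
    n_grid = max(int(round(extent / 250.0)) + 1, 2)
    spacing = extent / (n_grid - 1)
    nodes: dict[str, tuple[float, float]] = {}
    for i in range(n_grid):
        for j in range(n_grid):
            jitter = spacing * 0.08
            x = min(max(i * spacing + float(rng.uniform(-jitter, jitter)), 0.0), extent)
            y = min(max(j * spacing + float(rng.uniform(-jitter, jitter)), 0.0), extent)
            nodes[f"n{i}_{j}"] = (x, y)
    edges: list[RoadEdge] = []
    for i in range(n_grid):
        for j in range(n_grid):
            u = f"n{i}_{j}"
            for di, dj in ((1, 0), (0, 1)):
                if i + di >= n_grid or j + dj >= n_grid:
                    continue
                v = f"n{i + di}_{j + dj}"
                (x1, y1), (x2, y2) = nodes[u], nodes[v]
                euclid = math.hypot(x2 - x1, y2 - y1)
                length = euclid * (1.0 + float(rng.uniform(0.0, 0.25)))
                motorway = bool(rng.random() < config.motorway_fraction)
                walkable = (not motorway) and (rng.random() >= 0.02)
                edges.append(
                    RoadEdge(u=u, v=v, length_m=length, motorway=motorway, walkable=walkable)
                )

    # building blocks with exactly conserved cohort populations
    blocks: list[BuildingBlock] = []
    if config.n_blocks > 0:
        order = [AgeGroup.CHILDREN, AgeGroup.MAJORITY, AgeGroup.ELDERLY]
        group_totals = dict(
            zip(order, _largest_remainder(config.total_population, config.age_fractions))
        )
        per_block = {
            group: rng.multinomial(total, [1.0 / config.n_blocks] * config.n_blocks)
            for group, total in group_totals.items()
        }
        n_districts = 3  # 3×3 district grid
        for b in range(config.n_blocks):
            side = float(rng.uniform(70, 110))
            try:
                rect = _place_rect(rng, extent, side, side, placed, margin=10.0)
            except PlanningError:
                # dense city: allow the block to overlap green space rather than fail
                x = float(rng.uniform(0, extent - side))
                y = float(rng.uniform(0, extent - side))
                rect = box(x, y, x + side, y + side)
                placed.append(rect)
            cx, cy = rect.centroid.x, rect.centroid.y
            di = min(int(cx / extent * n_districts), n_districts - 1)
            dj = min(int(cy / extent * n_districts), n_districts - 1)
            blocks.append(
                BuildingBlock(
                    id=f"BL{b:03d}",
                    geometry=rect,
                    population={g: int(per_block[g][b]) for g in order},
                    district_id=f"D{di}{dj}",
                )
            )

    return CityDataset(
        config=config,
        biotopes=biotopes,
        features=FeatureLayer(features),
        blocks=blocks,
        road_nodes=nodes,
        road_edges=edges,
        noise_sources=sources,
        planted_ids=tuple(planted_ids),
    )


def plant_ground_truth(
    config: CityConfig, plan: GroundTruthPlan
) -> tuple[CityDataset, pd.DataFrame]:
    """Generate a city containing one engineered patch per plan spec.

    Returns the dataset and the truth table mapping planted polygon ids to the
    label sets the classifier must recover.
    """
    total_planted = sum(spec.area_ha for spec in plan.specs)
    if total_planted * 10_000.0 > 0.5 * config.extent_m**2:
        raise PlanningError(
            f"planted area ({total_planted} ha) exceeds half the city extent"
        )
    dataset = generate_city(config, plan=plan)
    return dataset, plan.truth_table()


def expected_ros_areas(
    plan: GroundTruthPlan, matrix: CriteriaMatrix | None = None
) -> pd.DataFrame:
    """Plan bookkeeping: expected (group, quality) areas over the planted patches.

    Evaluates each spec's demand suitability analytically (size, regime noise
    against the group's caps, declared features) and credits the full patch
    area to every expected label, which is exact because planted patches are
    single polygons with uniform attributes.
    """
    from .criteria import evaluate_noise
    from .demand import SHADE_COOL_BIOTOPES, default_demand_criteria

    if matrix is None:
        matrix = CriteriaMatrix.default()
    criteria = default_demand_criteria()
    area: dict[tuple[AgeGroup, str], float] = {}
    for spec in plan.specs:
        for group in AgeGroup:
            crit = criteria[group]
            if spec.area_ha < crit.min_size_ha:
                continue
            profile = REGIME_PROFILES[spec.noise_regime]
            if not evaluate_noise(profile, crit.noise_level, matrix.thresholds):
                continue
            if group is AgeGroup.CHILDREN:
                if not any(
                    f in (FeatureType.PLAYGROUND, FeatureType.SPORTS_GROUND)
                    for f in spec.features
                ):
                    continue
            elif group is AgeGroup.ELDERLY:
                has_pref = spec.biotope_type in SHADE_COOL_BIOTOPES or any(
                    f
                    in (
                        FeatureType.ALLOTMENT_GARDEN,
                        FeatureType.ACCESSIBLE_PATH,
                        FeatureType.BLUE_SPACE,
                    )
                    for f in spec.features
                )
                if not has_pref:
                    continue
            for label in spec.expected_labels or ():
                key = (group, label.value)
                area[key] = area.get(key, 0.0) + spec.area_ha
    rows = [
        {"group": group.value, "rnq": label, "area_ha": value}
        for (group, label), value in sorted(
            area.items(), key=lambda kv: (kv[0][0].value, kv[0][1])
        )
    ]
    return pd.DataFrame(rows, columns=["group", "rnq", "area_ha"])
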