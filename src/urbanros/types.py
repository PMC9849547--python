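"""Core domain types shared across the analysis pipeline.

All geometries live in a projected planar coordinate system in metres; there is
no geodesy anywhere in the package. Areas are reported in hectares
(1 ha = 10,000 m²), distances and noise immission levels in metres and dB.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry


class ConfigurationError(ValueError):
    """A config object, criteria matrix or bundling map violates its contract."""


class InputError(ValueError):
    """An input layer or record is malformed (bad geometry, unknown type, ...)."""


class PlanningError(ValueError):
    """A ground-truth plan is infeasible or inconsistent with the criteria matrix."""


class UndefinedShareError(ValueError):
    """A share was requested against a zero denominator (no green-space area)."""


#: The five immission source categories of European strategic noise mapping.
NOISE_SOURCES = ("road", "light_rail", "rail", "aircraft", "industry")


@dataclass(frozen=True)
class NoiseProfile:
    """Per-source noise immission levels (dB) received at one location."""

    road: float = 0.0
    light_rail: float = 0.0
    rail: float = 0.0
    aircraft: float = 0.0
    industry: float = 0.0

    def __post_init__(self) -> None:
        for source in NOISE_SOURCES:
            value = getattr(self, source)
            if not math.isfinite(value):
                raise InputError(f"noise level for {source!r} is not finite: {value}")
            if value < 0 or value > 120:
                raise InputError(
                    f"noise level for {source!r} out of range [0, 120] dB: {value}"
                )

    def as_dict(self) -> dict[str, float]:
        return {source: getattr(self, source) for source in NOISE_SOURCES}

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, source) for source in NOISE_SOURCES)


class NoiseLevel(str, Enum):
    """Noise criterion level of a quality or demand rule.

    QUIET and MODERATE carry per-source caps (strict upper bounds); NONE means
    the rule places no noise requirement at all.
    """

    QUIET = "quiet"
    MODERATE = "moderate"
    NONE = "none"


class RNQ(str, Enum):
    """The nine recreational nature qualities."""

    SERENE = "Serene"
    SPACIOUS = "Spacious"
    WILD = "Wild"
    SOUGHING_OPENNESS = "SoughingOpenness"
    SOUGHING_WILD = "SoughingWild"
    SOUGHING_OTHERS = "SoughingOthers"
    LUSH = "Lush"
    CULTURE = "Culture"
    COMMON = "Common"


class ROSClass(str, Enum):
    """Bundled recreation-opportunity classes, ordered low < medium < high."""

    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"

    @property
    def rank(self) -> int:
        return {"low": 0, "medium": 1, "high": 2}[self.value]


class AgeGroup(str, Enum):
    """Population cohorts: children (≤14 y), majority (15–64 y), elderly (≥65 y)."""

    CHILDREN = "children"
    MAJORITY = "majority"
    ELDERLY = "elderly"


class BiotopeType(str, Enum):
    """Land-cover / habitat categories of the biotope mapping."""

    FOREST = "forest"
    HEATH_GRASSLAND = "heath_grassland"
    FEN_BOG = "fen_bog"
    INLAND_WATER = "inland_water"
    RUDERAL_MEADOW = "ruderal_meadow"
    HEDGES_GROVES = "hedges_groves"
    HORTICULTURAL = "horticultural"
    BARE_ROCK = "bare_rock"
    ARABLE_LAND = "arable_land"
    BEACHES_DUNES = "beaches_dunes"
    URBAN_PARK = "urban_park"
    SEALED_OTHER = "sealed_other"


#: Everything except sealed surfaces counts as green/blue space.
GREEN_BLUE_TYPES = frozenset(t for t in BiotopeType if t is not BiotopeType.SEALED_OTHER)


class FeatureType(str, Enum):
    """Recreation-infrastructure feature categories."""

    PLAYGROUND = "playground"
    SPORTS_GROUND = "sports_ground"
    ALLOTMENT_GARDEN = "allotment_garden"
    ACCESSIBLE_PATH = "accessible_path"
    BLUE_SPACE = "blue_space"


@dataclass
class BiotopePolygon:
    """One land-cover polygon with its type, noise immissions and slope samples."""

    id: str
    geometry: BaseGeometry
    biotope_type: BiotopeType
    nature_reserve: bool = False
    noise: NoiseProfile = field(default_factory=NoiseProfile)
    slope_samples: tuple[float, ...] = ()

    def validate(self) -> None:
        if self.geometry.is_empty or not self.geometry.is_valid:
            raise InputError(f"invalid geometry for biotope polygon {self.id!r}")
        if self.geometry.area <= 0:
            raise InputError(f"biotope polygon {self.id!r} has zero area")
        for angle in self.slope_samples:
            if not (0 <= angle <= 90):
                raise InputError(
                    f"slope sample {angle} of polygon {self.id!r} outside [0, 90]°"
                )

    @property
    def area_ha(self) -> float:
        return self.geometry.area / 10_000.0


@dataclass
class UGSPatch:
    """A dissolved, contiguous green/blue unit made of one or more biotope polygons."""

    id: str
    component_ids: tuple[str, ...]
    geometry: BaseGeometry

    @property
    def area_ha(self) -> float:
        return self.geometry.area / 10_000.0


@dataclass
class Feature:
    """A typed recreation-infrastructure feature (point or polygon)."""

    id: str
    geometry: BaseGeometry
    feature_type: FeatureType


class FeatureLayer:
    """Collection of typed features with per-type lookup."""

    def __init__(self, features: Iterable[Feature] = ()) -> None:
        self.features: list[Feature] = []
        for feat in features:
            if not isinstance(feat.feature_type, FeatureType):
                try:
                    feat.feature_type = FeatureType(feat.feature_type)
                except ValueError as exc:
                    raise InputError(
                        f"unknown feature type {feat.feature_type!r} "
                        f"for feature {feat.id!r}"
                    ) from exc
            self.features.append(feat)

    def by_type(self, feature_type: FeatureType) -> list[Feature]:
        return [f for f in self.features if f.feature_type is feature_type]

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)


@dataclass
class BuildingBlock:
    """Smallest population-reporting unit, with age-stratified resident counts."""

    id: str
    geometry: BaseGeometry
    population: dict[AgeGroup, int]
    district_id: str = "D0"

    def __post_init__(self) -> None:
        for group, count in self.population.items():
            if count < 0 or int(count) != count:
                raise InputError(
                    f"population of block {self.id!r} for {group} must be a "
                    f"nonnegative integer, got {count}"
                )

    @property
    def centroid(self) -> Point:
        return self.geometry.centroid

    @property
    def total_population(self) -> int:
        return int(sum(self.population.values()))


@dataclass
class RoadEdge:
    """One undirected street segment of the raw edge list."""

    u: str
    v: str
    length_m: float
    motorway: bool = False
    walkable: bool = True


def group_walking_distances() -> dict[AgeGroup, float]:
    """Default maximum walking distances (m) per age group.

    Children and elderly people: 500 m; majority: 835 m (10 min at ~5 km/h).
    """
    return {
        AgeGroup.CHILDREN: 500.0,
        AgeGroup.ELDERLY: 500.0,
        AgeGroup.MAJORITY: 835.0,
    }


def linear_to_walking_factor(linear_m: float = 300.0, walking_m: float = 500.0) -> float:
    """Ratio of walking distance to straight-line distance, truncated to 2 decimals.

    The conventional German major-city calibration pairs a 300 m linear distance
    with a 500 m walking distance, a ratio quoted as 1:1.66; truncation (not
    half-up rounding) reproduces that quoted constant.
    """
    if linear_m <= 0:
        raise InputError("linear distance must be positive")
    return math.floor(walking_m / linear_m * 100.0) / 100.0
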