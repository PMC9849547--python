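"""Age-group potential demand: filter patches by size, noise and preferred
infrastructure, and summarise the suitable area per cohort.

Children (≤14 y) need a playground or sports ground in or next to the patch and
face no noise cap of their own; elderly people (≥65 y) and the majority
(15–64 y) face the moderate per-source noise caps; elderly people additionally
need at least one of: shade/cool-air biotopes (forest, urban park, blue space),
an allotment garden, or an easily accessible path on the patch. Every group
requires at least 0.5 ha (inclusive).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from shapely.ops import unary_union

from .criteria import CriteriaMatrix, evaluate_noise
from .rnq import PatchClassification, RNQResult
from .types import (
    AgeGroup,
    BiotopePolygon,
    BiotopeType,
    FeatureLayer,
    FeatureType,
    InputError,
    NoiseLevel,
    UGSPatch,
    UndefinedShareError,
    group_walking_distances,
)

#: Biotope types that provide shade and cool air (elderly preference).
SHADE_COOL_BIOTOPES = frozenset(
    {BiotopeType.FOREST, BiotopeType.URBAN_PARK, BiotopeType.INLAND_WATER}
)

#: Default adjacency radius (m) for playgrounds/sports grounds next to a patch.
DEFAULT_FEATURE_RADIUS_M = 50.0


@dataclass(frozen=True)
class DemandCriteria:
    """Per-age-group usability thresholds and preferred features."""

    walking_distance_m: float
    min_size_ha: float = 0.5
    noise_level: NoiseLevel = NoiseLevel.MODERATE
    special_features: tuple[FeatureType, ...] = ()
    feature_radius_m: float = DEFAULT_FEATURE_RADIUS_M
    #: elderly only: whether one listed preference suffices (any) or all must hold
    feature_mode: str = "any"

    def __post_init__(self) -> None:
        if self.walking_distance_m <= 0:
            raise InputError("walking distance must be positive")
        if self.min_size_ha < 0:
            raise InputError("minimum size must be nonnegative")
        if self.feature_mode not in ("any", "all"):
            raise InputError("feature_mode must be 'any' or 'all'")


def default_demand_criteria() -> dict[AgeGroup, DemandCriteria]:
    """The standard cohort criteria (distances, 0.5 ha, noise caps, preferences)."""
    distances = group_walking_distances()
    return {
        AgeGroup.CHILDREN: DemandCriteria(
            walking_distance_m=distances[AgeGroup.CHILDREN],
            noise_level=NoiseLevel.NONE,
            special_features=(FeatureType.PLAYGROUND, FeatureType.SPORTS_GROUND),
        ),
        AgeGroup.ELDERLY: DemandCriteria(
            walking_distance_m=distances[AgeGroup.ELDERLY],
            noise_level=NoiseLevel.MODERATE,
            special_features=(
                FeatureType.ALLOTMENT_GARDEN,
                FeatureType.ACCESSIBLE_PATH,
                FeatureType.BLUE_SPACE,
            ),
        ),
        AgeGroup.MAJORITY: DemandCriteria(
            walking_distance_m=distances[AgeGroup.MAJORITY],
            noise_level=NoiseLevel.MODERATE,
            special_features=(),
        ),
    }


def special_preference(
    patch: UGSPatch,
    components: Sequence[BiotopePolygon],
    group: AgeGroup,
    features: FeatureLayer,
    radius_m: float = DEFAULT_FEATURE_RADIUS_M,
    criteria: DemandCriteria | None = None,
) -> bool:
    """Does the patch offer the group's preferred infrastructure?

    Children: a playground or sports ground inside the patch or within
    `radius_m` of it. Elderly: a disjunction over shade/cool biotopes,
    allotment gardens (in/near the patch), accessible paths and blue-space
    features on the patch. Majority: always true.
    """
    if radius_m < 0:
        raise InputError("feature radius must be nonnegative")
    if group is AgeGroup.MAJORITY:
        return True
    if group is AgeGroup.CHILDREN:
        for ftype in (FeatureType.PLAYGROUND, FeatureType.SPORTS_GROUND):
            for feat in features.by_type(ftype):
                if feat.geometry.distance(patch.geometry) <= radius_m:
                    return True
        return False
    # elderly
    tests = {
        "shade": any(c.biotope_type in SHADE_COOL_BIOTOPES for c in components),
        "allotment": any(
            feat.geometry.distance(patch.geometry) <= radius_m
            for feat in features.by_type(FeatureType.ALLOTMENT_GARDEN)
        ),
        "path": any(
            feat.geometry.intersects(patch.geometry)
            for feat in features.by_type(FeatureType.ACCESSIBLE_PATH)
        ),
        "blue": any(
            feat.geometry.intersects(patch.geometry)
            for feat in features.by_type(FeatureType.BLUE_SPACE)
        ),
    }
    if criteria is not None and criteria.feature_mode == "all":
        return all(tests.values())
    return any(tests.values())


@dataclass
class DemandQualification:
    """A patch retained for one group, with its noise-qualifying sub-area."""

    patch: UGSPatch
    geometry: object  # union of components passing the group's noise level
    area_ha: float


@dataclass
class DemandResult:
    """Suitable patches per age group."""

    suitable: dict[AgeGroup, dict[str, DemandQualification]]
    criteria: dict[AgeGroup, DemandCriteria]

    def area_ha(self, group: AgeGroup) -> float:
        return sum(q.area_ha for q in self.suitable[group].values())


def demand_filter(
    rnq_result: RNQResult,
    features: FeatureLayer,
    criteria: Mapping[AgeGroup, DemandCriteria] | None = None,
) -> DemandResult:
    """Apply each group's size, noise and preference criteria to all patches.

    A patch is retained for a group iff it meets the minimum size (inclusive),
    at least one component passes the group's noise level (the qualifying area
    is the union of passing components), and the group's special preference
    holds. For children the noise level is NONE, so the qualifying area is the
    whole patch.
    """
    crits = dict(default_demand_criteria())
    if criteria:
        crits.update(criteria)
    thresholds = rnq_result.matrix.thresholds
    suitable: dict[AgeGroup, dict[str, DemandQualification]] = {g: {} for g in AgeGroup}
    for pc in rnq_result.patches:
        for group in AgeGroup:
            crit = crits[group]
            if pc.patch.area_ha < crit.min_size_ha:
                continue
            passing = [
                c
                for c in pc.components
                if evaluate_noise(c.noise, crit.noise_level, thresholds)
            ]
            if not passing:
                continue
            if not special_preference(
                pc.patch, pc.components, group, features, crit.feature_radius_m, crit
            ):
                continue
            geometry = unary_union([c.geometry for c in passing])
            suitable[group][pc.patch.id] = DemandQualification(
                patch=pc.patch, geometry=geometry, area_ha=geometry.area / 10_000.0
            )
    return DemandResult(suitable=suitable, criteria=crits)


def demand_summary(
    demand: DemandResult,
    total_ugs_area_ha: float,
    populations: Mapping[AgeGroup, int],
) -> pd.DataFrame:
    """Per-group suitable area (ha), share of overall green space, m² per head."""
    if total_ugs_area_ha <= 0:
        raise UndefinedShareError("total green-space area is zero; shares undefined")
    rows = []
    for group in AgeGroup:
        area = demand.area_ha(group)
        pop = int(populations.get(group, 0))
        per_capita = area * 10_000.0 / pop if pop > 0 else math.nan
        rows.append(
            {
                "group": group.value,
                "suitable_area_ha": round(area, 1),
                "share_pct": round(100.0 * area / total_ugs_area_ha, 1),
                "population": pop,
                "sqm_per_capita": round(per_capita, 1) if pop > 0 else math.nan,
            }
        )
    return pd.DataFrame(rows)
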