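"""Dissolve green/blue biotope polygons into patches and classify their
recreational nature qualities.

The unit of assessment is the contiguous dissolved patch: the size criterion
("> 25 ha") is evaluated on the dissolved patch, while noise, biotope and slope
criteria are evaluated per component polygon, since a large patch can mix a
quiet forest core with a loud road-side meadow. A patch carries a quality label
as soon as one component qualifies; the label's qualifying area is the area of
the union of its qualifying components, so overlapping evidence is never
counted twice within a label.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from shapely import STRtree
from shapely.ops import unary_union

from .criteria import CriteriaMatrix, LabelCriteria, evaluate_noise
from .types import (
    BiotopePolygon,
    BiotopeType,
    InputError,
    RNQ,
    UGSPatch,
    UndefinedShareError,
)

#: Fraction of a component's slope samples that must exceed the slope threshold
#: for the slope criterion to count as satisfied.
DEFAULT_SLOPE_AREA_FRACTION = 0.05


@dataclass
class LabelQualification:
    """Qualifying evidence of one quality label on one patch."""

    area_ha: float
    geometry: object  # shapely geometry: union of qualifying components
    component_ids: tuple[str, ...]


@dataclass
class PatchClassification:
    """One dissolved patch with its component polygons and label assignments."""

    patch: UGSPatch
    components: tuple[BiotopePolygon, ...]
    labels: dict[RNQ, LabelQualification] = field(default_factory=dict)

    @property
    def label_set(self) -> frozenset[RNQ]:
        return frozenset(self.labels)


@dataclass
class RNQResult:
    """Classification of a whole city: all patches plus total-area accounting."""

    patches: list[PatchClassification]
    matrix: CriteriaMatrix

    @property
    def total_area_ha(self) -> float:
        return sum(pc.patch.area_ha for pc in self.patches)

    def by_id(self) -> dict[str, PatchClassification]:
        return {pc.patch.id: pc for pc in self.patches}


def dissolve_ugs(polygons: Sequence[BiotopePolygon]) -> list[UGSPatch]:
    """Merge green/blue polygons into maximal contiguous patches.

    Sealed surfaces are excluded before adjacency is computed, so two green
    polygons that touch only via a sealed polygon stay in separate patches.
    """
    greens = [p for p in polygons if p.biotope_type is not BiotopeType.SEALED_OTHER]
    for poly in greens:
        poly.validate()
    if not greens:
        return []
    tree = STRtree([p.geometry for p in greens])
    graph = nx.Graph()
    graph.add_nodes_from(range(len(greens)))
    left, right = tree.query([p.geometry for p in greens], predicate="intersects")
    for i, j in zip(left.tolist(), right.tolist()):
        if i < j:
            graph.add_edge(i, j)
    patches: list[UGSPatch] = []
    components = sorted(nx.connected_components(graph), key=lambda c: min(greens[i].id for i in c))
    for k, comp in enumerate(components):
        members = sorted(comp, key=lambda i: greens[i].id)
        geometry = unary_union([greens[i].geometry for i in members])
        patches.append(
            UGSPatch(
                id=f"U{k:04d}",
                component_ids=tuple(greens[i].id for i in members),
                geometry=geometry,
            )
        )
    return patches


def _component_admissible(component: BiotopePolygon, crit: LabelCriteria) -> bool:
    by_type = component.biotope_type in crit.biotopes
    if crit.nature_reserve == "required":
        return component.nature_reserve and (not crit.biotopes or by_type)
    if crit.nature_reserve == "admitted":
        return by_type or component.nature_reserve
    return by_type


def _slope_ok(
    component: BiotopePolygon, crit: LabelCriteria, slope_area_fraction: float
) -> bool:
    if crit.min_slope_deg is None:
        return True
    samples = component.slope_samples
    if not samples:
        return False
    steep = sum(1 for s in samples if s > crit.min_slope_deg)
    return steep / len(samples) >= slope_area_fraction


def classify_patch(
    patch: UGSPatch,
    components: Sequence[BiotopePolygon],
    matrix: CriteriaMatrix | None = None,
    slope_area_fraction: float = DEFAULT_SLOPE_AREA_FRACTION,
) -> dict[RNQ, LabelQualification]:
    """Assign quality labels to one patch from its component polygons."""
    if matrix is None:
        matrix = CriteriaMatrix.default()
    labels: dict[RNQ, LabelQualification] = {}
    for label, crit in matrix.labels.items():
        if crit.min_size_ha is not None and not patch.area_ha > crit.min_size_ha:
            continue
        qualifying = [
            c
            for c in components
            if _component_admissible(c, crit)
            and evaluate_noise(c.noise, crit.noise_level, matrix.thresholds)
            and _slope_ok(c, crit, slope_area_fraction)
        ]
        if not qualifying:
            continue
        geometry = unary_union([c.geometry for c in qualifying])
        labels[label] = LabelQualification(
            area_ha=geometry.area / 10_000.0,
            geometry=geometry,
            component_ids=tuple(c.id for c in qualifying),
        )
    return labels


def classify_rnq(
    polygons: Sequence[BiotopePolygon],
    matrix: CriteriaMatrix | None = None,
    slope_area_fraction: float = DEFAULT_SLOPE_AREA_FRACTION,
) -> RNQResult:
    """Dissolve a biotope layer and classify every resulting patch."""
    if matrix is None:
        matrix = CriteriaMatrix.default()
    patches = dissolve_ugs(polygons)
    by_id = {p.id: p for p in polygons}
    result = RNQResult(patches=[], matrix=matrix)
    for patch in patches:
        components = tuple(by_id[cid] for cid in patch.component_ids)
        labels = classify_patch(patch, components, matrix, slope_area_fraction)
        result.patches.append(
            PatchClassification(patch=patch, components=components, labels=labels)
        )
    return result


def rnq_area_table(result: RNQResult) -> pd.DataFrame:
    """Per-label total qualifying area (ha) and share of overall green-space area.

    Labels overlap spatially, so the shares deliberately do not sum to 100%.
    """
    total = result.total_area_ha
    if total <= 0:
        raise UndefinedShareError("total green-space area is zero; shares undefined")
    rows = []
    for label in RNQ:
        area = sum(
            pc.labels[label].area_ha for pc in result.patches if label in pc.labels
        )
        rows.append(
            {
                "rnq": label.value,
                "area_ha": round(area, 1),
                "share_pct": round(100.0 * area / total, 1),
            }
        )
    return pd.DataFrame(rows)
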