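"""Recreation opportunity spectrum: cross quality labels with age-group demand
into 27 (quality × group) types and bundle them into nine (class × group)
combinations.

The high class collects Serene, Spacious and Wild (the qualities with evidence
of stress-relief benefit), the medium class the three Soughing variants (same
criteria at the higher noise caps), and the low class the remaining qualities
(Lush, Culture, Common).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from shapely.ops import unary_union

from .demand import DemandResult
from .rnq import RNQResult
from .types import (
    AgeGroup,
    ConfigurationError,
    InputError,
    ROSClass,
    RNQ,
    UndefinedShareError,
)


def default_bundling() -> dict[RNQ, ROSClass]:
    """The standard nine-quality → three-class reduction."""
    return {
        RNQ.SERENE: ROSClass.HIGH,
        RNQ.SPACIOUS: ROSClass.HIGH,
        RNQ.WILD: ROSClass.HIGH,
        RNQ.SOUGHING_OPENNESS: ROSClass.MEDIUM,
        RNQ.SOUGHING_WILD: ROSClass.MEDIUM,
        RNQ.SOUGHING_OTHERS: ROSClass.MEDIUM,
        RNQ.LUSH: ROSClass.LOW,
        RNQ.CULTURE: ROSClass.LOW,
        RNQ.COMMON: ROSClass.LOW,
    }


def ros_type_universe() -> list[tuple[RNQ, AgeGroup]]:
    """All possible (quality, group) recreation-opportunity types."""
    return [(label, group) for label in RNQ for group in AgeGroup]


@dataclass
class ROSRecord:
    """Positive-area intersection of one quality label with one group's demand."""

    ugs_id: str
    group: AgeGroup
    rnq: RNQ
    area_ha: float
    geometry: object
    ros_class: ROSClass | None = None


def build_ros_types(
    rnq_result: RNQResult, demand_result: DemandResult
) -> list[ROSRecord]:
    """One record per (patch, group, quality) with positive intersection area."""
    rnq_ids = {pc.patch.id for pc in rnq_result.patches}
    for group, qualified in demand_result.suitable.items():
        stray = set(qualified) - rnq_ids
        if stray:
            raise InputError(
                f"demand result for {group.value} references unknown patches: "
                f"{sorted(stray)}"
            )
    records: list[ROSRecord] = []
    for pc in rnq_result.patches:
        for group in AgeGroup:
            qual = demand_result.suitable[group].get(pc.patch.id)
            if qual is None:
                continue
            for label, lq in pc.labels.items():
                geom = lq.geometry.intersection(qual.geometry)
                if geom.is_empty or geom.area <= 0:
                    continue
                records.append(
                    ROSRecord(
                        ugs_id=pc.patch.id,
                        group=group,
                        rnq=label,
                        area_ha=geom.area / 10_000.0,
                        geometry=geom,
                    )
                )
    return records


def bundle_classes(
    records: Sequence[ROSRecord],
    bundling: Mapping[RNQ, ROSClass] | None = None,
) -> pd.DataFrame:
    """Tag records with their class and return per-(group, class) unioned areas.

    Within one patch the member qualities of a class may cover the same ground;
    the class area is the area of the union of their qualifying regions, so
    nothing is double counted.
    """
    if bundling is None:
        bundling = default_bundling()
    missing = [label for label in RNQ if label not in bundling]
    if missing:
        raise ConfigurationError(
            f"bundling map is not total; missing {[m.value for m in missing]}"
        )
    for record in records:
        record.ros_class = bundling[record.rnq]
    rows = []
    for group in AgeGroup:
        for ros_class in (ROSClass.LOW, ROSClass.MEDIUM, ROSClass.HIGH):
            members = [
                r for r in records if r.group is group and r.ros_class is ros_class
            ]
            area = 0.0
            by_patch: dict[str, list[ROSRecord]] = {}
            for r in members:
                by_patch.setdefault(r.ugs_id, []).append(r)
            for patch_records in by_patch.values():
                area += unary_union([r.geometry for r in patch_records]).area
            rows.append(
                {
                    "group": group.value,
                    "ros_class": ros_class.value,
                    "area_ha": area / 10_000.0,
                    "n_patches": len(by_patch),
                }
            )
    return pd.DataFrame(rows)


def class_membership(
    records: Sequence[ROSRecord],
) -> dict[tuple[AgeGroup, ROSClass], set[str]]:
    """Patch ids contributing positive area to each (group, class) combination."""
    membership: dict[tuple[AgeGroup, ROSClass], set[str]] = {
        (g, c): set() for g in AgeGroup for c in ROSClass
    }
    for record in records:
        if record.ros_class is None:
            raise InputError("records must be bundled before membership is derived")
        membership[(record.group, record.ros_class)].add(record.ugs_id)
    return membership


def ros_area_matrix(
    records: Sequence[ROSRecord],
    total_ugs_area_ha: float,
    group_totals: Mapping[AgeGroup, float] | None = None,
) -> pd.DataFrame:
    """Quality × group area matrix with shares of overall green-space area.

    Rows are the nine qualities plus a per-group total-suitable-area row; cells
    hold hectares and shares at 0.1 precision. Because qualities overlap
    spatially, cells must not be summed across rows.
    """
    if total_ugs_area_ha <= 0:
        raise UndefinedShareError("total green-space area is zero; shares undefined")
    area: dict[tuple[RNQ, AgeGroup], float] = {
        (label, group): 0.0 for label in RNQ for group in AgeGroup
    }
    for record in records:
        area[(record.rnq, record.group)] += record.area_ha
    rows = []
    if group_totals is not None:
        row: dict[str, object] = {"row": "total_suitable"}
        for group in AgeGroup:
            total = group_totals.get(group, 0.0)
            row[f"{group.value}_area_ha"] = round(total, 1)
            row[f"{group.value}_share_pct"] = round(
                100.0 * total / total_ugs_area_ha, 1
            )
        rows.append(row)
    for label in RNQ:
        row = {"row": label.value}
        for group in AgeGroup:
            a = area[(label, group)]
            row[f"{group.value}_area_ha"] = round(a, 1)
            row[f"{group.value}_share_pct"] = round(100.0 * a / total_ugs_area_ha, 1)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["remark"] = (
        "Qualities overlap spatially; cells must not be summed across rows."
    )
    return df
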