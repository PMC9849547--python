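"""End-to-end orchestration: synthetic city → quality classification →
age-group demand → opportunity spectrum → network access, with reproducible
file outputs and run metadata."""
from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import io
from .access import (
    DEFAULT_CATCHMENT_WIDTH_M,
    build_network,
    compute_access,
    service_population,
)
from .criteria import CriteriaMatrix
from .demand import default_demand_criteria, demand_filter, demand_summary
from .rnq import DEFAULT_SLOPE_AREA_FRACTION, classify_rnq, rnq_area_table
from .ros import (
    build_ros_types,
    bundle_classes,
    class_membership,
    default_bundling,
    ros_area_matrix,
)
from .synthetic_city import CityConfig, CityDataset, generate_city
from .types import AgeGroup, ConfigurationError, ROSClass

logger = logging.getLogger("urbanros")


@dataclass
class PipelineConfig:
    """What to run and where to write it."""

    city: CityConfig | None = None
    layers_dir: str | Path | None = None  # pre-existing city layers, alternative to `city`
    criteria_path: str | Path | None = None
    catchment_width_m: float = DEFAULT_CATCHMENT_WIDTH_M
    slope_area_fraction: float = DEFAULT_SLOPE_AREA_FRACTION
    out_dir: str | Path = "urbanros_out"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.city is None and self.layers_dir is None:
            raise ConfigurationError(
                "pipeline needs either a synthetic city config or a layers directory"
            )
        if self.seed is not None and self.city is not None:
            self.city = CityConfig(**{**self.city.__dict__, "seed": int(self.seed)})


@dataclass
class ReportBundle:
    """All tables of one pipeline run plus reproducibility metadata."""

    rnq_table: pd.DataFrame
    demand_table: pd.DataFrame
    ros_matrix: pd.DataFrame
    class_areas: pd.DataFrame
    access_city: pd.DataFrame
    access_district: pd.DataFrame
    access_blocks: pd.DataFrame
    metadata: dict


def _config_hash(config: PipelineConfig) -> str:
    def canon(value):
        if isinstance(value, Path):
            return str(value)
        if hasattr(value, "__dict__"):
            return {k: canon(v) for k, v in sorted(value.__dict__.items())}
        if isinstance(value, (list, tuple)):
            return [canon(v) for v in value]
        if isinstance(value, dict):
            return {k: canon(v) for k, v in sorted(value.items())}
        return value

    payload = canon(config)
    payload.pop("out_dir", None)  # where results land must not change their identity
    blob = yaml.safe_dump(payload, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage, write all artifacts under `config.out_dir`."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        logger.info("stage %s starting", name)
        timings[name] = time.perf_counter()

    def done(name, count):
        timings[name] = time.perf_counter() - timings[name]
        logger.info("stage %s done: %d records in %.2f s", name, count, timings[name])

    stage("city")
    if config.city is not None:
        dataset = generate_city(config.city)
        io.write_city(dataset, out / "city")
    else:
        dataset = io.read_city(config.layers_dir)
    done("city", len(dataset.biotopes))

    matrix = (
        CriteriaMatrix.from_yaml(config.criteria_path)
        if config.criteria_path
        else CriteriaMatrix.default()
    )

    stage("rnq")
    rnq_result = classify_rnq(dataset.biotopes, matrix, config.slope_area_fraction)
    rnq_table = rnq_area_table(rnq_result)
    rnq_table.to_csv(out / "rnq_area_table.csv", index=False)
    done("rnq", len(rnq_result.patches))

    stage("demand")
    demand_result = demand_filter(rnq_result, dataset.features)
    populations = dataset.populations() if dataset.blocks else {g: 0 for g in AgeGroup}
    demand_table = demand_summary(demand_result, rnq_result.total_area_ha, populations)
    demand_table.to_csv(out / "demand_summary.csv", index=False)
    done("demand", sum(len(v) for v in demand_result.suitable.values()))

    stage("ros")
    records = build_ros_types(rnq_result, demand_result)
    class_areas = bundle_classes(records)
    group_totals = {g: demand_result.area_ha(g) for g in AgeGroup}
    matrix_df = ros_area_matrix(records, rnq_result.total_area_ha, group_totals)
    matrix_df.to_csv(out / "ros_matrix.csv", index=False)
    class_areas.to_csv(out / "ros_class_areas.csv", index=False)
    done("ros", len(records))

    stage("access")
    if dataset.blocks:
        graph = build_network(dataset.road_edges, dataset.road_nodes)
        membership = class_membership(records)
        geometries = {pc.patch.id: pc.patch.geometry for pc in rnq_result.patches}
        walking = {g: demand_result.criteria[g].walking_distance_m for g in AgeGroup}
        computation = compute_access(
            dataset.blocks,
            graph,
            geometries,
            membership,
            walking,
            config.catchment_width_m,
        )
        access_blocks = computation.table
        city_rows, district_rows = [], []
        for group in AgeGroup:
            for ros_class in ROSClass:
                for mode in ("exact", "at_least"):
                    share, districts = service_population(
                        access_blocks, group, ros_class, mode
                    )
                    city_rows.append(
                        {
                            "group": group.value,
                            "ros_class": ros_class.value,
                            "mode": mode,
                            "share_pct": round(share, 1),
                        }
                    )
                    districts.insert(0, "group", group.value)
                    districts.insert(1, "ros_class", ros_class.value)
                    districts.insert(2, "mode", mode)
                    district_rows.append(districts)
        access_city = pd.DataFrame(city_rows)
        access_district = pd.concat(district_rows, ignore_index=True)
        access_blocks.to_csv(out / "access_blocks.csv", index=False)
        access_city.to_csv(out / "access_city.csv", index=False)
        access_district.to_csv(out / "access_districts.csv", index=False)
        done("access", len(access_blocks))
    else:
        logger.warning("no building blocks in dataset; access stage skipped")
        access_blocks = pd.DataFrame()
        access_city = pd.DataFrame()
        access_district = pd.DataFrame()
        done("access", 0)

    from . import __version__

    metadata = {
        "config_hash": _config_hash(config),
        "seed": dataset.config.seed if config.city is not None else None,
        "version": __version__,
        "n_patches": len(rnq_result.patches),
        "total_ugs_area_ha": round(rnq_result.total_area_ha, 3),
        "stages": sorted(timings),
    }
    (out / "metadata.yaml").write_text(yaml.safe_dump(metadata, sort_keys=True))

    return ReportBundle(
        rnq_table=rnq_table,
        demand_table=demand_table,
        ros_matrix=matrix_df,
        class_areas=class_areas,
        access_city=access_city,
        access_district=access_district,
        access_blocks=access_blocks,
        metadata=metadata,
    )
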