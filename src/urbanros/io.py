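"""Reading and writing the pipeline's layers and tables.

Vector layers travel as GeoJSON FeatureCollections (plain JSON, full float
precision so round trips are exact well below the 1e-6 m tolerance), the road
network as GeoJSON LineStrings carrying `from`/`to`/`length_m`/`motorway`
properties, tabular outputs as CSV with a header row, and configurations as
YAML. Schema violations are reported with the offending property and feature
index.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .synthetic_city import CityConfig, CityDataset, NoiseSource
from .types import (
    NOISE_SOURCES,
    AgeGroup,
    BiotopePolygon,
    BiotopeType,
    BuildingBlock,
    Feature,
    FeatureLayer,
    InputError,
    NoiseProfile,
    RoadEdge,
)


def _feature_collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def _dump_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, separators=(",", ":")) + "\n")


def _load_features(path: Path) -> list[dict]:
    with open(path, "r", encoding="utf-8") as fh:
        collection = json.load(fh)
    if collection.get("type") != "FeatureCollection":
        raise InputError(f"{path} is not a GeoJSON FeatureCollection")
    return collection.get("features", [])


def _require(props: dict, key: str, index: int, path: Path):
    if key not in props:
        raise InputError(f"feature {index} in {path.name} missing property {key!r}")
    return props[key]


# -- biotopes ---------------------------------------------------------------


def write_biotopes(biotopes: Sequence[BiotopePolygon], path: str | Path) -> None:
    features = []
    for poly in biotopes:
        props = {
            "id": poly.id,
            "biotope_type": poly.biotope_type.value,
            "nature_reserve": poly.nature_reserve,
            "slope_samples": list(poly.slope_samples),
        }
        for source in NOISE_SOURCES:
            props[f"noise_{source}"] = getattr(poly.noise, source)
        features.append(
            {"type": "Feature", "geometry": mapping(poly.geometry), "properties": props}
        )
    _dump_json(_feature_collection(features), Path(path))


def read_biotopes(path: str | Path) -> list[BiotopePolygon]:
    path = Path(path)
    biotopes = []
    for i, feat in enumerate(_load_features(path)):
        props = feat.get("properties", {})
        btype = _require(props, "biotope_type", i, path)
        try:
            biotope_type = BiotopeType(btype)
        except ValueError as exc:
            raise InputError(
                f"feature {i} in {path.name} has unknown biotope_type {btype!r}"
            ) from exc
        noise = NoiseProfile(
            **{s: float(_require(props, f"noise_{s}", i, path)) for s in NOISE_SOURCES}
        )
        biotopes.append(
            BiotopePolygon(
                id=str(_require(props, "id", i, path)),
                geometry=shape(feat["geometry"]),
                biotope_type=biotope_type,
                nature_reserve=bool(props.get("nature_reserve", False)),
                noise=noise,
                slope_samples=tuple(float(s) for s in props.get("slope_samples", [])),
            )
        )
    return biotopes


# -- recreation features ----------------------------------------------------


def write_features(layer: FeatureLayer, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(f.geometry),
            "properties": {"id": f.id, "feature_type": f.feature_type.value},
        }
        for f in layer
    ]
    _dump_json(_feature_collection(features), Path(path))


def read_features(path: str | Path) -> FeatureLayer:
    path = Path(path)
    out = []
    for i, feat in enumerate(_load_features(path)):
        props = feat.get("properties", {})
        out.append(
            Feature(
                id=str(_require(props, "id", i, path)),
                geometry=shape(feat["geometry"]),
                feature_type=_require(props, "feature_type", i, path),
            )
        )
    return FeatureLayer(out)


# -- building blocks ---------------------------------------------------------


def write_blocks(blocks: Sequence[BuildingBlock], path: str | Path) -> None:
    features = []
    for block in blocks:
        props = {"id": block.id, "district_id": block.district_id}
        for group in AgeGroup:
            props[f"pop_{group.value}"] = int(block.population.get(group, 0))
        features.append(
            {"type": "Feature", "geometry": mapping(block.geometry), "properties": props}
        )
    _dump_json(_feature_collection(features), Path(path))


def read_blocks(path: str | Path) -> list[BuildingBlock]:
    path = Path(path)
    blocks = []
    for i, feat in enumerate(_load_features(path)):
        props = feat.get("properties", {})
        blocks.append(
            BuildingBlock(
                id=str(_require(props, "id", i, path)),
                geometry=shape(feat["geometry"]),
                population={
                    group: int(_require(props, f"pop_{group.value}", i, path))
                    for group in AgeGroup
                },
                district_id=str(props.get("district_id", "D0")),
            )
        )
    return blocks


# -- road network -------------------------------------------------------------


def write_roads(
    nodes: dict[str, tuple[float, float]],
    edges: Sequence[RoadEdge],
    path: str | Path,
) -> None:
    features = []
    for edge in edges:
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [list(nodes[edge.u]), list(nodes[edge.v])],
                },
                "properties": {
                    "from": edge.u,
                    "to": edge.v,
                    "length_m": edge.length_m,
                    "motorway": edge.motorway,
                    "walkable": edge.walkable,
                },
            }
        )
    _dump_json(_feature_collection(features), Path(path))


def read_roads(path: str | Path) -> tuple[dict[str, tuple[float, float]], list[RoadEdge]]:
    path = Path(path)
    nodes: dict[str, tuple[float, float]] = {}
    edges: list[RoadEdge] = []
    for i, feat in enumerate(_load_features(path)):
        props = feat.get("properties", {})
        u = str(_require(props, "from", i, path))
        v = str(_require(props, "to", i, path))
        length = float(_require(props, "length_m", i, path))
        if length < 0:
            raise InputError(f"feature {i} in {path.name} has negative length_m")
        coords = feat["geometry"]["coordinates"]
        nodes.setdefault(u, (float(coords[0][0]), float(coords[0][1])))
        nodes.setdefault(v, (float(coords[-1][0]), float(coords[-1][1])))
        edges.append(
            RoadEdge(
                u=u,
                v=v,
                length_m=length,
                motorway=bool(props.get("motorway", False)),
                walkable=bool(props.get("walkable", True)),
            )
        )
    return nodes, edges


def read_edge_csv(path: str | Path) -> list[RoadEdge]:
    """Read a `from,to,length_m,motorway[,walkable]` CSV edge list."""
    df = pd.read_csv(path)
    for col in ("from", "to", "length_m", "motorway"):
        if col not in df.columns:
            raise InputError(f"edge list {Path(path).name} missing column {col!r}")
    if (df["length_m"] < 0).any():
        bad = int(df.index[df["length_m"] < 0][0])
        raise InputError(f"edge list row {bad} has negative length_m")
    return [
        RoadEdge(
            u=str(row["from"]),
            v=str(row["to"]),
            length_m=float(row["length_m"]),
            motorway=bool(row["motorway"]),
            walkable=bool(row.get("walkable", True)),
        )
        for _, row in df.iterrows()
    ]


# -- whole city round trip -----------------------------------------------------


def write_city(dataset: CityDataset, outdir: str | Path) -> dict[str, Path]:
    """Write all layers of a city into a directory; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "biotopes": outdir / "biotopes.geojson",
        "features": outdir / "features.geojson",
        "blocks": outdir / "blocks.geojson",
        "roads": outdir / "roads.geojson",
        "config": outdir / "city_config.yaml",
    }
    write_biotopes(dataset.biotopes, paths["biotopes"])
    write_features(dataset.features, paths["features"])
    write_blocks(dataset.blocks, paths["blocks"])
    write_roads(dataset.road_nodes, dataset.road_edges, paths["roads"])
    write_config(dataset.config, paths["config"])
    return paths


def read_city(indir: str | Path) -> CityDataset:
    indir = Path(indir)
    nodes, edges = read_roads(indir / "roads.geojson")
    config_path = indir / "city_config.yaml"
    config = read_config(config_path) if config_path.exists() else CityConfig()
    return CityDataset(
        config=config,
        biotopes=read_biotopes(indir / "biotopes.geojson"),
        features=read_features(indir / "features.geojson"),
        blocks=read_blocks(indir / "blocks.geojson"),
        road_nodes=nodes,
        road_edges=edges,
        noise_sources=[],
    )


# -- config -----------------------------------------------------------------


def write_config(config: CityConfig, path: str | Path) -> None:
    raw = {
        "extent_m": config.extent_m,
        "n_blocks": config.n_blocks,
        "age_fractions": list(config.age_fractions),
        "total_population": config.total_population,
        "patch_size_mix": [list(p) for p in config.patch_size_mix],
        "noise_source_spec": [list(s) for s in config.noise_source_spec],
        "motorway_fraction": config.motorway_fraction,
        "seed": config.seed,
    }
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


def read_config(path: str | Path) -> CityConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return CityConfig(
        extent_m=float(raw["extent_m"]),
        n_blocks=int(raw["n_blocks"]),
        age_fractions=tuple(raw["age_fractions"]),
        total_population=int(raw.get("total_population", 20_000)),
        patch_size_mix=tuple((float(a), int(c)) for a, c in raw["patch_size_mix"]),
        noise_source_spec=tuple(
            (str(k), float(e), float(d), float(x)) for k, e, d, x in raw["noise_source_spec"]
        ),
        motorway_fraction=float(raw.get("motorway_fraction", 0.05)),
        seed=int(raw.get("seed", 0)),
    )
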