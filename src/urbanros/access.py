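"""Walking-network service areas and population coverage shares.

The street graph is undirected with metric edge lengths; motorway and
non-walkable edges are removed before any distance is computed. Green-space
catchments (outward buffers approximating two-lane street widths) define
access points: graph nodes inside a catchment plus nodes inserted where an
edge crosses the catchment boundary. Each building block is anchored by
projecting its centroid onto the nearest walkable edge; the straight-line
projection offset is added to every network distance from that block.

The no-U-turn requirement is honoured trivially: with nonnegative edge
lengths, shortest paths on an undirected simple graph never immediately
backtrack, so no turn-expanded graph is needed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from shapely.geometry import LineString, Point, Polygon
from shapely.geometry.base import BaseGeometry

from .types import (
    AgeGroup,
    BuildingBlock,
    InputError,
    ROSClass,
    RoadEdge,
    UGSPatch,
    group_walking_distances,
)

#: Default catchment buffer width in metres (a typical two-lane carriageway).
DEFAULT_CATCHMENT_WIDTH_M = 7.5

#: District coverage-share bins (percent, 0.1 precision partition).
SHARE_BINS = (
    "0.0-20.0",
    "20.1-40.0",
    "40.1-60.0",
    "60.1-80.0",
    "80.1-100.0",
)


def share_bin(share_pct: float) -> str:
    """Bin a coverage share (percent) into the five standard district classes."""
    if not 0 <= share_pct <= 100:
        raise InputError(f"share {share_pct} outside [0, 100]")
    r = round(share_pct, 1)
    for i, upper in enumerate((20.0, 40.0, 60.0, 80.0)):
        if r <= upper:
            return SHARE_BINS[i]
    return SHARE_BINS[4]


def build_network(
    edges: Sequence[RoadEdge],
    nodes: Mapping[str, tuple[float, float]],
) -> nx.Graph:
    """Build the walkable graph: drop motorways and non-walkable edges,
    deduplicate parallel edges keeping the shortest, reject bad lengths."""
    graph = nx.Graph()
    for node_id, pos in nodes.items():
        graph.add_node(node_id, pos=(float(pos[0]), float(pos[1])))
    for edge in edges:
        if edge.length_m < 0:
            raise InputError(
                f"edge {edge.u}-{edge.v} has negative length {edge.length_m}"
            )
        if edge.motorway or not edge.walkable:
            continue
        if edge.u not in nodes or edge.v not in nodes:
            raise InputError(f"edge {edge.u}-{edge.v} references unknown node")
        if edge.u == edge.v:
            continue
        (x1, y1), (x2, y2) = nodes[edge.u], nodes[edge.v]
        euclid = math.hypot(x2 - x1, y2 - y1)
        if edge.length_m < euclid - 1e-6:
            raise InputError(
                f"edge {edge.u}-{edge.v} length {edge.length_m:.3f} m is shorter "
                f"than the straight-line node distance {euclid:.3f} m"
            )
        if graph.has_edge(edge.u, edge.v):
            graph[edge.u][edge.v]["length"] = min(
                graph[edge.u][edge.v]["length"], edge.length_m
            )
        else:
            graph.add_edge(edge.u, edge.v, length=float(edge.length_m))
    return graph


def catchment(patch: UGSPatch | BaseGeometry, width_m: float = DEFAULT_CATCHMENT_WIDTH_M):
    """Outward buffer of a dissolved patch; width 0 returns the geometry itself."""
    if width_m < 0:
        raise InputError("catchment width must be nonnegative")
    geometry = patch.geometry if isinstance(patch, UGSPatch) else patch
    if width_m == 0:
        return geometry
    return geometry.buffer(width_m)


@dataclass
class AccessGraph:
    """Walkable graph augmented with catchment-crossing and block-anchor nodes."""

    graph: nx.Graph
    access_nodes: dict[str, frozenset]  # ugs id -> node ids covered by its catchment
    anchors: dict[str, tuple[str, float]]  # block id -> (node id, offset m)


def _edge_chain_points(
    seg: LineString, boundary
) -> list[float]:
    """Normalised positions (0..1) where a segment crosses a polygon boundary."""
    inter = seg.intersection(boundary)
    if inter.is_empty:
        return []
    points: list[Point] = []
    if inter.geom_type == "Point":
        points = [inter]
    elif inter.geom_type == "MultiPoint":
        points = list(inter.geoms)
    else:  # collinear overlap: take the overlap's endpoints
        geoms = getattr(inter, "geoms", [inter])
        for g in geoms:
            if g.geom_type == "Point":
                points.append(g)
            else:
                coords = list(g.coords)
                points.extend([Point(coords[0]), Point(coords[-1])])
    ts = []
    for p in points:
        t = seg.project(p, normalized=True)
        if 1e-9 < t < 1 - 1e-9:
            ts.append(float(t))
    return ts


def build_access_graph(
    graph: nx.Graph,
    catchments: Mapping[str, BaseGeometry],
    blocks: Sequence[BuildingBlock] = (),
) -> AccessGraph:
    """Insert catchment-boundary crossings and block anchors as graph nodes.

    Edge splits preserve declared lengths (sub-lengths are proportional to the
    straight-line parameter), so detoured edges keep their full metric length.
    """
    pos = nx.get_node_attributes(graph, "pos")
    # collect split points per edge
    splits: dict[tuple[str, str], list[tuple[float, str, tuple[float, float]]]] = {}
    edge_segs: dict[tuple[str, str], LineString] = {}
    for u, v in graph.edges():
        key = (u, v) if u <= v else (v, u)
        edge_segs[key] = LineString([pos[key[0]], pos[key[1]]])

    for ugs_id, poly in catchments.items():
        boundary = poly.boundary
        for key, seg in edge_segs.items():
            if not seg.intersects(poly):
                continue
            for t in _edge_chain_points(seg, boundary):
                node_id = f"x|{key[0]}|{key[1]}|{t:.9f}"
                p = seg.interpolate(t, normalized=True)
                splits.setdefault(key, []).append((t, node_id, (p.x, p.y)))

    anchors: dict[str, tuple[str, float]] = {}
    for block in blocks:
        centroid = block.centroid
        best: tuple[float, tuple[str, str], float] | None = None
        for key, seg in edge_segs.items():
            d = seg.distance(centroid)
            if best is None or d < best[0]:
                t = float(seg.project(centroid, normalized=True))
                best = (d, key, t)
        if best is None:
            continue  # empty graph: block stays unanchored (unreachable)
        d, key, t = best
        node_id = f"a|{block.id}"
        p = edge_segs[key].interpolate(t, normalized=True)
        if t <= 1e-9:
            anchors[block.id] = (key[0], d)
        elif t >= 1 - 1e-9:
            anchors[block.id] = (key[1], d)
        else:
            splits.setdefault(key, []).append((t, node_id, (p.x, p.y)))
            anchors[block.id] = (node_id, d)

    # rebuild edges with their split chains
    augmented = nx.Graph()
    for node, p in pos.items():
        augmented.add_node(node, pos=p)
    for key, seg in edge_segs.items():
        u, v = key
        length = graph[u][v]["length"]
        chain = sorted(splits.get(key, []))
        prev_node, prev_t = u, 0.0
        for t, node_id, p in chain:
            if not augmented.has_node(node_id):
                augmented.add_node(node_id, pos=p)
            augmented.add_edge(prev_node, node_id, length=length * (t - prev_t))
            prev_node, prev_t = node_id, t
        augmented.add_edge(prev_node, v, length=length * (1.0 - prev_t))

    all_pos = nx.get_node_attributes(augmented, "pos")
    access_nodes = {
        ugs_id: frozenset(
            n for n, p in all_pos.items() if poly.covers(Point(p))
        )
        for ugs_id, poly in catchments.items()
    }
    return AccessGraph(graph=augmented, access_nodes=access_nodes, anchors=anchors)


def shortest_access_distance(
    access: AccessGraph,
    block_id: str,
    ugs_ids: Iterable[str],
) -> float:
    """Offset-corrected network distance from a block to the nearest access
    point of any listed green space; inf when unreachable."""
    if block_id not in access.anchors:
        return math.inf
    anchor, offset = access.anchors[block_id]
    targets: set[str] = set()
    for ugs_id in ugs_ids:
        targets.update(access.access_nodes.get(ugs_id, ()))
    if not targets or anchor not in access.graph:
        return math.inf
    lengths = nx.single_source_dijkstra_path_length(
        access.graph, anchor, weight="length"
    )
    best = min((lengths[t] for t in targets if t in lengths), default=math.inf)
    return offset + best if math.isfinite(best) else math.inf


@dataclass
class AccessComputation:
    """Block-level distances per (group, class), plus the graph used."""

    table: pd.DataFrame  # block_id, district, group, ros_class, mode, distance_m, accessible
    access_graph: AccessGraph


def compute_access(
    blocks: Sequence[BuildingBlock],
    graph: nx.Graph,
    patch_geometries: Mapping[str, BaseGeometry],
    membership: Mapping[tuple[AgeGroup, ROSClass], set],
    walking_distances: Mapping[AgeGroup, float] | None = None,
    catchment_width_m: float = DEFAULT_CATCHMENT_WIDTH_M,
) -> AccessComputation:
    """Distances and accessibility flags for every block, group and class.

    Two readings are emitted per class: ``exact`` (green spaces qualifying for
    exactly that class) and ``at_least`` (that class or better), the cumulative
    reading under which coverage is monotone in class rank.
    """
    if walking_distances is None:
        walking_distances = group_walking_distances()
    qualifying_ids = set()
    for ids in membership.values():
        qualifying_ids.update(ids)
    catchments = {
        pid: catchment(geom, catchment_width_m)
        for pid, geom in patch_geometries.items()
        if pid in qualifying_ids
    }
    access = build_access_graph(graph, catchments, blocks)

    # one single-source run per block, reused across groups/classes
    per_block_lengths: dict[str, dict[str, float]] = {}
    for block in blocks:
        if block.id in access.anchors:
            anchor, _ = access.anchors[block.id]
            per_block_lengths[block.id] = nx.single_source_dijkstra_path_length(
                access.graph, anchor, weight="length"
            )

    classes = (ROSClass.LOW, ROSClass.MEDIUM, ROSClass.HIGH)
    rows = []
    for block in blocks:
        lengths = per_block_lengths.get(block.id)
        offset = access.anchors[block.id][1] if block.id in access.anchors else None
        for group in AgeGroup:
            limit = walking_distances[group]
            for mode in ("exact", "at_least"):
                for ros_class in classes:
                    if mode == "exact":
                        ids = membership.get((group, ros_class), set())
                    else:
                        ids = set()
                        for c in classes:
                            if c.rank >= ros_class.rank:
                                ids |= membership.get((group, c), set())
                    if lengths is None:
                        distance = math.inf
                    else:
                        targets: set[str] = set()
                        for pid in ids:
                            targets.update(access.access_nodes.get(pid, ()))
                        best = min(
                            (lengths[t] for t in targets if t in lengths),
                            default=math.inf,
                        )
                        distance = offset + best if math.isfinite(best) else math.inf
                    rows.append(
                        {
                            "block_id": block.id,
                            "district": block.district_id,
                            "group": group.value,
                            "ros_class": ros_class.value,
                            "mode": mode,
                            "distance_m": distance,
                            "accessible": bool(distance <= limit),
                            "population": block.population.get(group, 0),
                        }
                    )
    return AccessComputation(table=pd.DataFrame(rows), access_graph=access)


def service_population(
    access_table: pd.DataFrame,
    group: AgeGroup,
    ros_class: ROSClass,
    mode: str = "exact",
) -> tuple[float, pd.DataFrame]:
    """Citywide share (%) of the group's population with access, plus binned
    district shares. Returns (nan, empty frame) for a zero-population group."""
    sub = access_table[
        (access_table["group"] == group.value)
        & (access_table["ros_class"] == ros_class.value)
        & (access_table["mode"] == mode)
    ]
    total = int(sub["population"].sum())
    if total == 0:
        return math.nan, pd.DataFrame(columns=["district", "share_pct", "share_bin"])
    city_share = 100.0 * sub.loc[sub["accessible"], "population"].sum() / total
    district_rows = []
    for district, grp in sub.groupby("district", sort=True):
        dpop = int(grp["population"].sum())
        if dpop == 0:
            continue
        share = 100.0 * grp.loc[grp["accessible"], "population"].sum() / dpop
        district_rows.append(
            {
                "district": district,
                "share_pct": round(share, 1),
                "share_bin": share_bin(share),
            }
        )
    return city_share, pd.DataFrame(district_rows)
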