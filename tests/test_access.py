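"""Walking network, catchments, access points and coverage shares."""
from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest
from shapely.geometry import Point, box

from urbanros import (
    AgeGroup,
    BuildingBlock,
    ROSClass,
    RoadEdge,
    UGSPatch,
    build_access_graph,
    build_network,
    catchment,
    compute_access,
    service_population,
    share_bin,
    shortest_access_distance,
)
from urbanros.access import SHARE_BINS
from urbanros.types import InputError


def brute_force_distance(graph: nx.Graph, source: str, targets: set[str]) -> float:
    """Exhaustive simple-path enumeration with branch-and-bound pruning."""
    best = math.inf

    def extend(node: str, length: float, visited: set[str]) -> None:
        nonlocal best
        if length >= best:
            return
        if node in targets:
            best = length
            return
        for nbr in graph[node]:
            if nbr not in visited:
                extend(nbr, length + graph[node][nbr]["length"], visited | {nbr})

    extend(source, 0.0, {source})
    return best


def toy_nodes():
    return {"A": (0.0, 0.0), "B": (3.0, 0.0), "C": (0.0, 4.0)}


class TestBuildNetwork:
    def test_motorway_edges_filtered(self):
        edges = [
            RoadEdge("A", "B", 3.0),
            RoadEdge("B", "C", 5.0),
            RoadEdge("A", "C", 4.0, motorway=True),
        ]
        graph = build_network(edges, toy_nodes())
        assert graph.number_of_edges() == 2

    def test_all_motorway_gives_empty_graph(self):
        edges = [RoadEdge("A", "B", 3.0, motorway=True)]
        graph = build_network(edges, toy_nodes())
        assert graph.number_of_edges() == 0

    def test_parallel_edges_keep_shortest(self):
        edges = [RoadEdge("A", "B", 4.5), RoadEdge("A", "B", 3.2)]
        graph = build_network(edges, toy_nodes())
        assert graph["A"]["B"]["length"] == pytest.approx(3.2)

    def test_negative_length_rejected(self):
        with pytest.raises(InputError):
            build_network([RoadEdge("A", "B", -1.0)], toy_nodes())

    def test_length_below_straight_line_rejected(self):
        with pytest.raises(InputError):
            build_network([RoadEdge("A", "B", 2.0)], toy_nodes())


class TestCatchment:
    def test_zero_width_returns_patch_geometry(self):
        patch = UGSPatch("u", ("a",), box(0, 0, 100, 100))
        assert catchment(patch, 0.0).equals(patch.geometry)

    def test_buffered_square_area_matches_closed_form(self):
        patch = UGSPatch("u", ("a",), box(0, 0, 100, 100))
        expected = math.pi * 100 + 4 * 100 * 10 + 10_000  # πr² + 4·side·r + side²
        assert catchment(patch, 10.0).area == pytest.approx(expected, rel=1e-3)

    def test_catchment_contains_patch(self):
        patch = UGSPatch("u", ("a",), box(0, 0, 100, 100))
        assert catchment(patch, 7.5).covers(patch.geometry)


class TestAccessPoints:
    def test_node_inside_catchment_is_access_node(self):
        graph = build_network([RoadEdge("A", "B", 110.0)], {"A": (50.0, 50.0), "B": (160.0, 50.0)})
        access = build_access_graph(graph, {"u": box(0, 0, 100, 100)})
        assert "A" in access.access_nodes["u"]

    def test_crossing_edge_without_inner_node_gets_inserted_node(self):
        # edge passes through the catchment, both endpoints outside
        graph = build_network(
            [RoadEdge("A", "B", 300.0)], {"A": (-100.0, 50.0), "B": (200.0, 50.0)}
        )
        access = build_access_graph(graph, {"u": box(0, 0, 100, 100)})
        assert access.access_nodes["u"]
        assert all(n not in ("A", "B") for n in access.access_nodes["u"])
        # split preserves total length
        total = sum(d["length"] for _, _, d in access.graph.edges(data=True))
        assert total == pytest.approx(300.0)

    def test_isolated_patch_far_from_edges_has_no_access(self):
        graph = build_network([RoadEdge("A", "B", 100.0)], {"A": (0.0, 0.0), "B": (100.0, 0.0)})
        access = build_access_graph(graph, {"u": box(5000, 5000, 5100, 5100)})
        assert access.access_nodes["u"] == frozenset()


class TestShortestAccess:
    def test_single_edge_distance(self):
        graph = build_network([RoadEdge("A", "B", 100.0)], {"A": (0.0, 0.0), "B": (100.0, 0.0)})
        block = BuildingBlock("bl", Point(0, 0).buffer(1.0), {AgeGroup.MAJORITY: 10})
        access = build_access_graph(graph, {"u": box(99, -1, 101, 1)}, [block])
        d = shortest_access_distance(access, "bl", ["u"])
        assert d == pytest.approx(100.0, abs=1.5)

    def test_triangle_matches_exhaustive_enumeration(self):
        nodes = toy_nodes()
        edges = [RoadEdge("A", "B", 3.0), RoadEdge("B", "C", 5.0), RoadEdge("A", "C", 4.0)]
        graph = build_network(edges, nodes)
        assert brute_force_distance(graph, "A", {"C"}) == pytest.approx(4.0)
        assert brute_force_distance(graph, "B", {"C"}) == pytest.approx(5.0)

    def test_disconnected_components_are_unreachable(self):
        nodes = {"A": (0.0, 0.0), "B": (10.0, 0.0), "C": (1000.0, 0.0), "D": (1010.0, 0.0)}
        graph = build_network([RoadEdge("A", "B", 10.0), RoadEdge("C", "D", 10.0)], nodes)
        block = BuildingBlock("bl", Point(0, 0).buffer(1.0), {AgeGroup.MAJORITY: 10})
        access = build_access_graph(graph, {"u": box(1005, -1, 1015, 1)}, [block])
        assert shortest_access_distance(access, "bl", ["u"]) == math.inf

    def test_random_graphs_match_enumeration_oracle(self):
        """Dijkstra on the augmented graph equals exhaustive path enumeration."""
        rng = np.random.default_rng(123)
        for _ in range(25):
            n = int(rng.integers(5, 30))
            pts = rng.uniform(0, 1000, size=(n, 2))
            nodes = {f"n{i}": (float(x), float(y)) for i, (x, y) in enumerate(pts)}
            edges = []
            for _ in range(int(n * 1.4)):
                i, j = rng.integers(0, n, size=2)
                if i == j:
                    continue
                euclid = math.hypot(*(pts[i] - pts[j]))
                edges.append(
                    RoadEdge(f"n{i}", f"n{j}", euclid * (1 + float(rng.uniform(0, 0.5))))
                )
            graph = build_network(edges, nodes)
            if graph.number_of_edges() == 0:
                continue
            source = f"n{int(rng.integers(0, n))}"
            targets = {f"n{i}" for i in rng.integers(0, n, size=3)} & set(graph.nodes)
            if source not in graph or not targets:
                continue
            lengths = nx.single_source_dijkstra_path_length(graph, source, weight="length")
            dijkstra = min((lengths[t] for t in targets if t in lengths), default=math.inf)
            oracle = brute_force_distance(graph, source, targets)
            assert dijkstra == pytest.approx(oracle) or (
                math.isinf(dijkstra) and math.isinf(oracle)
            )


class TestServicePopulation:
    def _one_patch_city(self, walk_limit_hits: bool):
        nodes = {"A": (0.0, 0.0), "B": (400.0, 0.0), "C": (2000.0, 0.0)}
        edges = [RoadEdge("A", "B", 400.0), RoadEdge("B", "C", 1600.0)]
        graph = build_network(edges, nodes)
        patch_geoms = {"u": box(-20, -20, 20, 20)}
        blocks = [
            BuildingBlock("near", box(390, 10, 410, 30), {g: 50 for g in AgeGroup}),
            BuildingBlock("far", box(1990, 10, 2010, 30), {g: 50 for g in AgeGroup}),
        ]
        membership = {
            (g, c): ({"u"} if c is ROSClass.LOW else set())
            for g in AgeGroup
            for c in ROSClass
        }
        return blocks, graph, patch_geoms, membership

    def test_half_population_accessible_gives_fifty_percent(self):
        blocks, graph, geoms, membership = self._one_patch_city(True)
        comp = compute_access(blocks, graph, geoms, membership)
        share, districts = service_population(comp.table, AgeGroup.CHILDREN, ROSClass.LOW)
        assert share == pytest.approx(50.0)
        assert set(districts["share_bin"]) <= set(SHARE_BINS)

    def test_zero_walking_distance_needs_anchor_on_access_node(self):
        blocks, graph, geoms, membership = self._one_patch_city(True)
        walking = {g: 1e-9 for g in AgeGroup}
        comp = compute_access(blocks, graph, geoms, membership, walking)
        share, _ = service_population(comp.table, AgeGroup.CHILDREN, ROSClass.LOW)
        assert share == pytest.approx(0.0)

    def test_network_distance_at_least_straight_line(self, city):
        from urbanros import classify_rnq, demand_filter, build_ros_types, bundle_classes
        from urbanros.ros import class_membership

        result = classify_rnq(city.biotopes)
        demand = demand_filter(result, city.features)
        records = build_ros_types(result, demand)
        bundle_classes(records)
        membership = class_membership(records)
        graph = build_network(city.road_edges, city.road_nodes)
        geoms = {pc.patch.id: pc.patch.geometry for pc in result.patches}
        comp = compute_access(city.blocks[:15], graph, geoms, membership)
        pos = nx.get_node_attributes(comp.access_graph.graph, "pos")
        blocks = {b.id: b for b in city.blocks[:15]}
        for _, row in comp.table[comp.table["mode"] == "at_least"].iterrows():
            if not math.isfinite(row["distance_m"]):
                continue
            centroid = blocks[row["block_id"]].centroid
            ids = set()
            for (g, c), members in membership.items():
                if g.value == row["group"] and c.rank >= ROSClass(row["ros_class"]).rank:
                    ids |= members
            nearest_access = min(
                (
                    math.hypot(pos[n][0] - centroid.x, pos[n][1] - centroid.y)
                    for pid in ids
                    for n in comp.access_graph.access_nodes.get(pid, ())
                ),
                default=0.0,
            )
            assert row["distance_m"] >= nearest_access - 1e-6

    def test_monotone_in_walking_distance_and_class(self, city):
        from urbanros import classify_rnq, demand_filter, build_ros_types, bundle_classes
        from urbanros.ros import class_membership

        result = classify_rnq(city.biotopes)
        demand = demand_filter(result, city.features)
        records = build_ros_types(result, demand)
        bundle_classes(records)
        membership = class_membership(records)
        graph = build_network(city.road_edges, city.road_nodes)
        geoms = {pc.patch.id: pc.patch.geometry for pc in result.patches}
        short = compute_access(
            city.blocks, graph, geoms, membership, {g: 500.0 for g in AgeGroup}
        )
        longer = compute_access(
            city.blocks, graph, geoms, membership, {g: 835.0 for g in AgeGroup}
        )
        for group in AgeGroup:
            shares = []
            for ros_class in (ROSClass.LOW, ROSClass.MEDIUM, ROSClass.HIGH):
                s_short, _ = service_population(short.table, group, ros_class, "at_least")
                s_long, _ = service_population(longer.table, group, ros_class, "at_least")
                assert s_long >= s_short - 1e-9
                shares.append(s_long)
            assert shares[0] >= shares[1] >= shares[2]

    def test_share_bins_partition_the_range(self):
        assert share_bin(0.0) == "0.0-20.0"
        assert share_bin(20.04) == "0.0-20.0"
        assert share_bin(20.06) == "20.1-40.0"
        assert share_bin(100.0) == "80.1-100.0"
        with pytest.raises(InputError):
            share_bin(101.0)
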