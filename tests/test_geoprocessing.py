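"""Census filter, zones, zonal statistics, and connectivity classification."""

import networkx as nx
import pytest
from shapely.geometry import LineString, Point, box

from limnodb.geoprocessing import (
    GeoprocessingError,
    ZoneGeometry,
    assign_zone_membership,
    build_buffer_zones,
    build_flow_network,
    census_filter,
    classify_connectivity,
    zonal_summary_categorical,
    zonal_summary_continuous,
)
from limnodb.models import ZoneDef


def _wb(pid, area_ha, fclass="natural", perennial=True):
    side = (area_ha * 1e4) ** 0.5
    return {
        "geometry": box(0, 0, side, side),
        "properties": {
            "id": pid, "area_ha": area_ha, "fclass": fclass,
            "perennial": perennial,
        },
    }


class TestCensusFilter:
    def test_four_hectare_threshold_is_boundary_inclusive(self):
        census, excluded = census_filter(
            [_wb("a", 4.0), _wb("b", 3.99), _wb("c", 12.0, "sewage treatment")]
        )
        assert [f["properties"]["id"] for f in census] == ["a"]
        reasons = {f["properties"]["id"]: r for f, r in excluded}
        assert reasons == {"b": "TOO_SMALL", "c": "ARTIFICIAL"}

    def test_non_perennial_bodies_excluded(self):
        _, excluded = census_filter([_wb("d", 10.0, perennial=False)])
        assert excluded[0][1] == "NON_PERENNIAL"

    def test_missing_area_attribute_errors(self):
        wb = {"geometry": box(0, 0, 10, 10), "properties": {"id": "x"}}
        with pytest.raises(GeoprocessingError, match="area"):
            census_filter([wb])

    def test_aquaculture_is_artificial(self):
        _, excluded = census_filter([_wb("e", 30.0, "aquaculture")])
        assert excluded[0][1] == "ARTIFICIAL"


class TestBufferZones:
    def test_ring_excludes_the_lake_itself(self, unit_square):
        zones = build_buffer_zones([(1, unit_square)], [100.0])
        (zg,) = zones
        assert zg.zone.zone_id == "buffer100_1"
        assert zg.zone.zone_type == "buffer" and zg.zone.lake_id == 1
        assert zg.geometry.area > 0
        assert zg.geometry.intersection(unit_square).area == pytest.approx(0.0)

    def test_ring_area_positive_and_monotone_in_distance(self, unit_square):
        zones = build_buffer_zones([(1, unit_square)], [50.0, 100.0, 200.0])
        areas = [zg.geometry.area for zg in zones]
        assert all(a > 0 for a in areas)
        assert areas[0] < areas[1] < areas[2]

    def test_two_distances_give_two_distinct_zone_ids(self, unit_square):
        zones = build_buffer_zones([(1, unit_square)], [100.0, 500.0])
        ids = {zg.zone.zone_id for zg in zones}
        assert ids == {"buffer100_1", "buffer500_1"}

    def test_non_polygonal_geometry_refused(self):
        with pytest.raises(GeoprocessingError, match="polygonal"):
            build_buffer_zones([(1, LineString([(0, 0), (1, 1)]))], [100.0])


class TestZoneMembership:
    def _zones(self):
        return [
            ZoneGeometry(ZoneDef("State_A", "state"), box(0, 0, 1000, 2000)),
            ZoneGeometry(ZoneDef("State_B", "state"), box(1000, 0, 3000, 2000)),
        ]

    def test_lake_wholly_inside_one_zone(self):
        lake = box(100, 100, 400, 400)
        rows = assign_zone_membership([(1, lake)], self._zones())
        assert rows == [(1, "state", "State_A")]

    def test_straddling_lake_assigned_by_largest_intersection(self):
        # 60 % of the lake's area lies east of the boundary at x=1000
        lake = box(800, 0, 1300, 500)
        rows = assign_zone_membership([(1, lake)], self._zones())
        assert rows == [(1, "state", "State_B")]

    def test_empty_zone_set_reports_missing(self):
        rows = assign_zone_membership([(1, box(0, 0, 10, 10))], [])
        assert rows == []
        rows = assign_zone_membership(
            [(1, box(5000, 5000, 5010, 5010))], self._zones()
        )
        assert rows == [(1, "state", None)]


class TestZonalSummaries:
    def test_total_coverage_single_class(self, unit_square):
        lc = [{"geometry": box(-100, -100, 2000, 2000),
               "properties": {"class": "forest"}}]
        props, flag = zonal_summary_categorical(unit_square, lc)
        assert props == {"forest": pytest.approx(1.0)}
        assert flag is None

    def test_half_forest_half_agriculture_is_exact(self, unit_square):
        lc = [
            {"geometry": box(0, 0, 500, 1000), "properties": {"class": "forest"}},
            {"geometry": box(500, 0, 1000, 1000),
             "properties": {"class": "agriculture"}},
        ]
        props, flag = zonal_summary_categorical(unit_square, lc)
        assert props["forest"] == pytest.approx(0.5, abs=1e-9)
        assert props["agriculture"] == pytest.approx(0.5, abs=1e-9)
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-9)

    def test_zone_outside_layer_is_no_data(self, unit_square):
        lc = [{"geometry": box(5000, 5000, 6000, 6000),
               "properties": {"class": "forest"}}]
        props, flag = zonal_summary_categorical(unit_square, lc)
        assert props == {} and flag == "NO_DATA"

    def test_partial_coverage_flagged(self, unit_square):
        lc = [{"geometry": box(0, 0, 500, 1000), "properties": {"class": "forest"}}]
        props, flag = zonal_summary_categorical(unit_square, lc)
        assert flag == "PARTIAL_COVERAGE"
        assert props == {"forest": pytest.approx(1.0)}

    def test_proportions_invariant_to_splitting_class_polygons(self, unit_square, rng):
        whole = [
            {"geometry": box(0, 0, 600, 1000), "properties": {"class": "forest"}},
            {"geometry": box(600, 0, 1000, 1000), "properties": {"class": "urban"}},
        ]
        split = [
            {"geometry": box(0, y, 600, y + 100), "properties": {"class": "forest"}}
            for y in range(0, 1000, 100)
        ] + [
            {"geometry": box(600, 0, 1000, 1000), "properties": {"class": "urban"}}
        ]
        p1, _ = zonal_summary_categorical(unit_square, whole)
        perm = rng.permutation(len(split))
        p2, _ = zonal_summary_categorical(unit_square, [split[i] for i in perm])
        for cls in p1:
            assert p1[cls] == pytest.approx(p2[cls], abs=1e-9)

    def test_zero_area_zone_errors(self):
        with pytest.raises(GeoprocessingError, match="zero-area"):
            zonal_summary_categorical(Point(0, 0).buffer(0), [])

    def test_uniform_value_gives_that_mean(self, unit_square):
        layer = [{"geometry": box(-10, -10, 2000, 2000), "properties": {"v": 7.5}}]
        value, flag = zonal_summary_continuous(unit_square, layer, "v", "mean")
        assert value == pytest.approx(7.5) and flag is None

    def test_half_half_area_weighted_mean(self, unit_square):
        layer = [
            {"geometry": box(0, 0, 500, 1000), "properties": {"v": 2.0}},
            {"geometry": box(500, 0, 1000, 1000), "properties": {"v": 4.0}},
        ]
        value, _ = zonal_summary_continuous(unit_square, layer, "v", "mean")
        assert value == pytest.approx(3.0, abs=1e-9)  # (2*A/2 + 4*A/2)/A
        vmin, _ = zonal_summary_continuous(unit_square, layer, "v", "min")
        assert vmin == 2.0

    def test_zero_intersection_is_no_data(self, unit_square):
        layer = [{"geometry": box(9000, 9000, 9100, 9100), "properties": {"v": 1.0}}]
        value, flag = zonal_summary_continuous(unit_square, layer, "v", "mean")
        assert value is None and flag == "NO_DATA"


def _lake_at(lake_id, cx, cy, side=400.0):
    return (lake_id, box(cx - side / 2, cy - side / 2, cx + side / 2, cy + side / 2))


def _stream(p1, p2):
    return {"geometry": LineString([p1, p2]), "properties": {}}


class TestFlowNetwork:
    def test_no_streams_leaves_isolated_lakes(self):
        net = build_flow_network([], [_lake_at(1, 0, 0), _lake_at(2, 5000, 0)])
        assert classify_connectivity(1, net) == "ISOLATED"
        assert classify_connectivity(2, net) == "ISOLATED"

    def test_single_edge_chain_reachability(self):
        lakes = [_lake_at(1, 0, 0), _lake_at(2, 5000, 0)]
        net = build_flow_network([_stream((0, 0), (5000, 0))], lakes)
        assert classify_connectivity(1, net) == "HEADWATER"
        assert classify_connectivity(2, net) == "DRAINAGE_UPSTREAM_LAKES"
        assert net.upstream_lakes(2) == {1}

    def test_junction_inflow_without_upstream_lake_is_drainage(self):
        lakes = [_lake_at(1, 0, 0)]
        net = build_flow_network([_stream((5000, 5000), (0, 0))], lakes)
        assert classify_connectivity(1, net) == "DRAINAGE"

    def test_two_segment_chain_detects_upstream_lake(self):
        lakes = [_lake_at(1, 0, 0), _lake_at(2, 10000, 0)]
        streams = [
            _stream((0, 0), (5000, 0)),       # lake 1 -> junction
            _stream((5000, 0), (10000, 0)),   # junction -> lake 2
        ]
        net = build_flow_network(streams, lakes)
        assert classify_connectivity(2, net) == "DRAINAGE_UPSTREAM_LAKES"

    def test_five_lake_fixture_matches_hand_enumeration(self):
        # 1 -> 2 -> 3; 4 isolated; junction -> 5
        lakes = [_lake_at(i, 6000 * i, 0) for i in range(1, 6)]
        streams = [
            _stream((6000, 0), (12000, 0)),
            _stream((12000, 0), (18000, 0)),
            _stream((27000, 3000), (30000, 0)),
        ]
        net = build_flow_network(streams, lakes)
        assert net.upstream_lakes(3) == {1, 2}
        assert net.upstream_lakes(2) == {1}
        assert classify_connectivity(4, net) == "ISOLATED"
        assert classify_connectivity(5, net) == "DRAINAGE"

    def test_cycle_is_an_error_naming_the_cycle(self):
        lakes = [_lake_at(1, 0, 0), _lake_at(2, 5000, 0)]
        streams = [_stream((0, 0), (5000, 0)), _stream((5000, 0), (0, 0))]
        with pytest.raises(GeoprocessingError, match="cycle"):
            build_flow_network(streams, lakes)

    def test_unknown_lake_errors(self):
        net = build_flow_network([], [_lake_at(1, 0, 0)])
        with pytest.raises(GeoprocessingError, match="99"):
            classify_connectivity(99, net)

    def test_classification_agrees_with_brute_force_oracle(self, rng):
        """Random 20-node DAGs: classes vs direct reachability enumeration."""
        for trial in range(50):
            n_lakes, n_junctions = 8, 12
            lakes = [
                _lake_at(i + 1, (i % 5) * 6000, (i // 5) * 6000)
                for i in range(n_lakes)
            ]
            net_graph = nx.DiGraph()
            nodes = [f"lake:{i + 1}" for i in range(n_lakes)] + [
                f"J:{j}" for j in range(n_junctions)
            ]
            for i in range(n_lakes):
                net_graph.add_node(f"lake:{i + 1}", lake_id=i + 1)
            for j in range(n_junctions):
                net_graph.add_node(f"J:{j}", lake_id=None)
            # random DAG edges respecting a topological order
            order = list(rng.permutation(len(nodes)))
            rank = {nodes[i]: order[i] for i in range(len(nodes))}
            for _ in range(25):
                a, b = rng.choice(nodes, size=2, replace=False)
                if rank[a] < rank[b]:
                    net_graph.add_edge(a, b)
            from limnodb.geoprocessing import FlowNetwork

            net = FlowNetwork(
                net_graph, {i + 1: f"lake:{i + 1}" for i in range(n_lakes)}
            )
            for lake_id in range(1, n_lakes + 1):
                node = f"lake:{lake_id}"
                indeg = net_graph.in_degree(node)
                outdeg = net_graph.out_degree(node)
                # brute-force transitive closure by BFS over reversed edges
                seen, stack = set(), [node]
                while stack:
                    cur = stack.pop()
                    for pred in net_graph.predecessors(cur):
                        if pred not in seen:
                            seen.add(pred)
                            stack.append(pred)
                upstream_lakes = {
                    net_graph.nodes[x]["lake_id"]
                    for x in seen
                    if net_graph.nodes[x].get("lake_id")
                }
                if indeg == 0 and outdeg == 0:
                    expected = "ISOLATED"
                elif indeg == 0:
                    expected = "HEADWATER"
                elif upstream_lakes:
                    expected = "DRAINAGE_UPSTREAM_LAKES"
                else:
                    expected = "DRAINAGE"
                assert classify_connectivity(lake_id, net) == expected
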