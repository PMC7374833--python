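"""Graph building, travel-time assignment and OD matrices."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString

from mmfca.network import (
    DEFAULT_MODES,
    NetworkError,
    RoadSegment,
    TravelMode,
    assign_travel_times,
    build_network,
    od_matrix,
)

from conftest import oracle_all_pairs


def seg(sid, coords, road_class="major", zone="Ondo City"):
    return RoadSegment(sid, LineString(coords), road_class, zone)


SPEEDS = {"Ondo City": {"highway": 53.00, "major": 38.00, "residential": 29.80},
          "Okitipupa": {"highway": 53.33, "major": 31.00, "residential": 11.35}}


class TestBuild:
    def test_shared_endpoint_joins(self):
        g, rep = build_network([seg("a", [(0, 0), (100, 0)]), seg("b", [(100, 0), (200, 0)])])
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 2
        assert rep.n_components == 1

    def test_tolerance_merges_nearby_endpoints(self):
        g, rep = build_network(
            [seg("a", [(0, 0), (100, 0)]), seg("b", [(100.5, 0), (200, 0)])],
            snap_tolerance=1.0,
        )
        assert g.number_of_nodes() == 3
        assert rep.merged_endpoints == 1

    def test_beyond_tolerance_stays_apart(self):
        g, rep = build_network(
            [seg("a", [(0, 0), (100, 0)]), seg("b", [(102, 0), (200, 0)])],
            snap_tolerance=1.0,
        )
        assert g.number_of_nodes() == 4
        assert rep.n_components == 2

    def test_degenerate_segment_rejected_with_report(self):
        g, rep = build_network([seg("a", [(0, 0), (100, 0)]), seg("z", [(5, 5), (5, 5)])])
        assert rep.rejected_segments == ["z"]
        assert g.number_of_edges() == 1

    def test_duplicate_edge_keeps_shorter(self):
        g, rep = build_network(
            [seg("short", [(0, 0), (100, 0)]), seg("long", [(0, 0), (50, 80), (100, 0)])]
        )
        assert g.number_of_edges() == 1
        assert g.edges[(0.0, 0.0), (100.0, 0.0)]["segment_id"] == "short"
        assert rep.collapsed_duplicates == 1

    def test_empty_input_rejected(self):
        with pytest.raises(NetworkError):
            build_network([])

    def test_component_count_matches_union_find_oracle(self, rng):
        """Random 50-segment scatter: component count equals brute-force
        union-find over snapped endpoints."""
        for _ in range(10):
            pts = rng.uniform(0, 5000, size=(30, 2)).round(0)
            segs = []
            for i in range(50):
                a, b = rng.integers(0, 30, size=2)
                if not np.allclose(pts[a], pts[b]):
                    segs.append(seg(f"s{i}", [tuple(pts[a]), tuple(pts[b])]))
            g, rep = build_network(segs, snap_tolerance=1.0)
            # oracle: union endpoints by coordinate equality (pts are integer-valued)
            parent = {}

            def find(u):
                while parent.setdefault(u, u) != u:
                    u = parent[u]
                return u

            for s in segs:
                c = list(s.geometry.coords)
                u, v = find(tuple(c[0])), find(tuple(c[-1]))
                if u != v:
                    parent[u] = v
            roots = {find(tuple(p)) for s in segs for p in
                     (s.geometry.coords[0], s.geometry.coords[-1])}
            assert rep.n_components == len(roots)


class TestTravelTimes:
    def test_highway_edge_six_minutes(self):
        """5.30 km of highway at the Ondo City mean speed of 53 km/h."""
        g, _ = build_network([seg("a", [(0, 0), (5300, 0)], "highway", "Ondo City")])
        assign_travel_times(g, SPEEDS)
        assert g.edges[(0.0, 0.0), (5300.0, 0.0)]["travel_time_min"] == pytest.approx(6.0)

    def test_residential_edge_six_minutes(self):
        """1.135 km residential at the Okitipupa mean speed of 11.35 km/h."""
        g, _ = build_network([seg("a", [(0, 0), (1135, 0)], "residential", "Okitipupa")])
        assign_travel_times(g, SPEEDS)
        assert g.edges[(0.0, 0.0), (1135.0, 0.0)]["travel_time_min"] == pytest.approx(6.0)

    def test_missing_speed_entry_names_the_pair(self):
        g, _ = build_network([seg("a", [(0, 0), (1000, 0)], "major", "Atlantis")])
        with pytest.raises(NetworkError, match="Atlantis"):
            assign_travel_times(g, SPEEDS)

    def test_default_zone_fallback(self):
        g, _ = build_network([seg("a", [(0, 0), (1000, 0)], "major", "Atlantis")])
        assign_travel_times(g, SPEEDS, default_zone="Ondo City")
        assert g.edges[(0.0, 0.0), (1000.0, 0.0)]["speed_kmh"] == 38.00


def _demand(points):
    return pd.DataFrame(
        {"cell_id": [f"c{i}" for i in range(len(points))],
         "x": [p[0] for p in points], "y": [p[1] for p in points]}
    )


def _facilities(points):
    return pd.DataFrame(
        {"facility_id": [f"f{i}" for i in range(len(points))],
         "x": [p[0] for p in points], "y": [p[1] for p in points],
         "staff": [1] * len(points)}
    )


class TestODMatrix:
    def _grid_graph(self):
        segs = [
            seg("a", [(0, 0), (1000, 0)]),
            seg("b", [(1000, 0), (2000, 0)]),
            seg("c", [(5000, 5000), (6000, 5000)]),  # disconnected island
        ]
        g, _ = build_network(segs)
        return assign_travel_times(g, SPEEDS)

    def test_colocated_demand_and_facility(self):
        g = self._grid_graph()
        od = od_matrix(g, _demand([(0, 0)]), _facilities([(0, 0)]))
        assert od.times["taxi"][0, 0] == 0.0
        assert od.times["minibus"][0, 0] == 15.0

    def test_disconnected_facility_is_unreachable(self):
        g = self._grid_graph()
        od = od_matrix(g, _demand([(0, 0)]), _facilities([(5000, 5000)]))
        assert np.isinf(od.times["taxi"][0, 0])
        assert np.isinf(od.times["minibus"][0, 0])

    def test_unsnappable_point_lists_ids(self):
        g = self._grid_graph()
        with pytest.raises(NetworkError, match="c0"):
            od_matrix(g, _demand([(50_000, 50_000)]), _facilities([(0, 0)]))

    def test_minibus_is_taxi_plus_penalty_on_finite_entries(self):
        g = self._grid_graph()
        od = od_matrix(g, _demand([(0, 0), (2000, 0)]), _facilities([(1000, 0)]))
        t, m = od.times["taxi"], od.times["minibus"]
        finite = np.isfinite(t)
        assert np.allclose(m[finite] - t[finite], 15.0)

    def _random_network(self, rng, n_nodes=20):
        pts = rng.uniform(0, 10_000, size=(n_nodes, 2)).round(1)
        segs = []
        for i in range(n_nodes):  # ring + chords: connected, cyclic
            a, b = pts[i], pts[(i + 1) % n_nodes]
            segs.append(seg(f"r{i}", [tuple(a), tuple(b)]))
        for i in range(n_nodes):
            a, b = rng.integers(0, n_nodes, size=2)
            if not np.allclose(pts[a], pts[b]):
                segs.append(seg(f"x{i}", [tuple(pts[a]), tuple(pts[b])]))
        g, _ = build_network(segs, snap_tolerance=0.0)
        return assign_travel_times(g, SPEEDS), pts

    def test_taxi_times_match_floyd_warshall_oracle(self, rng):
        for _ in range(5):
            g, pts = self._random_network(rng)
            nodes = list(pts[: min(len(pts), 20)])
            od = od_matrix(g, _demand([tuple(p) for p in nodes]),
                           _facilities([tuple(p) for p in nodes[:5]]), snap_tolerance=1.0)
            oracle = oracle_all_pairs(g)
            for i, p in enumerate(nodes):
                for j, q in enumerate(nodes[:5]):
                    got = od.times["taxi"][i, j]
                    want = oracle["dist"][oracle["idx"][tuple(p)], oracle["idx"][tuple(q)]]
                    assert got == pytest.approx(want, abs=1e-9)

    def test_triangle_inequality(self, rng):
        g, pts = self._random_network(rng)
        nodes = [tuple(p) for p in pts]
        od = od_matrix(g, _demand(nodes), _facilities(nodes), snap_tolerance=1.0)
        t = od.times["taxi"]
        # d(i, j) <= d(i, k) + d(k, j) for every intermediate k
        via = t[:, :, None] + t[None, :, :]  # via[i, k, j]
        assert np.all(t[:, None, :] <= via + 1e-9)

    def test_adding_an_edge_never_increases_od_times(self, rng):
        g, pts = self._random_network(rng)
        nodes = [tuple(p) for p in pts]
        before = od_matrix(g, _demand(nodes), _facilities(nodes[:5]), snap_tolerance=1.0)
        a, b = nodes[2], nodes[11]
        if not g.has_edge(a, b):
            g.add_edge(a, b, segment_id="new", road_class="highway", zone="Ondo City",
                       length_km=float(np.hypot(a[0] - b[0], a[1] - b[1])) / 1000.0)
            assign_travel_times(g, SPEEDS)
        after = od_matrix(g, _demand(nodes), _facilities(nodes[:5]), snap_tolerance=1.0)
        assert np.all(after.times["taxi"] <= before.times["taxi"] + 1e-9)


class TestTravelMode:
    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            TravelMode("walk", -1.0)

    def test_default_modes(self):
        names = {m.name: m.time_penalty_min for m in DEFAULT_MODES}
        assert names == {"taxi": 0.0, "minibus": 15.0}
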