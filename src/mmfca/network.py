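"""Routable travel-time network and origin–destination matrices.

Road segments (classed polylines in planar metres) are snapped into a graph,
edge traversal times follow ``60 * length_km / speed_kmh`` with class-by-zone
mean speeds, and per-mode OD travel times come from Dijkstra shortest paths
plus a fixed mode penalty (15 min for shared minibus, reflecting pick-up and
drop-off stops along the way).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import LineString


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class RoadSegment:
    segment_id: str
    geometry: LineString
    road_class: str  # highway | major | residential
    zone: str

    @property
    def length_km(self) -> float:
        return self.geometry.length / 1000.0


@dataclass(frozen=True)
class TravelMode:
    """A transport mode with a fixed time penalty added to every trip."""

    name: str
    time_penalty_min: float = 0.0

    def __post_init__(self) -> None:
        if self.time_penalty_min < 0:
            raise ValueError("time_penalty_min must be >= 0")


TAXI = TravelMode("taxi", 0.0)
MINIBUS = TravelMode("minibus", 15.0)
DEFAULT_MODES = (TAXI, MINIBUS)


@dataclass
class TopologyReport:
    """Outcome of the topological check performed while building the graph."""

    n_nodes: int = 0
    n_edges: int = 0
    n_components: int = 0
    dangling_endpoints: int = 0
    merged_endpoints: int = 0
    rejected_segments: list[str] = field(default_factory=list)
    collapsed_duplicates: int = 0

    @property
    def n_errors(self) -> int:
        return len(self.rejected_segments)


def _snap_endpoints(points: np.ndarray, tolerance: float) -> np.ndarray:
    """Union-find merge of endpoints within ``tolerance``; returns cluster ids."""
    n = len(points)
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if tolerance > 0 and n > 1:
        tree = cKDTree(points)
        for i, j in sorted(tree.query_pairs(r=tolerance)):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
    return np.array([find(i) for i in range(n)])


def build_network(
    segments: list[RoadSegment], snap_tolerance: float = 1.0
) -> tuple[nx.Graph, TopologyReport]:
    """Snap segment endpoints into a graph; collapse duplicate edges.

    Endpoints within ``snap_tolerance`` metres merge into one node (the
    cluster representative is the lexicographically smallest coordinate, so
    the build is deterministic).  Parallel edges keep the shorter segment;
    degenerate segments (< 2 distinct points after snapping) are rejected
    into the report rather than silently dropped.
    """
    if not segments:
        raise NetworkError("cannot build a network from zero segments")
    if snap_tolerance < 0:
        raise NetworkError("snap_tolerance must be >= 0")

    report = TopologyReport()
    endpoints = []
    seg_ok: list[RoadSegment] = []
    for seg in segments:
        coords = list(seg.geometry.coords)
        if len(coords) < 2 or seg.geometry.length == 0.0:
            report.rejected_segments.append(seg.segment_id)
            continue
        seg_ok.append(seg)
        endpoints.append(coords[0])
        endpoints.append(coords[-1])
    if not seg_ok:
        raise NetworkError("all segments were degenerate")

    pts = np.asarray(endpoints, dtype=float)
    cluster = _snap_endpoints(pts, snap_tolerance)
    # representative coordinate per cluster: lexicographic minimum
    node_xy: dict[int, tuple[float, float]] = {}
    for idx, c in enumerate(cluster):
        xy = (pts[idx, 0], pts[idx, 1])
        if c not in node_xy or xy < node_xy[c]:
            node_xy[c] = xy
    report.merged_endpoints = len(pts) - len(set(cluster.tolist()))

    g = nx.Graph()
    for k, seg in enumerate(seg_ok):
        u = node_xy[cluster[2 * k]]
        v = node_xy[cluster[2 * k + 1]]
        if u == v:
            report.rejected_segments.append(seg.segment_id)
            continue
        if g.has_edge(u, v):
            report.collapsed_duplicates += 1
            if g.edges[u, v]["length_km"] <= seg.length_km:
                continue
        g.add_edge(
            u,
            v,
            segment_id=seg.segment_id,
            road_class=seg.road_class,
            zone=seg.zone,
            length_km=seg.length_km,
        )
    report.n_nodes = g.number_of_nodes()
    report.n_edges = g.number_of_edges()
    report.n_components = nx.number_connected_components(g)
    report.dangling_endpoints = sum(1 for _, d in g.degree() if d == 1)
    return g, report


def assign_travel_times(
    g: nx.Graph,
    speed_table: dict[str, dict[str, float]],
    default_zone: str | None = None,
) -> nx.Graph:
    """Attach ``speed_kmh`` and ``travel_time_min`` to every edge.

    ``speed_table`` maps zone -> road_class -> km/h (the layout of a
    class-by-city mean-speed table).  A missing (zone, class) pair falls back
    to ``default_zone`` if given, otherwise raises naming the pair.
    """
    for u, v, data in g.edges(data=True):
        zone, rclass = data["zone"], data["road_class"]
        row = speed_table.get(zone)
        if row is None or rclass not in row:
            if default_zone is not None and rclass in speed_table.get(default_zone, {}):
                row = speed_table[default_zone]
            else:
                raise NetworkError(f"no speed for road_class={rclass!r} in zone={zone!r}")
        speed = float(row[rclass])
        if speed <= 0:
            raise NetworkError(f"non-positive speed for ({rclass}, {zone})")
        data["speed_kmh"] = speed
        data["travel_time_min"] = 60.0 * data["length_km"] / speed
    return g


class ODMatrix:
    """Per-mode travel times (minutes) from demand cells to facilities.

    ``times[mode]`` is an ``(n_demand, n_facility)`` array; unreachable pairs
    are ``+inf``.  For every reachable pair the minibus entry exceeds the
    taxi entry by exactly the minibus penalty.
    """

    def __init__(
        self,
        demand_ids: list[str],
        facility_ids: list[str],
        modes: tuple[TravelMode, ...],
        base_times: np.ndarray,
    ):
        base = np.asarray(base_times, dtype=float)
        if base.shape != (len(demand_ids), len(facility_ids)):
            raise ValueError("base_times shape mismatch")
        if np.any(base[np.isfinite(base)] < 0):
            raise ValueError("travel times must be >= 0")
        self.demand_ids = list(demand_ids)
        self.facility_ids = list(facility_ids)
        self.modes = tuple(modes)
        self.times = {m.name: base + m.time_penalty_min for m in modes}

    @property
    def mode_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.modes)

    def entry(self, demand_id: str, facility_id: str, mode: str) -> float:
        i = self.demand_ids.index(demand_id)
        j = self.facility_ids.index(facility_id)
        return float(self.times[mode][i, j])

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for mode in self.mode_names:
            t = self.times[mode]
            for i, did in enumerate(self.demand_ids):
                for j, fid in enumerate(self.facility_ids):
                    rows.append((did, fid, mode, t[i, j]))
        return pd.DataFrame(rows, columns=["demand_id", "facility_id", "mode", "minutes"])

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, modes: tuple[TravelMode, ...] = DEFAULT_MODES) -> "ODMatrix":
        demand_ids = list(pd.unique(df["demand_id"]))
        facility_ids = list(pd.unique(df["facility_id"]))
        mode_names = {m.name for m in modes}
        if set(pd.unique(df["mode"])) != mode_names:
            raise ValueError("mode set in frame does not match requested modes")
        base_mode = modes[0]
        sub = df[df["mode"] == base_mode.name]
        pivot = sub.pivot(index="demand_id", columns="facility_id", values="minutes")
        base = pivot.loc[demand_ids, facility_ids].to_numpy(dtype=float) - base_mode.time_penalty_min
        return cls(demand_ids, facility_ids, modes, base)


def _snap_points(
    g: nx.Graph, points: np.ndarray, ids: list[str], tolerance: float
) -> list[tuple[float, float]]:
    nodes = list(g.nodes)
    tree = cKDTree(np.asarray(nodes, dtype=float))
    dist, idx = tree.query(points)
    bad = [ids[i] for i in range(len(ids)) if dist[i] > tolerance]
    if bad:
        raise NetworkError(
            f"{len(bad)} point(s) farther than {tolerance} m from any network node: {bad[:5]}"
        )
    return [nodes[i] for i in idx]


def od_matrix(
    g: nx.Graph,
    demand: pd.DataFrame,
    facilities: pd.DataFrame,
    modes: tuple[TravelMode, ...] = DEFAULT_MODES,
    snap_tolerance: float = 500.0,
) -> ODMatrix:
    """Shortest-path travel times from every demand point to every facility.

    ``demand`` needs columns ``cell_id, x, y``; ``facilities`` needs
    ``facility_id, x, y``.  Points snap to the nearest graph node within
    ``snap_tolerance`` metres (an error lists offending ids).  Unreachable
    pairs are ``+inf``; each mode adds its fixed penalty.
    """
    sample = next(iter(g.edges(data=True)))[2] if g.number_of_edges() else {}
    if "travel_time_min" not in sample:
        raise NetworkError("network has no travel times; run assign_travel_times first")
    d_nodes = _snap_points(
        g, demand[["x", "y"]].to_numpy(dtype=float), list(demand["cell_id"]), snap_tolerance
    )
    f_nodes = _snap_points(
        g, facilities[["x", "y"]].to_numpy(dtype=float), list(facilities["facility_id"]), snap_tolerance
    )
    base = np.full((len(d_nodes), len(f_nodes)), np.inf)
    for j, fn in enumerate(f_nodes):
        lengths = nx.single_source_dijkstra_path_length(g, fn, weight="travel_time_min")
        for i, dn in enumerate(d_nodes):
            if dn in lengths:
                base[i, j] = lengths[dn]
    return ODMatrix(list(demand["cell_id"]), list(facilities["facility_id"]), modes, base)
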