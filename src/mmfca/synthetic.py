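"""Synthetic study-region generator.

Builds complete, seed-deterministic scenarios emulating a predominantly
rural region with a few dense cities: classed road segments (inter-city
highways, intra-city major/residential street grids, rural residential spur
roads), a ~1 km gridded population surface (Gaussian urban cores that
conserve the configured city totals, thinned rural settlement along roads),
screening facilities with integer staff counts, and client residence points
sampled with an urban bias.

Geometry is arranged so the downstream snapping contracts hold by
construction: city street intersections coincide with cell centroids,
facilities sit on intersections, and rural cells lie within the default
point-snap tolerance of a road node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString
from shapely.ops import unary_union

from .config import DEFAULT_CITY_POSITIONS, ConfigurationError, ScenarioConfig
from .demand import classify_urban
from .network import RoadSegment

# substream tags so each generator stage is independently deterministic
_RNG_LAYOUT, _RNG_NETWORK, _RNG_POPULATION, _RNG_CLIENTS = 10, 11, 12, 13

# cells whose centroid lies this close to a rural road are settlement
# candidates (kept within the default 500 m point-snap tolerance of a node)
_RURAL_BAND_M = 400.0
_HIGHWAY_STEP_M = 500.0
_SPUR_LENGTH_KM = (10.0, 18.0)


@dataclass(frozen=True)
class City:
    name: str
    center: tuple[float, float]  # a cell centroid
    side_cells: int              # odd; footprint is side x side cells
    population: int

    def half_extent(self, cell_size: float) -> float:
        return (self.side_cells / 2.0) * cell_size


def _snap_to_centroid(x: float, y: float, cell_size: float) -> tuple[float, float]:
    return (
        (np.floor(x / cell_size) + 0.5) * cell_size,
        (np.floor(y / cell_size) + 0.5) * cell_size,
    )


def city_layout(config: ScenarioConfig) -> list[City]:
    """Deterministic city placement.

    With explicit ``city_positions`` (or the stylised four-city default) the
    layout is fixed regardless of seed; otherwise cities occupy distinct
    blocks of a jittered lattice so footprints never overlap.  Centers snap
    to population-cell centroids so street intersections and facilities land
    exactly on demand points.
    """
    xmin, ymin, xmax, ymax = config.region_extent
    positions = config.city_positions
    if positions is None and config.n_cities == len(DEFAULT_CITY_POSITIONS):
        positions = DEFAULT_CITY_POSITIONS

    def _side_cells(pop: int) -> int:
        side_km = np.sqrt(pop / config.urban_density_per_km2)
        side = max(3, int(round(side_km * 1000.0 / config.cell_size)))
        return side + 1 if side % 2 == 0 else side

    centers_frac: list[tuple[float, float]]
    if positions is not None:
        centers_frac = list(positions)
        jitter = None
    else:
        rng = np.random.default_rng([config.seed, _RNG_LAYOUT])
        b = int(np.ceil(np.sqrt(config.n_cities)))
        order = rng.permutation(b * b)[: config.n_cities]
        centers_frac = []
        for block in order:
            br, bc = divmod(int(block), b)
            centers_frac.append(
                (
                    (bc + 0.5 + rng.uniform(-0.15, 0.15)) / b,
                    (br + 0.5 + rng.uniform(-0.15, 0.15)) / b,
                )
            )
    cities = []
    for i, (fx, fy) in enumerate(centers_frac):
        pop = int(config.city_populations[i])
        side_cells = _side_cells(pop)
        margin = (side_cells / 2.0 + 2.0) * config.cell_size
        cx = float(np.clip(xmin + fx * (xmax - xmin), xmin + margin, xmax - margin))
        cy = float(np.clip(ymin + fy * (ymax - ymin), ymin + margin, ymax - margin))
        center = _snap_to_centroid(cx, cy, config.cell_size)
        cities.append(City(config.city_names[i], center, side_cells, pop))
    return cities


def _nearest_city(cities: list[City], x: float, y: float) -> City:
    d2 = [(c.center[0] - x) ** 2 + (c.center[1] - y) ** 2 for c in cities]
    return cities[int(np.argmin(d2))]


def _subdivide(p0, p1, step: float) -> list[tuple[float, float]]:
    """Points along the segment p0->p1 at spacing <= step (endpoints included)."""
    p0, p1 = np.asarray(p0, dtype=float), np.asarray(p1, dtype=float)
    length = float(np.hypot(*(p1 - p0)))
    n = max(1, int(np.ceil(length / step)))
    return [tuple(p0 + (p1 - p0) * t) for t in np.linspace(0.0, 1.0, n + 1)]


def _city_grid_segments(city: City, cell_size: float, counter) -> list[RoadSegment]:
    """Street grid whose intersections are the city's cell centroids.

    The central row and column are major roads; the rest are residential.
    """
    h = city.side_cells // 2
    cx, cy = city.center
    segs = []
    for r in range(-h, h + 1):
        for c in range(-h, h + 1):
            x, y = cx + c * cell_size, cy + r * cell_size
            for dx, dy in ((cell_size, 0.0), (0.0, cell_size)):
                if c + (dx > 0) > h or r + (dy > 0) > h:
                    continue
                on_axis = (r == 0 and dx > 0) or (c == 0 and dy > 0)
                segs.append(
                    RoadSegment(
                        segment_id=f"seg{next(counter):05d}",
                        geometry=LineString([(x, y), (x + dx, y + dy)]),
                        road_class="major" if on_axis else "residential",
                        zone=city.name,
                    )
                )
    return segs


def _mst_edges(cities: list[City]) -> list[tuple[int, int]]:
    """Euclidean minimum spanning tree over city centers (Prim, deterministic)."""
    n = len(cities)
    pts = np.array([c.center for c in cities])
    in_tree = [0]
    edges = []
    while len(in_tree) < n:
        best = None
        for i in in_tree:
            for j in range(n):
                if j in in_tree:
                    continue
                d = float(np.hypot(*(pts[i] - pts[j])))
                if best is None or d < best[0] or (d == best[0] and (i, j) < best[1:]):
                    best = (d, i, j)
        edges.append((best[1], best[2]))
        in_tree.append(best[2])
    return edges


def generate_network(config: ScenarioConfig) -> list[RoadSegment]:
    """Generate the region's classed road segments.

    Highways join city centers along the minimum spanning tree; each city has
    a street grid (major axes, residential side streets); each highway grows
    a perpendicular rural residential spur from its midpoint.  The resulting
    graph is connected by construction.
    """
    if config.n_cities < 2:
        raise ConfigurationError("need at least 2 cities to generate an inter-city highway")
    rng = np.random.default_rng([config.seed, _RNG_NETWORK])
    cities = city_layout(config)
    counter = iter(range(10**6))
    segments: list[RoadSegment] = []
    for city in cities:
        segments.extend(_city_grid_segments(city, config.cell_size, counter))

    xmin, ymin, xmax, ymax = config.region_extent

    # radial rural roads: each city's major axes continue outward as
    # residential roads, the corridors along which villages sit
    for city in cities:
        he = city.half_extent(config.cell_size)
        for ux, uy in ((1.0, 0.0), (-1.0, 0.0), (0.0, 1.0), (0.0, -1.0)):
            start = (city.center[0] + ux * he, city.center[1] + uy * he)
            length = rng.uniform(8.0, 15.0) * 1000.0
            end = (start[0] + ux * length, start[1] + uy * length)
            end = (
                float(np.clip(end[0], xmin + 1000.0, xmax - 1000.0)),
                float(np.clip(end[1], ymin + 1000.0, ymax - 1000.0)),
            )
            # the grid node nearest the footprint edge anchors the radial
            anchor = (
                city.center[0] + ux * (city.side_cells // 2) * config.cell_size,
                city.center[1] + uy * (city.side_cells // 2) * config.cell_size,
            )
            for p0, p1 in zip(*(lambda s: (s[:-1], s[1:]))(_subdivide(anchor, end, _HIGHWAY_STEP_M))):
                segments.append(
                    RoadSegment(
                        segment_id=f"seg{next(counter):05d}",
                        geometry=LineString([p0, p1]),
                        road_class="residential",
                        zone=city.name,
                    )
                )

    for i, j in _mst_edges(cities):
        pts = _subdivide(cities[i].center, cities[j].center, _HIGHWAY_STEP_M)
        for p0, p1 in zip(pts[:-1], pts[1:]):
            mid = ((p0[0] + p1[0]) / 2.0, (p0[1] + p1[1]) / 2.0)
            segments.append(
                RoadSegment(
                    segment_id=f"seg{next(counter):05d}",
                    geometry=LineString([p0, p1]),
                    road_class="highway",
                    zone=_nearest_city(cities, *mid).name,
                )
            )
        # rural spurs: residential roads leaving the highway at right angles
        # at the quarter points, alternating sides, each with a mid-length
        # branch -- the minor-road structure rural settlements string along
        direction = np.array(cities[j].center) - np.array(cities[i].center)
        direction = direction / np.linalg.norm(direction)
        normal = np.array([-direction[1], direction[0]])
        for q, quarter in enumerate((0.25, 0.5, 0.75)):
            anchor = pts[int(round(quarter * (len(pts) - 1)))]
            side = normal * (1.0 if (q % 2 == 0) else -1.0) * rng.choice([-1.0, 1.0])
            length = rng.uniform(*_SPUR_LENGTH_KM) * 1000.0
            end = np.array(anchor) + side * length
            end[0] = float(np.clip(end[0], xmin + 1000.0, xmax - 1000.0))
            end[1] = float(np.clip(end[1], ymin + 1000.0, ymax - 1000.0))
            spur_pts = _subdivide(anchor, tuple(end), _HIGHWAY_STEP_M)
            branch_root = spur_pts[len(spur_pts) // 2]
            for p0, p1 in zip(spur_pts[:-1], spur_pts[1:]):
                segments.append(
                    RoadSegment(
                        segment_id=f"seg{next(counter):05d}",
                        geometry=LineString([p0, p1]),
                        road_class="residential",
                        zone=_nearest_city(cities, *p0).name,
                    )
                )
            # branch off the spur, parallel to the highway
            b_len = rng.uniform(0.4, 0.7) * length
            b_dir = direction * rng.choice([-1.0, 1.0])
            b_end = np.array(branch_root) + b_dir * b_len
            b_end[0] = float(np.clip(b_end[0], xmin + 1000.0, xmax - 1000.0))
            b_end[1] = float(np.clip(b_end[1], ymin + 1000.0, ymax - 1000.0))
            for p0, p1 in zip(*(lambda s: (s[:-1], s[1:]))(_subdivide(branch_root, tuple(b_end), _HIGHWAY_STEP_M))):
                segments.append(
                    RoadSegment(
                        segment_id=f"seg{next(counter):05d}",
                        geometry=LineString([p0, p1]),
                        road_class="residential",
                        zone=_nearest_city(cities, *p0).name,
                    )
                )
    return segments


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer apportionment of ``total`` by ``weights`` (sum is exact)."""
    shares = total * weights / weights.sum()
    base = np.floor(shares).astype(int)
    short = total - int(base.sum())
    order = np.argsort(-(shares - base), kind="stable")
    base[order[:short]] += 1
    return base


def generate_population(config: ScenarioConfig) -> pd.DataFrame:
    """Generate the gridded population: dense urban cores, sparse rural matrix.

    City cells follow a discretised Gaussian around the center and sum
    exactly to the configured totals (largest-remainder rounding).  Rural
    cells are a thinned sample of grid cells near highways and spurs with
    small populations, mirroring settlement along roads.  Zero-population
    cells are omitted.  Returns ``cell_id, x, y, pop``.
    """
    cities = city_layout(config)
    rng = np.random.default_rng([config.seed, _RNG_POPULATION])
    cs = config.cell_size
    rows = []
    for city in cities:
        h = city.side_cells // 2
        cx, cy = city.center
        offs = np.arange(-h, h + 1)
        dx, dy = np.meshgrid(offs, offs)
        sigma = max(city.side_cells / 3.0, 1.0)
        w = np.exp(-(dx**2 + dy**2) / (2.0 * sigma**2)).ravel()
        counts = _largest_remainder(city.population, w)
        for k, (ox, oy) in enumerate(zip(dx.ravel(), dy.ravel())):
            if counts[k] > 0:
                rows.append((cx + ox * cs, cy + oy * cs, int(counts[k])))

    # rural candidates: cells near a road line, outside every city footprint
    segments = generate_network(config) if config.n_cities >= 2 else []
    rural_geoms = [
        s.geometry for s in segments
        if not _inside_any_city(s.geometry.centroid, cities, cs)
    ]
    xmin, ymin, xmax, ymax = config.region_extent
    n_cols = int(np.floor((xmax - xmin) / cs))
    n_rows = int(np.floor((ymax - ymin) / cs))
    xs = xmin + (np.arange(n_cols) + 0.5) * cs
    ys = ymin + (np.arange(n_rows) + 0.5) * cs
    gx, gy = np.meshgrid(xs, ys)
    centroids = np.column_stack([gx.ravel(), gy.ravel()])
    in_city = np.zeros(len(centroids), dtype=bool)
    for city in cities:
        he = city.half_extent(cs)
        in_city |= (np.abs(centroids[:, 0] - city.center[0]) <= he) & (
            np.abs(centroids[:, 1] - city.center[1]) <= he
        )
    if rural_geoms:
        rural_lines = unary_union(rural_geoms)
        dist = shapely.distance(shapely.points(centroids), rural_lines)
        candidate = (~in_city) & (dist <= _RURAL_BAND_M)
        keep = candidate & (rng.random(len(centroids)) < config.rural_keep_p)
        lo, hi = config.rural_pop_range
        pops = rng.integers(lo, hi + 1, size=len(centroids))
        for x, y, p in zip(centroids[keep, 0], centroids[keep, 1], pops[keep]):
            rows.append((float(x), float(y), int(p)))

    df = pd.DataFrame(rows, columns=["x", "y", "pop"])
    df = df.groupby(["x", "y"], as_index=False)["pop"].sum()  # city/rural overlap guard
    df = df.sort_values(["y", "x"], kind="stable").reset_index(drop=True)
    df.insert(0, "cell_id", [f"c{i:05d}" for i in range(len(df))])
    return df


def _inside_any_city(point, cities: list[City], cell_size: float) -> bool:
    for city in cities:
        he = city.half_extent(cell_size)
        if abs(point.x - city.center[0]) <= he and abs(point.y - city.center[1]) <= he:
            return True
    return False


def generate_facilities(config: ScenarioConfig) -> pd.DataFrame:
    """Place facilities on street intersections near their city's center.

    Several facilities in the same city occupy successive intersections so
    no two facilities share a node.  Returns ``facility_id, x, y, staff``.
    """
    cities = city_layout(config)
    cs = config.cell_size
    offsets = [(0, 0), (1, 0), (0, 1), (-1, 0), (0, -1), (1, 1), (-1, -1), (1, -1), (-1, 1)]
    used_per_city: dict[int, int] = {}
    rows = []
    for k, (city_idx, staff) in enumerate(config.facility_spec):
        city = cities[city_idx]
        slot = used_per_city.get(city_idx, 0)
        if slot >= len(offsets):
            raise ConfigurationError("too many facilities in one city")
        ox, oy = offsets[slot]
        used_per_city[city_idx] = slot + 1
        rows.append(
            (f"f{k:02d}", city.center[0] + ox * cs, city.center[1] + oy * cs, int(staff))
        )
    return pd.DataFrame(rows, columns=["facility_id", "x", "y", "staff"])


def generate_clients(
    config: ScenarioConfig,
    cells: pd.DataFrame,
    urban_threshold: float = 20_000,
) -> pd.DataFrame:
    """Sample client residence points with an urban bias.

    Each client independently falls in the urban stratum with probability
    ``urban_client_fraction`` (when that stratum exists), then in a cell
    proportional to its population, then uniformly within the cell footprint.
    Returns ``client_id, x, y``.
    """
    if config.n_clients < 0:
        raise ConfigurationError("n_clients must be >= 0")
    if config.n_clients == 0:
        return pd.DataFrame(columns=["client_id", "x", "y"])
    if cells.empty:
        raise ConfigurationError("cannot sample clients from an empty cell table")
    rng = np.random.default_rng([config.seed, _RNG_CLIENTS])
    classified = (
        cells if "is_urban" in cells.columns
        else classify_urban(cells, urban_threshold, config.cell_size)
    )
    urban_cells = classified[classified["is_urban"]]
    rural_cells = classified[~classified["is_urban"]]
    p_urban = config.urban_client_fraction
    if urban_cells.empty:
        p_urban = 0.0
    if rural_cells.empty:
        p_urban = 1.0
    strata = rng.random(config.n_clients) < p_urban
    rows = []
    for i, is_urb in enumerate(strata):
        stratum = urban_cells if is_urb else rural_cells
        weights = stratum["pop"].to_numpy(dtype=float)
        cell = stratum.iloc[int(rng.choice(len(stratum), p=weights / weights.sum()))]
        x = cell["x"] + rng.uniform(-0.5, 0.5) * config.cell_size
        y = cell["y"] + rng.uniform(-0.5, 0.5) * config.cell_size
        rows.append((f"k{i:04d}", float(x), float(y)))
    return pd.DataFrame(rows, columns=["client_id", "x", "y"])
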