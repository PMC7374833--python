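"""End-to-end pipeline stages over on-disk artifacts.

Each stage reads/writes the conventional file set inside one working
directory, so stages can be run separately (CLI subcommands, analysis
drivers) or chained with :func:`run_all`:

    roads.geojson, speed_table.csv, population.csv/.asc, facilities.geojson,
    clients.csv  ->  od_matrix.csv  ->  demand.csv, access.csv/.geojson  ->
    report.json/.csv, sensitivity.json
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .access import DecayParams, build_access_surface
from .config import RunConfig, ScenarioConfig
from .demand import assign_mode_split, classify_urban, load_population_grid, write_ascii_grid
from .network import DEFAULT_MODES, MINIBUS, TAXI, TravelMode, assign_travel_times, build_network, od_matrix
from .reporting import assign_clients, coverage_stats, sensitivity_sweep, zone_shares
from .synthetic import (
    generate_clients,
    generate_facilities,
    generate_network,
    generate_population,
)


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required input not found: {path}")
    return path


def _modes(run: RunConfig) -> tuple[TravelMode, ...]:
    return (TAXI, TravelMode(MINIBUS.name, run.minibus_penalty_min))


def simulate(scenario: ScenarioConfig, outdir) -> dict[str, Path]:
    """Generate a synthetic scenario and write its file set."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    segments = generate_network(scenario)
    cells = generate_population(scenario)
    facilities = generate_facilities(scenario)
    clients = generate_clients(scenario, cells)

    mio.write_roads_geojson(out / "roads.geojson", segments)
    mio.write_speed_table(out / "speed_table.csv", scenario.speed_table)
    cells.to_csv(out / "population.csv", index=False)
    _write_population_asc(out / "population.asc", cells, scenario)
    mio.write_facilities_geojson(out / "facilities.geojson", facilities)
    clients.to_csv(out / "clients.csv", index=False)
    (out / "scenario.json").write_text(
        json.dumps(
            {
                "seed": scenario.seed,
                "n_cities": scenario.n_cities,
                "city_populations": list(scenario.city_populations),
                "n_cells": len(cells),
                "n_segments": len(segments),
                "n_clients": len(clients),
            },
            indent=2,
        )
        + "\n"
    )
    return {name: out / name for name in
            ("roads.geojson", "speed_table.csv", "population.csv", "facilities.geojson", "clients.csv")}


def _write_population_asc(path, cells: pd.DataFrame, scenario: ScenarioConfig) -> None:
    xmin, ymin, xmax, ymax = scenario.region_extent
    cs = scenario.cell_size
    ncols = int(np.floor((xmax - xmin) / cs))
    nrows = int(np.floor((ymax - ymin) / cs))
    grid = np.zeros((nrows, ncols))
    col = np.floor((cells["x"].to_numpy() - xmin) / cs).astype(int)
    row = (nrows - 1 - np.floor((cells["y"].to_numpy() - ymin) / cs)).astype(int)
    ok = (col >= 0) & (col < ncols) & (row >= 0) & (row < nrows)
    grid[row[ok], col[ok]] = cells["pop"].to_numpy()[ok]
    write_ascii_grid(path, grid, xmin, ymin, cs)


def build_travel_times(workdir, run: RunConfig):
    """Build the routable network and write the per-mode OD matrix."""
    work = Path(workdir)
    segments = mio.read_roads_geojson(_require(work / "roads.geojson"))
    speeds = mio.read_speed_table(_require(work / "speed_table.csv"))
    g, report = build_network(segments, snap_tolerance=run.endpoint_snap_m)
    g = assign_travel_times(g, speeds)
    cells = load_population_grid(_require(work / "population.csv"))
    facilities = mio.read_facilities(_require(work / "facilities.geojson"))
    od = od_matrix(g, cells, facilities, modes=_modes(run), snap_tolerance=run.point_snap_m)
    mio.write_od_matrix(work / "od_matrix.csv", od)
    (work / "topology_report.json").write_text(
        json.dumps(
            {
                "n_nodes": report.n_nodes,
                "n_edges": report.n_edges,
                "n_components": report.n_components,
                "dangling_endpoints": report.dangling_endpoints,
                "merged_endpoints": report.merged_endpoints,
                "rejected_segments": report.rejected_segments,
                "collapsed_duplicates": report.collapsed_duplicates,
            },
            indent=2,
        )
        + "\n"
    )
    return od, report


def compute_access(workdir, run: RunConfig) -> pd.DataFrame:
    """Classify demand, run the two-step model, zone the surface."""
    work = Path(workdir)
    cells = load_population_grid(_require(work / "population.csv"))
    cells = classify_urban(cells, run.urban_threshold)
    cells = assign_mode_split(cells, run.urban_split, run.rural_split)
    cells.to_csv(work / "demand.csv", index=False)
    od = mio.read_od_matrix(_require(work / "od_matrix.csv"), modes=_modes(run))
    facilities = mio.read_facilities(_require(work / "facilities.geojson"))
    decay = DecayParams.calibrated(run.d0_urban_min, run.d0_rural_min, run.epsilon)
    surface, ratios = build_access_surface(od, cells, facilities, decay, run.n_zones)
    surface.to_csv(work / "access.csv", index=False)
    mio.write_access_geojson(work / "access.geojson", surface)
    ratios.to_csv(work / "supply_ratios.csv", index=False)
    return surface


def report(workdir, run: RunConfig, designated_facility: str | None = None) -> dict:
    """Overlay clients on the surface; write zone shares and coverage."""
    work = Path(workdir)
    surface = pd.read_csv(_require(work / "access.csv"))
    clients = pd.read_csv(_require(work / "clients.csv"))
    od = mio.read_od_matrix(_require(work / "od_matrix.csv"), modes=_modes(run))
    cell_size = _infer_cell_size(surface)
    records = assign_clients(clients, surface, cell_size)
    if designated_facility is None:
        facilities = mio.read_facilities(_require(work / "facilities.geojson"))
        designated_facility = facilities.loc[facilities["staff"].idxmax(), "facility_id"]
    result = {
        "provenance": {"config": run.to_dict(), "designated_facility": designated_facility},
        "n_clients": len(records),
        "zone_shares_pct": zone_shares(records, run.n_zones),
        "coverage_pct": coverage_stats(
            records,
            od,
            designated_facility,
            {"taxi": run.d0_urban_min, "minibus": run.d0_rural_min},
        ),
    }
    shares = result["zone_shares_pct"]
    result["top_two_zone_share_pct"] = shares["1"] + shares["2"]
    (work / "report.json").write_text(json.dumps(result, indent=2) + "\n")
    records.to_csv(work / "report.csv", index=False)
    return result


def _infer_cell_size(surface: pd.DataFrame) -> float:
    xs = np.sort(np.unique(surface["x"].to_numpy(dtype=float)))
    diffs = np.diff(xs)
    diffs = diffs[diffs > 0]
    return float(diffs.min()) if diffs.size else 1000.0


def default_sweep_scenarios(run: RunConfig) -> list[tuple[dict, dict]]:
    """Baseline plus the published alternative mode shares.

    Urban taxi share 80->70->60% with the rural share held, then rural taxi
    share 20->30->40% with the urban share held.
    """
    base = (dict(run.urban_split), dict(run.rural_split))
    scen = [base]
    for u in (0.7, 0.6):
        scen.append(({"taxi": u, "minibus": round(1 - u, 10)}, dict(run.rural_split)))
    for r in (0.3, 0.4):
        scen.append((dict(run.urban_split), {"taxi": r, "minibus": round(1 - r, 10)}))
    return scen


def sensitivity(workdir, run: RunConfig, scenarios=None) -> list[dict]:
    """Mode-split sensitivity sweep over the current scenario's files."""
    work = Path(workdir)
    cells = load_population_grid(_require(work / "population.csv"))
    cells = classify_urban(cells, run.urban_threshold)
    od = mio.read_od_matrix(_require(work / "od_matrix.csv"), modes=_modes(run))
    facilities = mio.read_facilities(_require(work / "facilities.geojson"))
    decay = DecayParams.calibrated(run.d0_urban_min, run.d0_rural_min, run.epsilon)
    if scenarios is None:
        scenarios = default_sweep_scenarios(run)
    results = sensitivity_sweep(od, cells, facilities, decay, scenarios, run.n_zones)
    (work / "sensitivity.json").write_text(json.dumps(results, indent=2) + "\n")
    return results


def run_all(workdir, run: RunConfig, scenarios=None) -> dict:
    """build-network/od -> access -> report -> sensitivity, in order."""
    build_travel_times(workdir, run)
    compute_access(workdir, run)
    result = report(workdir, run)
    result["sensitivity"] = sensitivity(workdir, run, scenarios)
    (Path(workdir) / "report.json").write_text(json.dumps(result, indent=2) + "\n")
    return result
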