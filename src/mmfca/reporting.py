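"""Client overlay statistics and mode-split sensitivity analysis.

Clients are residence points overlaid on the modelled access surface: each
inherits the zone of its containing (or nearest, within twice the cell size)
demand cell, and its travel times to the designated screening facility are
those of that cell's OD row.  The sensitivity sweep reruns the access model
under alternative taxi/minibus shares and compares high-access population
shares and per-zone population counts against the baseline scenario.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .access import OUTSIDE, DecayParams, build_access_surface
from .demand import assign_mode_split
from .network import ODMatrix


class ReportingError(ValueError):
    pass


def assign_clients(
    clients: pd.DataFrame, surface: pd.DataFrame, cell_size: float
) -> pd.DataFrame:
    """Map each client to a demand cell and inherit its access zone.

    A client belongs to the cell whose square footprint contains it, else to
    the nearest cell centroid within ``2 * cell_size``; beyond that it is
    labelled outside (zone 0) with no cell.  Unmatched clients are kept, not
    dropped.
    """
    if surface.empty:
        raise ReportingError("access surface is empty")
    out = clients.copy()
    if clients.empty:
        out["cell_id"] = pd.Series(dtype=object)
        out["zone"] = pd.Series(dtype=int)
        return out
    tree = cKDTree(surface[["x", "y"]].to_numpy(dtype=float))
    pts = clients[["x", "y"]].to_numpy(dtype=float)
    dist, idx = tree.query(pts)
    # containment = Chebyshev distance <= cell_size/2; nearest-centroid
    # fallback within 2 cells
    near = surface.iloc[idx]
    cheb = np.maximum(
        np.abs(pts[:, 0] - near["x"].to_numpy()), np.abs(pts[:, 1] - near["y"].to_numpy())
    )
    matched = (cheb <= cell_size / 2.0 + 1e-9) | (dist <= 2.0 * cell_size)
    out["cell_id"] = np.where(matched, near["cell_id"].to_numpy(), None)
    out["zone"] = np.where(matched, near["zone"].to_numpy(), OUTSIDE).astype(int)
    return out


def zone_shares(records: pd.DataFrame, n_zones: int = 6) -> dict[str, float]:
    """Percentage of clients per access zone ('1'..'6' plus 'outside')."""
    if records.empty:
        raise ReportingError("no client records to summarise")
    counts = records["zone"].value_counts()
    total = len(records)
    shares = {str(z): 100.0 * counts.get(z, 0) / total for z in range(1, n_zones + 1)}
    shares["outside"] = 100.0 * counts.get(OUTSIDE, 0) / total
    return shares


def coverage_stats(
    records: pd.DataFrame,
    od: ODMatrix,
    facility_id: str,
    thresholds: dict[str, float],
) -> dict[str, float]:
    """Share of clients within a per-mode travel-time budget of one facility.

    Uses each client's assigned cell's (penalised) OD time; comparison is
    inclusive ("within 40 min" counts a 40.0-min trip).  Clients with no
    assigned cell count as not covered.
    """
    if facility_id not in od.facility_ids:
        raise ReportingError(f"unknown facility_id {facility_id!r}")
    j = od.facility_ids.index(facility_id)
    row_of = {cid: i for i, cid in enumerate(od.demand_ids)}
    out = {}
    for mode, budget in thresholds.items():
        covered = 0
        for cid in records["cell_id"]:
            if cid is not None and cid in row_of:
                if od.times[mode][row_of[cid], j] <= budget:
                    covered += 1
        out[mode] = 100.0 * covered / len(records)
    return out


def _stratum_stats(surface: pd.DataFrame, n_zones: int) -> dict:
    """High-access (zones 1-2) population share per stratum + zone counts."""
    pop = surface["pop"].to_numpy(dtype=float)
    zone = surface["zone"].to_numpy()
    urban = surface["is_urban"].to_numpy(dtype=bool)
    high = (zone >= 1) & (zone <= 2)
    stats = {"zone_pop": {int(z): float(pop[zone == z].sum()) for z in range(n_zones + 1)}}
    for name, mask in (("urban", urban), ("rural", ~urban)):
        denom = pop[mask].sum()
        stats[f"{name}_high_access_share"] = (
            float(pop[mask & high].sum() / denom) if denom > 0 else 0.0
        )
    return stats


def sensitivity_sweep(
    od: ODMatrix,
    cells: pd.DataFrame,
    facilities: pd.DataFrame,
    decay: DecayParams,
    scenarios: list[tuple[dict[str, float], dict[str, float]]],
    n_zones: int = 6,
) -> list[dict]:
    """Rerun the access model under each (urban_split, rural_split) scenario.

    The first scenario is the baseline; each result carries the per-stratum
    high-access population shares, per-zone population counts, and deltas of
    both against the baseline.
    """
    if not scenarios:
        raise ReportingError("scenario list is empty")
    results = []
    for urban_split, rural_split in scenarios:
        cells_s = assign_mode_split(
            cells.drop(columns=[c for c in cells.columns if c.endswith("_frac")]),
            urban_split,
            rural_split,
        )
        surface, _ = build_access_surface(od, cells_s, facilities, decay, n_zones)
        stats = _stratum_stats(surface, n_zones)
        label = (
            f"urban {int(100 * urban_split.get('taxi', 0))}/{int(100 * urban_split.get('minibus', 0))}"
            f" rural {int(100 * rural_split.get('taxi', 0))}/{int(100 * rural_split.get('minibus', 0))}"
        )
        results.append({"label": label, "urban_split": urban_split, "rural_split": rural_split, **stats})
    base = results[0]
    for res in results:
        res["delta_urban_high_access_share"] = (
            res["urban_high_access_share"] - base["urban_high_access_share"]
        )
        res["delta_rural_high_access_share"] = (
            res["rural_high_access_share"] - base["rural_high_access_share"]
        )
        res["delta_zone_pop"] = {
            z: res["zone_pop"][z] - base["zone_pop"][z] for z in res["zone_pop"]
        }
    return results
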