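"""Demand layer: population grid, settlement detection and mode splits.

A gridded population raster (one value per ~1 km cell) becomes a table of
demand points at cell centroids.  Settlements are connected components of
populated cells under 8-neighbour (queen) adjacency; a settlement is urban
when its total population reaches the urbanisation threshold (20,000 people).
Each cell's population then splits into taxi/minibus subpopulations with the
urban or rural mode shares.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage


class DemandError(ValueError):
    pass


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid (6-line header + row-major values, north up)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise DemandError("ASCII grid dimensions do not match its header")
    return data, header


def write_ascii_grid(path, data: np.ndarray, xllcorner: float, yllcorner: float,
                     cellsize: float, nodata: float = -9999) -> None:
    data = np.atleast_2d(np.asarray(data))
    with open(path, "w") as fh:
        fh.write(
            f"ncols {data.shape[1]}\nnrows {data.shape[0]}\n"
            f"xllcorner {xllcorner:.6f}\nyllcorner {yllcorner:.6f}\n"
            f"cellsize {cellsize:.6f}\nNODATA_value {nodata}\n"
        )
        np.savetxt(fh, data, fmt="%.10g")


def load_population_grid(source) -> pd.DataFrame:
    """Load demand cells from an ESRI ASCII grid or a centroid CSV.

    Returns columns ``cell_id, x, y, pop`` with one row per cell of positive
    population (zero/nodata cells are excluded, mirroring the exclusion of
    unpopulated grid cells from the analysis).  Negative populations are a
    validation error naming the offending cell.
    """
    path = str(source)
    if path.endswith(".asc"):
        data, header = read_ascii_grid(path)
        nodata = header.get("nodata_value", -9999)
        data = np.where(data == nodata, 0.0, data)
        nrows, ncols = data.shape
        cs = header["cellsize"]
        rows, cols = np.nonzero(~np.isclose(data, 0.0))
        neg = data[rows, cols] < 0
        if neg.any():
            r, c = rows[neg][0], cols[neg][0]
            raise DemandError(f"negative population at grid cell (row={r}, col={c})")
        x = header["xllcorner"] + (cols + 0.5) * cs
        y = header["yllcorner"] + (nrows - rows - 0.5) * cs
        df = pd.DataFrame({"x": x, "y": y, "pop": data[rows, cols]})
        df = df.sort_values(["y", "x"], kind="stable").reset_index(drop=True)
        df.insert(0, "cell_id", [f"c{i:05d}" for i in range(len(df))])
        return df
    df = pd.read_csv(path)
    required = {"cell_id", "x", "y", "pop"}
    if not required.issubset(df.columns):
        raise DemandError(f"population CSV must have columns {sorted(required)}")
    neg = df["pop"] < 0
    if neg.any():
        raise DemandError(f"negative population at cell {df.loc[neg, 'cell_id'].iloc[0]!r}")
    return df[df["pop"] > 0].reset_index(drop=True)[["cell_id", "x", "y", "pop"]]


def _grid_indices(cells: pd.DataFrame, cell_size: float) -> tuple[np.ndarray, np.ndarray]:
    x = cells["x"].to_numpy(dtype=float)
    y = cells["y"].to_numpy(dtype=float)
    col = np.round((x - x.min()) / cell_size).astype(int)
    row = np.round((y - y.min()) / cell_size).astype(int)
    return row, col


def classify_urban(
    cells: pd.DataFrame, urban_threshold: float = 20_000, cell_size: float | None = None
) -> pd.DataFrame:
    """Label settlements and their urban/rural status.

    Settlements are queen-adjacency connected components of populated cells;
    a component is urban when its summed population meets ``urban_threshold``.
    Adds ``settlement_id`` (s000, s001, ... in raster order) and ``is_urban``.
    """
    if cell_size is None:
        for arr in (np.unique(cells["x"]), np.unique(cells["y"])):
            diffs = np.diff(np.sort(arr))
            diffs = diffs[diffs > 0]
            if diffs.size:
                cell_size = float(diffs.min())
                break
        if cell_size is None:
            cell_size = 1.0
    row, col = _grid_indices(cells, cell_size)
    raster = np.zeros((row.max() + 1, col.max() + 1), dtype=bool)
    raster[row, col] = True
    labels, _ = ndimage.label(raster, structure=np.ones((3, 3), dtype=int))
    comp = labels[row, col]
    pop_by_comp = pd.Series(cells["pop"].to_numpy(dtype=float)).groupby(comp).sum()
    out = cells.copy()
    out["settlement_id"] = [f"s{c - 1:03d}" for c in comp]
    out["is_urban"] = pop_by_comp.loc[comp].to_numpy() >= urban_threshold
    return out


def assign_mode_split(
    cells: pd.DataFrame,
    urban_split: dict[str, float],
    rural_split: dict[str, float],
) -> pd.DataFrame:
    """Attach per-mode population fractions (``<mode>_frac`` columns).

    Urban cells take ``urban_split`` (default 80% taxi / 20% minibus), rural
    cells ``rural_split`` (20% taxi / 80% minibus).  Splits must cover the
    same modes and each sum to 1.
    """
    if set(urban_split) != set(rural_split):
        raise DemandError("urban and rural splits must cover the same modes")
    for name, split in (("urban_split", urban_split), ("rural_split", rural_split)):
        if abs(sum(split.values()) - 1.0) > 1e-9:
            raise DemandError(f"{name} fractions sum to {sum(split.values())}, not 1")
        if any(v < 0 for v in split.values()):
            raise DemandError(f"{name} has a negative fraction")
    if "is_urban" not in cells.columns:
        raise DemandError("cells must be classified urban/rural first")
    out = cells.copy()
    urban = out["is_urban"].to_numpy(dtype=bool)
    for mode in urban_split:
        out[f"{mode}_frac"] = np.where(urban, urban_split[mode], rural_split[mode])
    return out
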