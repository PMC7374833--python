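"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from mmfca.network import DEFAULT_MODES, ODMatrix


def make_cells(
    n: int,
    pops,
    urban,
    taxi_frac,
    xy=None,
) -> pd.DataFrame:
    pops = np.asarray(pops, dtype=float)
    urban = np.asarray(urban, dtype=bool)
    taxi = np.asarray(taxi_frac, dtype=float)
    if xy is None:
        xy = np.column_stack([np.arange(n) * 1000.0, np.zeros(n)])
    return pd.DataFrame(
        {
            "cell_id": [f"c{i:03d}" for i in range(n)],
            "x": xy[:, 0],
            "y": xy[:, 1],
            "pop": pops,
            "is_urban": urban,
            "taxi_frac": taxi,
            "minibus_frac": 1.0 - taxi,
        }
    )


def make_facilities(staff) -> pd.DataFrame:
    staff = np.asarray(staff, dtype=int)
    return pd.DataFrame(
        {
            "facility_id": [f"f{j:02d}" for j in range(len(staff))],
            "x": np.arange(len(staff)) * 500.0,
            "y": np.full(len(staff), -1000.0),
            "staff": staff,
        }
    )


def make_od(cells: pd.DataFrame, facilities: pd.DataFrame, base_times) -> ODMatrix:
    return ODMatrix(
        list(cells["cell_id"]), list(facilities["facility_id"]), DEFAULT_MODES, base_times
    )


def random_instance(rng: np.random.Generator, max_cells: int = 50, max_fac: int = 5):
    """A random small model instance: cells, facilities, OD matrix."""
    n = int(rng.integers(1, max_cells + 1))
    m = int(rng.integers(1, max_fac + 1))
    cells = make_cells(
        n,
        pops=rng.integers(1, 2000, size=n),
        urban=rng.random(n) < 0.5,
        taxi_frac=rng.random(n),
    )
    facilities = make_facilities(rng.integers(0, 30, size=m))
    base = rng.uniform(0.0, 120.0, size=(n, m))
    base[rng.random((n, m)) < 0.1] = np.inf  # some unreachable pairs
    return cells, facilities, make_od(cells, facilities, base)


def oracle_access(od: ODMatrix, cells: pd.DataFrame, facilities: pd.DataFrame, decay):
    """Direct triple-loop evaluation of the two-step model (independent of
    the vectorised implementation)."""
    modes = od.mode_names
    n, m = len(cells), len(facilities)
    ratios = []
    for j in range(m):
        denom = 0.0
        for k in range(n):
            d0 = decay.d0_urban if cells["is_urban"].iloc[k] else decay.d0_rural
            beta = decay.beta_urban if cells["is_urban"].iloc[k] else decay.beta_rural
            for mode in modes:
                d = od.times[mode][k, j]
                if d <= d0:
                    denom += (
                        cells["pop"].iloc[k]
                        * cells[f"{mode}_frac"].iloc[k]
                        * math.exp(-d * d / beta)
                    )
        s = float(facilities["staff"].iloc[j])
        ratios.append(s / denom if denom > 0 else 0.0)
    access = []
    for i in range(n):
        d0 = decay.d0_urban if cells["is_urban"].iloc[i] else decay.d0_rural
        beta = decay.beta_urban if cells["is_urban"].iloc[i] else decay.beta_rural
        a = 0.0
        for mode in modes:
            inner = 0.0
            for j in range(m):
                d = od.times[mode][i, j]
                if d <= d0:
                    inner += ratios[j] * math.exp(-d * d / beta)
            a += cells[f"{mode}_frac"].iloc[i] * inner
        access.append(a)
    return np.array(ratios), np.array(access)


def oracle_jenks_cost(values, k: int) -> float:
    """Best within-class sum of squares over every contiguous partition."""
    svals = np.sort(np.asarray(values, dtype=float))
    n = len(svals)
    k = min(k, len(np.unique(svals)))

    def ssd(seg):
        return float(np.sum((seg - seg.mean()) ** 2)) if len(seg) else 0.0

    if k == 1:
        return ssd(svals)
    best = math.inf
    for cuts in combinations(range(1, n), k - 1):
        edges = (0, *cuts, n)
        cost = sum(ssd(svals[a:b]) for a, b in zip(edges[:-1], edges[1:]))
        best = min(best, cost)
    return best


def oracle_all_pairs(g) -> dict:
    """Floyd–Warshall all-pairs shortest travel times (independent of
    networkx Dijkstra)."""
    nodes = list(g.nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v, data in g.edges(data=True):
        w = data["travel_time_min"]
        i, j = idx[u], idx[v]
        dist[i, j] = min(dist[i, j], w)
        dist[j, i] = min(dist[j, i], w)
    for k in range(n):
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    return {"nodes": nodes, "dist": dist, "idx": idx}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
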