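"""Multi-mode enhanced two-step floating catchment area (E2SFCA) model.

The access index combines three ingredients:

* a Gaussian distance-decay weight ``f(d) = exp(-d^2 / beta)`` truncated at a
  catchment threshold ``d0`` (40 min for urban demand, 90 min for rural
  demand), with ``beta`` calibrated so ``f(d0)`` equals a small ``epsilon``
  ("the value at which the curve approaches zero");
* a mode split: each cell's population divides into taxi and minibus
  subpopulations with mode-specific (penalised) travel times;
* the two-step construction: step 1 computes each facility's
  provider-to-population ratio ``R_j = S_j / sum_k sum_m P_{k,m} f_k(d_kj(m))``
  over the demand it can draw, step 2 sums the reachable ratios at each cell,
  ``A_i = sum_m (P_{i,m}/P_i) sum_j R_j f_i(d_ij(m))``.

Decay parameters are keyed to the demand cell's urban/rural class in both
steps, which makes the population-weighted access surface conserve supply
exactly: ``sum_i P_i A_i = sum_j S_j`` over facilities with nonzero demand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .jenks import jenks_labels
from .network import ODMatrix

#: Zone code for cells/clients outside every facility catchment.
OUTSIDE = 0


def calibrate_beta(d0: float, epsilon: float) -> float:
    """Impedance coefficient beta (min^2) with ``exp(-d0^2/beta) = epsilon``."""
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must lie strictly between 0 and 1")
    return d0 * d0 / math.log(1.0 / epsilon)


@dataclass(frozen=True)
class DecayParams:
    """Urban/rural Gaussian decay scales and catchment thresholds (minutes)."""

    beta_urban: float
    beta_rural: float
    d0_urban: float = 40.0
    d0_rural: float = 90.0
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        for beta, d0 in ((self.beta_urban, self.d0_urban), (self.beta_rural, self.d0_rural)):
            if beta <= 0 or d0 <= 0:
                raise ValueError("decay parameters must be positive")
            if abs(math.exp(-d0 * d0 / beta) - self.epsilon) > 1e-9:
                raise ValueError(
                    f"beta={beta} is not calibrated to epsilon={self.epsilon} at d0={d0}"
                )

    @classmethod
    def calibrated(
        cls, d0_urban: float = 40.0, d0_rural: float = 90.0, epsilon: float = 0.01
    ) -> "DecayParams":
        return cls(
            beta_urban=calibrate_beta(d0_urban, epsilon),
            beta_rural=calibrate_beta(d0_rural, epsilon),
            d0_urban=d0_urban,
            d0_rural=d0_rural,
            epsilon=epsilon,
        )


def decay_weight(d, beta: float, d0: float):
    """Truncated Gaussian decay: ``exp(-d^2/beta)`` for ``d <= d0``, else 0.

    Accepts scalars or arrays; ``+inf`` (unreachable) maps to 0.
    """
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0):
        raise ValueError("travel times must be non-negative")
    with np.errstate(over="ignore"):
        w = np.where(arr <= d0, np.exp(-np.square(arr) / beta), 0.0)
    if np.isscalar(d):
        return float(w)
    return w


def _aligned_cells(od: ODMatrix, cells: pd.DataFrame) -> pd.DataFrame:
    missing = set(od.demand_ids) - set(cells["cell_id"])
    if missing:
        raise ValueError(f"OD matrix covers cells absent from the demand table: {sorted(missing)[:5]}")
    return cells.set_index("cell_id").loc[list(od.demand_ids)].reset_index()

def _mode_weights(od: ODMatrix, cells: pd.DataFrame, decay: DecayParams) -> dict[str, np.ndarray]:
    """Per-mode (n_cells, n_facilities) decay weights, demand-side calibrated."""
    urban = cells["is_urban"].to_numpy(dtype=bool)
    beta = np.where(urban, decay.beta_urban, decay.beta_rural)[:, None]
    d0 = np.where(urban, decay.d0_urban, decay.d0_rural)[:, None]
    weights = {}
    for mode in od.mode_names:
        t = od.times[mode]
        with np.errstate(over="ignore", invalid="ignore"):
            w = np.where(t <= d0, np.exp(-np.square(t) / beta), 0.0)
        w[~np.isfinite(t)] = 0.0
        weights[mode] = w
    return weights


def _mode_fracs(cells: pd.DataFrame, mode_names: tuple[str, ...]) -> dict[str, np.ndarray]:
    fracs = {m: cells[f"{m}_frac"].to_numpy(dtype=float) for m in mode_names}
    total = sum(fracs.values())
    if np.any(np.abs(total - 1.0) > 1e-9):
        raise ValueError("per-cell mode fractions must sum to 1")
    return fracs


def supply_ratios(
    od: ODMatrix,
    cells: pd.DataFrame,
    facilities: pd.DataFrame,
    decay: DecayParams,
) -> pd.DataFrame:
    """Step 1: provider-to-population ratio R_j per facility.

    Returns a frame indexed like ``facilities`` with columns ``ratio`` and
    ``empty_catchment`` (True when no weighted demand reaches the facility,
    in which case the ratio is 0 rather than an error: an isolated facility
    is a legitimate scenario).
    """
    cells = _aligned_cells(od, cells)
    if list(facilities["facility_id"]) != list(od.facility_ids):
        facilities = facilities.set_index("facility_id").loc[list(od.facility_ids)].reset_index()
    weights = _mode_weights(od, cells, decay)
    fracs = _mode_fracs(cells, od.mode_names)
    pop = cells["pop"].to_numpy(dtype=float)
    denom = np.zeros(len(facilities))
    for mode in od.mode_names:
        denom += (pop * fracs[mode]) @ weights[mode]
    supply = facilities["staff"].to_numpy(dtype=float)
    empty = denom == 0.0
    ratio = np.zeros_like(denom)
    ratio[~empty] = supply[~empty] / denom[~empty]
    return pd.DataFrame(
        {
            "facility_id": facilities["facility_id"].to_numpy(),
            "staff": supply,
            "ratio": ratio,
            "empty_catchment": empty,
        }
    )


def access_index(
    od: ODMatrix,
    cells: pd.DataFrame,
    ratios: pd.DataFrame,
    decay: DecayParams,
) -> pd.DataFrame:
    """Step 2: access index A_i per cell (providers per person).

    ``ratios`` must come from :func:`supply_ratios` on the same OD matrix,
    cells and decay parameters.  Cells reaching no facility within their
    catchment get ``A_i = 0``.
    """
    cells = _aligned_cells(od, cells)
    if np.any(cells["pop"].to_numpy(dtype=float) <= 0):
        raise ValueError("cells with zero population must be excluded upstream")
    r = ratios.set_index("facility_id").loc[list(od.facility_ids), "ratio"].to_numpy(dtype=float)
    weights = _mode_weights(od, cells, decay)
    fracs = _mode_fracs(cells, od.mode_names)
    a = np.zeros(len(cells))
    for mode in od.mode_names:
        a += fracs[mode] * (weights[mode] @ r)
    out = cells.copy()
    out["access"] = a
    return out


def classify_zones(values, k: int = 6) -> np.ndarray:
    """Natural-breaks zone labels (1 = highest access) for positive values.

    With fewer than ``k`` distinct values the class count degrades to the
    number of distinct values.  Raises on empty input.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("cannot classify an empty access surface")
    if np.any(vals <= 0):
        raise ValueError("classify_zones expects strictly positive access values")
    return jenks_labels(vals, k, highest_is_one=True)


def build_access_surface(
    od: ODMatrix,
    cells: pd.DataFrame,
    facilities: pd.DataFrame,
    decay: DecayParams,
    n_zones: int = 6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run both steps and zone the surface.

    Returns ``(surface, ratios)`` where ``surface`` adds ``access`` and
    ``zone`` columns to the cell table.  Zone 1 is the highest-access class;
    cells with zero access are coded ``zone = 0`` ("outside" every
    catchment) and excluded from the natural-breaks classification.
    """
    ratios = supply_ratios(od, cells, facilities, decay)
    surface = access_index(od, cells, ratios, decay)
    zone = np.full(len(surface), OUTSIDE, dtype=int)
    pos = surface["access"].to_numpy() > 0
    if pos.any():
        zone[pos] = classify_zones(surface.loc[pos, "access"].to_numpy(), n_zones)
    surface["zone"] = zone
    return surface, ratios
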