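"""Decay calibration, the two-step index, and its structural invariants."""

import math

import numpy as np
import pandas as pd
import pytest

from mmfca.access import (
    DecayParams,
    access_index,
    build_access_surface,
    calibrate_beta,
    decay_weight,
    supply_ratios,
)

from conftest import make_cells, make_facilities, make_od, oracle_access, random_instance

DECAY = DecayParams.calibrated()


class TestCalibration:
    def test_urban_forty_minute_catchment(self):
        beta = calibrate_beta(40.0, 0.01)
        assert beta == pytest.approx(1600.0 / math.log(100.0))
        assert beta == pytest.approx(347.44, abs=0.01)

    def test_rural_ninety_minute_catchment(self):
        beta = calibrate_beta(90.0, 0.01)
        assert beta == pytest.approx(8100.0 / math.log(100.0))
        assert beta == pytest.approx(1758.9, abs=0.1)

    def test_epsilon_one_over_e_gives_beta_d0_squared(self):
        assert calibrate_beta(25.0, math.exp(-1.0)) == pytest.approx(625.0)

    @pytest.mark.parametrize("eps", [0.0, 1.0, 1.5, -0.2])
    def test_invalid_epsilon_rejected(self, eps):
        with pytest.raises(ValueError):
            calibrate_beta(40.0, eps)

    @pytest.mark.parametrize("d0", [40.0, 90.0])
    def test_calibration_identity(self, d0):
        beta = calibrate_beta(d0, 0.01)
        assert math.exp(-d0 * d0 / beta) == pytest.approx(0.01, abs=1e-9)


class TestDecayWeight:
    def test_zero_distance_weight_is_one(self):
        assert decay_weight(0.0, DECAY.beta_urban, DECAY.d0_urban) == 1.0

    def test_weight_at_threshold_equals_epsilon(self):
        w = decay_weight(40.0, DECAY.beta_urban, 40.0)
        assert w == pytest.approx(0.01, abs=1e-9)

    def test_hard_cutoff_beyond_threshold(self):
        assert decay_weight(41.0, DECAY.beta_urban, 40.0) == 0.0
        assert decay_weight(np.inf, DECAY.beta_urban, 40.0) == 0.0

    def test_strictly_decreasing_inside_catchment(self):
        d = np.linspace(0.0, 40.0, 200)
        w = decay_weight(d, DECAY.beta_urban, 40.0)
        assert np.all(np.diff(w) < 0)
        assert np.all((w >= 0) & (w <= 1))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            decay_weight(-1.0, DECAY.beta_urban, 40.0)


class TestSupplyRatios:
    def test_single_colocated_cell(self):
        """One facility with 2 staff at a 1000-person cell's node: R = 0.002."""
        cells = make_cells(1, [1000], [True], [0.8])
        fac = make_facilities([2])
        od = make_od(cells, fac, [[0.0]])
        od.times["minibus"][:] = 0.0  # both modes at the facility
        ratios = supply_ratios(od, cells, fac, DECAY)
        assert ratios["ratio"].iloc[0] == pytest.approx(0.002, rel=1e-12)
        assert not ratios["empty_catchment"].iloc[0]

    def test_cell_beyond_both_thresholds_flags_empty_catchment(self):
        cells = make_cells(1, [1000], [True], [0.8])
        fac = make_facilities([2])
        od = make_od(cells, fac, [[200.0]])
        ratios = supply_ratios(od, cells, fac, DECAY)
        assert ratios["ratio"].iloc[0] == 0.0
        assert bool(ratios["empty_catchment"].iloc[0])

    def test_hand_summed_denominator(self):
        """Weights 1 and 0.5 on two 500-person cells give R = S / 750."""
        cells = make_cells(2, [500, 500], [True, True], [0.6, 0.3])
        fac = make_facilities([3])
        d_half = math.sqrt(DECAY.beta_urban * math.log(2.0))  # f = 0.5
        base = np.array([[0.0], [d_half]])
        od = make_od(cells, fac, base)
        od.times["minibus"] = od.times["taxi"].copy()  # same weight for both modes
        ratios = supply_ratios(od, cells, fac, DECAY)
        assert ratios["ratio"].iloc[0] == pytest.approx(3.0 / 750.0, rel=1e-12)


class TestAccessIndex:
    def test_colocated_cell_recovers_ratio(self):
        cells = make_cells(1, [1000], [True], [0.8])
        fac = make_facilities([2])
        od = make_od(cells, fac, [[0.0]])
        od.times["minibus"][:] = 0.0
        ratios = supply_ratios(od, cells, fac, DECAY)
        out = access_index(od, cells, ratios, DECAY)
        assert out["access"].iloc[0] == pytest.approx(0.002, rel=1e-12)

    def test_mode_beyond_threshold_contributes_nothing(self):
        """Taxi at the facility, minibus pushed past the urban threshold:
        only the 80% taxi subpopulation accrues access."""
        cells = make_cells(1, [1000], [True], [0.8])
        fac = make_facilities([2])
        od = make_od(cells, fac, [[30.0]])  # minibus = 45 > 40
        ratios = supply_ratios(od, cells, fac, DECAY)
        out = access_index(od, cells, ratios, DECAY)
        f30 = math.exp(-900.0 / DECAY.beta_urban)
        r = 2.0 / (1000.0 * 0.8 * f30)
        assert out["access"].iloc[0] == pytest.approx(0.8 * r * f30, rel=1e-12)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(30):
            cells, fac, od = random_instance(rng)
            r_oracle, a_oracle = oracle_access(od, cells, fac, DECAY)
            ratios = supply_ratios(od, cells, fac, DECAY)
            out = access_index(od, cells, ratios, DECAY)
            np.testing.assert_allclose(ratios["ratio"].to_numpy(), r_oracle, atol=1e-12)
            np.testing.assert_allclose(out["access"].to_numpy(), a_oracle, atol=1e-12)

    def test_zero_population_cell_is_a_contract_violation(self):
        cells = make_cells(1, [0], [True], [0.8])
        fac = make_facilities([2])
        od = make_od(cells, fac, [[0.0]])
        ratios = supply_ratios(od, cells, fac, DECAY)
        with pytest.raises(ValueError):
            access_index(od, cells, ratios, DECAY)


class TestInvariants:
    def test_supply_conservation(self, rng):
        """Population-weighted access returns exactly the supply that found
        any demand: sum_i P_i A_i = sum_j S_j over non-empty catchments."""
        for _ in range(100):
            cells, fac, od = random_instance(rng)
            ratios = supply_ratios(od, cells, fac, DECAY)
            out = access_index(od, cells, ratios, DECAY)
            lhs = float((out["pop"] * out["access"]).sum())
            rhs = float(ratios.loc[~ratios["empty_catchment"], "staff"].sum())
            assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)

    def test_supply_monotonicity(self, rng):
        for _ in range(50):
            cells, fac, od = random_instance(rng)
            base = access_index(od, cells, supply_ratios(od, cells, fac, DECAY), DECAY)
            j = int(rng.integers(len(fac)))
            fac2 = fac.copy()
            fac2.loc[j, "staff"] += int(rng.integers(1, 10))
            bumped = access_index(od, cells, supply_ratios(od, cells, fac2, DECAY), DECAY)
            assert np.all(bumped["access"].to_numpy() >= base["access"].to_numpy() - 1e-15)

    def test_distance_monotonicity(self, rng):
        """Pushing one cell farther from one facility weakly lowers its own
        access and weakly raises everyone else's."""
        for _ in range(50):
            cells, fac, od = random_instance(rng)
            base = access_index(od, cells, supply_ratios(od, cells, fac, DECAY), DECAY)
            i = int(rng.integers(len(cells)))
            j = int(rng.integers(len(fac)))
            extra = float(rng.uniform(1.0, 60.0))
            for mode in od.mode_names:
                od.times[mode][i, j] += extra
            moved = access_index(od, cells, supply_ratios(od, cells, fac, DECAY), DECAY)
            a0, a1 = base["access"].to_numpy(), moved["access"].to_numpy()
            assert a1[i] <= a0[i] + 1e-15
            others = np.arange(len(cells)) != i
            assert np.all(a1[others] >= a0[others] - 1e-15)

    def test_rural_taxi_share_weakly_increases_access(self, rng):
        """The 15-min minibus penalty makes taxi weakly faster, so shifting a
        rural cell's split toward taxi cannot lower its access index."""
        for _ in range(50):
            cells, fac, od = random_instance(rng)
            rural = np.flatnonzero(~cells["is_urban"].to_numpy())
            if rural.size == 0:
                continue
            i = int(rng.choice(rural))
            base = access_index(od, cells, supply_ratios(od, cells, fac, DECAY), DECAY)
            cells2 = cells.copy()
            bump = float(rng.uniform(0.0, 1.0)) * (1.0 - float(cells2.loc[i, "taxi_frac"]))
            cells2.loc[i, "taxi_frac"] += bump
            cells2.loc[i, "minibus_frac"] -= bump
            shifted = access_index(od, cells2, supply_ratios(od, cells2, fac, DECAY), DECAY)
            assert shifted["access"].iloc[i] >= base["access"].iloc[i] - 1e-15

    def test_degenerate_reduction_to_classic_2sfca(self, rng):
        """One mode and a flat in-catchment weight reproduce the classic
        two-step ratio sum; the 1-cell/1-facility case returns S / P."""
        flat = DecayParams.calibrated(40.0, 90.0, epsilon=1.0 - 1e-12)
        for _ in range(30):
            cells, fac, od = random_instance(rng)
            cells = cells.assign(taxi_frac=1.0, minibus_frac=0.0)
            ratios = supply_ratios(od, cells, fac, flat)
            out = access_index(od, cells, ratios, flat)
            # classic 2SFCA oracle: indicator weights inside the catchment
            t = od.times["taxi"]
            d0 = np.where(cells["is_urban"], flat.d0_urban, flat.d0_rural)[:, None]
            within = t <= d0
            denom = (cells["pop"].to_numpy()[:, None] * within).sum(axis=0)
            r = np.where(denom > 0, fac["staff"].to_numpy() / np.where(denom > 0, denom, 1), 0.0)
            a = (within * r[None, :]).sum(axis=1)
            np.testing.assert_allclose(out["access"].to_numpy(), a, rtol=1e-6)

    def test_one_cell_one_facility_exact(self):
        cells = make_cells(1, [400], [False], [1.0])
        fac = make_facilities([7])
        od = make_od(cells, fac, [[0.0]])
        surface, ratios = build_access_surface(od, cells, fac, DECAY, n_zones=6)
        assert surface["access"].iloc[0] == 7.0 / 400.0  # single mode: exact
        assert surface["zone"].iloc[0] == 1
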