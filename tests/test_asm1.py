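"""Plant-model unit and property tests: kinetic saturation functions, the
Euler update, dilution-only closed form, steady state and the quality index."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from sludgesense.asm1 import (InfluentRecord, compute_rates, effluent_compliance,
                              simulate, steady_state, step, tcod,
                              read_trajectory, write_trajectory)
from sludgesense.config import KineticParams, PlantConfig, StoichParams

KIN = KineticParams()
STOICH = StoichParams()
PLANT = PlantConfig()

EPS = 1e-30          # effectively switches a rate constant off


def biology_off(kin: KineticParams = KIN) -> KineticParams:
    return replace(kin, mu_max_H=EPS, mu_max_A=EPS, k_h=EPS, b_H=EPS, b_A=EPS)


class TestComputeRates:
    def test_monod_half_saturation_point(self):
        state = [KIN.K_S, 50.0, 40.0, 1.7, 2.5]
        assert compute_rates(state, KIN)[0] == pytest.approx(0.5)

    def test_oxygen_switches_at_zero_oxygen(self):
        mus = compute_rates([100.0, 50.0, 40.0, 1.7, 0.0], KIN)
        assert mus[2] == 0.0          # aerobic switch off
        assert mus[3] == 1.0          # anoxic switch fully on

    def test_hydrolysis_half_saturation(self):
        # X2/X3 = K_X puts the hydrolysis saturation at exactly 1/2
        state = [100.0, KIN.K_X * 40.0, 40.0, 1.7, 2.5]
        assert compute_rates(state, KIN)[6] == pytest.approx(0.5)

    def test_rates_bounded_and_monotone(self, rng):
        states = np.column_stack([
            rng.uniform(0, 1000, 10_000), rng.uniform(0, 500, 10_000),
            rng.uniform(0, 200, 10_000), rng.uniform(0, 20, 10_000),
            rng.uniform(0, 8, 10_000)])
        rates = np.array([compute_rates(s, KIN) for s in states])
        assert (rates >= 0).all() and (rates <= 1).all()
        # saturation terms nondecreasing / oxygen-inhibition nonincreasing
        base = compute_rates([100.0, 50.0, 40.0, 1.7, 2.5], KIN)
        more_o2 = compute_rates([100.0, 50.0, 40.0, 1.7, 3.5], KIN)
        assert more_o2[2] >= base[2] and more_o2[4] >= base[4]
        assert more_o2[3] <= base[3]

    def test_nonfinite_state_rejected_with_field_name(self):
        with pytest.raises(ValueError, match="X2"):
            compute_rates([1.0, np.nan, 1.0, 1.0, 1.0], KIN)


class TestStep:
    def test_washout_fixed_point(self):
        # biology and aeration off, state equals influent: pure dilution
        # has nothing to change
        plant = replace(PLANT, kLa=EPS, r_recycle=1.0)
        state = np.array([100.0, 50.0, 20.0, 1.0, 2.0])
        inf = InfluentRecord(100.0, 50.0, 20.0, 1.0, 2.0, 0.05, 30.0)
        out = step(state, inf, biology_off(), STOICH, plant)
        np.testing.assert_allclose(out, state, rtol=1e-12)

    def test_dilution_only_closed_form(self):
        # X_k = X_in + (X_0 - X_in)(1 - Ts*D)^k for the linear map
        plant = replace(PLANT, kLa=EPS, r_recycle=1.0)
        D = 0.0625
        x0 = np.array([300.0, 100.0, 40.0, 1.5, 2.0])
        x_in = np.array([200.0, 60.0, 10.0, 0.5, 1.0])
        inf = InfluentRecord(*x_in, D, 30.0)
        x = x0.copy()
        kin = biology_off()
        for k in range(1, 1001):
            x = step(x, inf, kin, STOICH, plant)
            expected = x_in + (x0 - x_in) * (1.0 - plant.Ts * D) ** k
            np.testing.assert_allclose(x, expected, rtol=1e-9)

    def test_oxygen_rises_toward_saturation_without_biomass(self):
        state = np.array([100.0, 50.0, 0.0, 0.0, 1.0])
        inf = InfluentRecord(100.0, 50.0, 0.0, 0.0, 1.0, 0.0625, 30.0)
        x5 = state[4]
        x = state
        for _ in range(200):
            x = step(x, inf, KIN, STOICH, PLANT)
            assert x[4] > x5 or x[4] == PLANT.X5_max
            x5 = x[4]
        assert x5 <= PLANT.X5_max

    def test_negative_dilution_rejected(self):
        inf = InfluentRecord(1, 1, 1, 1, 1, -0.1, 30.0)
        with pytest.raises(ValueError, match="D_t"):
            step([1, 1, 1, 1, 1], inf, KIN, STOICH, PLANT)


class TestSimulate:
    def test_zero_steps_returns_initial_state_only(self):
        traj = simulate([1, 2, 3, 4, 5], [], KIN, STOICH, PLANT)
        assert len(traj) == 1
        np.testing.assert_allclose(
            traj[["X1", "X2", "X3", "X4", "X5"]].iloc[0], [1, 2, 3, 4, 5])

    def test_matches_iterated_step(self, shipped_config):
        """The fast inlined loop and the public one-step map must agree."""
        cfg = shipped_config
        inf = InfluentRecord(245.0, 45.0, 16.0, 0.74, 2.5, 0.0625, 30.0)
        records = [inf] * 50
        traj = simulate([290.0, 108.0, 40.0, 1.7, 2.5], records,
                        cfg.kinetics, cfg.stoichiometry, cfg.plant)
        x = np.array([290.0, 108.0, 40.0, 1.7, 2.5])
        for k in range(50):
            x = step(x, inf, cfg.kinetics, cfg.stoichiometry, cfg.plant)
        np.testing.assert_allclose(
            traj[["X1", "X2", "X3", "X4", "X5"]].iloc[-1], x, rtol=1e-12)

    def test_constant_influent_reaches_steady_state(self, shipped_config):
        cfg = shipped_config
        inf = InfluentRecord(245.0, 45.0, 16.0, 0.74, 2.5, 0.0625, 30.0)
        ss = steady_state(inf, cfg.kinetics, cfg.stoichiometry, cfg.plant,
                          tol=1e-10)
        traj = simulate(ss, [inf] * 200, cfg.kinetics, cfg.stoichiometry,
                        cfg.plant)
        states = traj[["X1", "X2", "X3", "X4", "X5"]].to_numpy()
        assert np.max(np.abs(np.diff(states, axis=0))) < 1e-8

    def test_trajectory_shape_and_time_grid(self, shipped_config):
        cfg = shipped_config
        from sludgesense.influent import generate_influent
        inf = generate_influent(cfg.influent, 99, cfg.plant.Ts, cfg.plant.Is)
        traj = simulate([290, 108, 40, 1.7, 2.5], inf, cfg.kinetics,
                        cfg.stoichiometry, cfg.plant)
        assert len(traj) == 100
        dt = np.diff(traj["time_h"])
        np.testing.assert_allclose(dt, cfg.plant.Ts, rtol=1e-12)
        # inert channel passes through unchanged, and TCOD honors it
        assert (traj["Is"] == cfg.plant.Is).all()
        np.testing.assert_allclose(
            traj["TCOD"], traj["X1"] + traj["X2"] + cfg.plant.Is)

    def test_csv_roundtrip(self, tmp_path, shipped_config):
        cfg = shipped_config
        inf = InfluentRecord(245.0, 45.0, 16.0, 0.74, 2.5, 0.0625, 30.0)
        traj = simulate([290, 108, 40, 1.7, 2.5], [inf] * 5, cfg.kinetics,
                        cfg.stoichiometry, cfg.plant)
        write_trajectory(traj, tmp_path / "t.csv")
        back = read_trajectory(tmp_path / "t.csv")
        pd.testing.assert_frame_equal(traj, back, check_exact=False,
                                      rtol=1e-12)


class TestTcod:
    def test_zero_substrate_gives_inert_only(self):
        assert tcod(0.0, 0.0, 30.0) == 30.0

    def test_reference_sum(self):
        assert tcod(290.82, 107.80, 30.0) == pytest.approx(428.62)

    def test_commutative_in_substrates(self, rng):
        a, b = rng.uniform(0, 300, 50), rng.uniform(0, 150, 50)
        np.testing.assert_allclose(tcod(a, b, 30.0), tcod(b, a, 30.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            tcod(-1.0, 0.0, 30.0)


class TestCompliance:
    def test_all_below_limit(self):
        frac, flags = effluent_compliance([10, 20, 30], 150.0)
        assert frac == 1.0 and flags.all()

    def test_half_compliant(self):
        frac, flags = effluent_compliance([100.0, 200.0], 150.0)
        assert frac == 0.5
        assert flags.tolist() == [True, False]

    def test_monotone_in_limit(self, rng):
        for _ in range(100):
            series = rng.uniform(0, 400, 50)
            limits = np.sort(rng.uniform(0, 400, 5))
            fracs = [effluent_compliance(series, c)[0] for c in limits]
            assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            effluent_compliance([], 150.0)


class TestSteadyState:
    def test_dilution_only_fixed_point_is_influent(self):
        plant = replace(PLANT, kLa=EPS, r_recycle=1.0)
        inf = InfluentRecord(200.0, 60.0, 10.0, 0.5, 1.0, 0.0625, 30.0)
        ss = steady_state(inf, biology_off(), STOICH, plant, tol=1e-12)
        np.testing.assert_allclose(ss, [200.0, 60.0, 10.0, 0.5, 1.0],
                                   atol=1e-9)

    def test_residual_below_tolerance(self, shipped_config):
        cfg = shipped_config
        inf = InfluentRecord(245.0, 45.0, 16.0, 0.74, 2.5, 0.0625, 30.0)
        tol = 1e-9
        ss = steady_state(inf, cfg.kinetics, cfg.stoichiometry, cfg.plant,
                          tol=tol)
        nxt = step(ss, inf, cfg.kinetics, cfg.stoichiometry, cfg.plant)
        assert np.max(np.abs(nxt - ss)) < tol

    def test_agrees_with_long_simulation(self, shipped_config):
        # two independent routes to the fixed point; a once-through settler
        # (r_recycle = 1) keeps every relaxation mode fast enough that the
        # long simulation actually arrives
        cfg = shipped_config
        plant = replace(cfg.plant, r_recycle=1.0)
        inf = InfluentRecord(245.0, 45.0, 16.0, 0.74, 2.5, 0.0625, 30.0)
        tol = 1e-10
        ss = steady_state(inf, cfg.kinetics, cfg.stoichiometry, plant,
                          tol=tol)
        traj = simulate([290, 108, 40, 1.7, 2.5], [inf] * 60_000,
                        cfg.kinetics, cfg.stoichiometry, plant)
        terminal = traj[["X1", "X2", "X3", "X4", "X5"]].iloc[-1].to_numpy()
        # a per-step-change stopping rule leaves the iterate within about
        # tol / (Ts * p) of the fixed point (p ~ D is the slowest relaxation
        # rate here), i.e. ~6e-8; the two routes must agree at that scale
        assert np.max(np.abs(terminal - ss)) < 10 * tol / (plant.Ts * 0.0625)
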