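"""DFBA engine: stepping schemes, conservation, fed-batch, and metrics."""

import numpy as np
import pandas as pd
import pytest

from dfba_pdo.simulate import (CultureState, FeedPolicy, RegimeSwitchError,
                               SimulationSpec, Trajectory, excess_batch_spec,
                               limited_batch_spec, simulate, simulate_da,
                               simulate_doa, simulate_fedbatch, simulate_soa,
                               trajectory_metrics)
from dfba_pdo.units import g_per_l_to_mm

_CARBONS = {"glycerol": 3, "pdo": 3, "acetate": 2, "butyrate": 4,
            "lactate": 3, "ethanol": 2, "butanol": 4, "co2": 1, "h2": 0}


def _total_carbon(row: pd.Series, c_x: float) -> float:
    """mmol carbon per litre in solutes plus viable biomass."""
    tot = sum(g_per_l_to_mm(row[s], s) * c for s, c in _CARBONS.items())
    return tot + row["X"] * c_x


class TestSoa:
    def test_no_biomass_means_no_change(self, network):
        spec = limited_batch_spec(network, initial=CultureState(X=0.0, z={"glycerol": 10.0}),
                                  n_intervals=20)
        traj = simulate_soa(spec)
        st = traj.states
        assert st["glycerol"].nunique() == 1
        assert st["pdo"].max() == 0.0
        assert st["X"].max() == 0.0

    def test_starvation_decay_at_limitation_death_rate(self, network, kinetics):
        spec = limited_batch_spec(network, initial=CultureState(X=0.5, z={"glycerol": 0.0}),
                                  tf=10.0, n_intervals=200)
        traj = simulate_soa(spec)
        st = traj.states
        assert st["glycerol"].max() == 0.0
        assert st["pdo"].max() == 0.0
        # Euler decay at kd_lim: X = X0 (1 - kd dt)^n
        n = len(st) - 1
        dt = traj.metadata["dt"]
        expected = 0.5 * (1.0 - kinetics.kd_lim * dt) ** n
        assert st["X"].iloc[-1] == pytest.approx(expected, rel=1e-9)

    def test_short_horizon_matches_exponential_growth(self, network):
        # without depletion the growth rate is constant and X is exponential
        spec = excess_batch_spec(network, tf=0.5, n_intervals=500)
        traj = simulate_soa(spec)
        mu_eff = traj.states["mu"].iloc[0] - traj.states["kd"].iloc[0]
        expected = 0.1 * np.exp(mu_eff * 0.5)
        assert traj.states["X"].iloc[-1] == pytest.approx(expected, rel=2e-3)

    def test_glycerol_never_negative_and_growth_stops_after_exhaustion(self, network):
        spec = excess_batch_spec(network, tf=24.0, n_intervals=100)
        traj = simulate_soa(spec)
        st = traj.states
        assert st["glycerol"].min() >= 0.0
        exhausted = st[st["glycerol"] < 1e-3]   # Monod tail: asymptotic decay
        assert len(exhausted) > 3            # the culture does exhaust
        assert np.all(np.diff(exhausted["X"]) <= 1e-12)  # decay only

    def test_per_step_carbon_conservation(self, network):
        spec = excess_batch_spec(network, tf=16.0, n_intervals=64)
        traj = simulate_soa(spec)
        st = traj.states
        c_x = network.composition.carbon_content()
        dt = traj.metadata["dt"]
        dead = 0.0
        c0 = _total_carbon(st.iloc[0], c_x)
        for i in range(1, len(st)):
            dead += st["kd"].iloc[i - 1] * st["X"].iloc[i - 1] * dt
            ci = _total_carbon(st.iloc[i], c_x) + dead * c_x
            assert ci == pytest.approx(c0, rel=1e-6)


class TestDa:
    def test_final_state_close_to_fine_soa(self, network):
        spec = excess_batch_spec(network, tf=18.0)
        da = simulate_da(spec)
        spec_fine = excess_batch_spec(network, tf=18.0, n_intervals=1500)
        soa = simulate_soa(spec_fine)
        for col in ("X", "glycerol", "pdo", "butyrate"):
            a, b = da.states[col].iloc[-1], soa.states[col].iloc[-1]
            assert a == pytest.approx(b, rel=0.01, abs=0.02), col

    def test_zero_initial_glycerol_gives_zero_pdo(self, network):
        spec = excess_batch_spec(network, initial=CultureState(X=0.1, z={"glycerol": 0.0}),
                                 tf=5.0)
        traj = simulate_da(spec)
        assert traj.states["pdo"].max() == 0.0

    def test_time_grid_and_monotone_time(self, network):
        spec = excess_batch_spec(network, tf=12.0, n_intervals=48)
        traj = simulate_da(spec)
        assert np.all(np.diff(traj.states["t"]) > 0)
        assert traj.states["t"].iloc[-1] == pytest.approx(12.0)


class TestDoa:
    def test_regime_switch_inside_horizon_is_refused(self, network):
        # 40 g/L initial glycerol falls through 15 g/L within 24 h
        spec = excess_batch_spec(network, approach="DOA", tf=24.0)
        with pytest.raises(RegimeSwitchError, match="change of objective"):
            simulate_doa(spec)

    def test_collocation_matches_adaptive_integrator_on_frozen_dynamics(self, network):
        # X tiny: depletion is negligible, growth is a pure linear ODE
        spec = limited_batch_spec(network, initial=CultureState(X=1e-6, z={"glycerol": 10.0}),
                                  tf=2.0, doa_elements=4)
        doa = simulate_doa(spec)
        mu_eff = doa.states["mu"].iloc[0] - doa.states["kd"].iloc[0]
        expected = 1e-6 * np.exp(mu_eff * 2.0)
        assert doa.states["X"].iloc[-1] == pytest.approx(expected, rel=1e-4)

    def test_three_approaches_agree_on_limited_scenario(self, network):
        specs = {
            "DOA": limited_batch_spec(network, approach="DOA"),
            "SOA": limited_batch_spec(network, approach="SOA", n_intervals=400),
            "DA": limited_batch_spec(network, approach="DA"),
        }
        finals = {}
        for name, spec in specs.items():
            finals[name] = simulate(spec).states["pdo"].iloc[-1]
        spread = max(finals.values()) - min(finals.values())
        assert spread <= 0.07, finals


class TestFedBatch:
    def test_zero_feed_reduces_to_batch(self, network):
        feed = FeedPolicy(mode="constant", alpha=0.0)
        spec = excess_batch_spec(network, tf=12.0, n_intervals=120, feed=feed)
        fb = simulate_fedbatch(spec)
        batch = simulate_soa(excess_batch_spec(network, tf=12.0, n_intervals=120))
        for col in ("X", "glycerol", "pdo"):
            assert fb.states[col].iloc[-1] == pytest.approx(
                batch.states[col].iloc[-1], rel=1e-9)
        assert fb.states["V"].nunique() == 1

    def test_volume_non_decreasing_and_capped(self, network):
        feed = FeedPolicy.glycerol_feed("constant", 0.05, 50.0, v_max=1.5)
        spec = excess_batch_spec(network, tf=30.0, n_intervals=300, feed=feed)
        traj = simulate_fedbatch(spec)
        v = traj.states["V"].to_numpy()
        assert np.all(np.diff(v) >= -1e-12)
        assert v[0] == 1.0 and v.max() <= 1.5 + 1e-9

    def test_glycerol_mass_balance(self, network):
        feed = FeedPolicy.glycerol_feed("constant", 0.02, 40.0)
        spec = excess_batch_spec(network, tf=20.0, n_intervals=200, feed=feed)
        traj = simulate_fedbatch(spec)
        m = trajectory_metrics(traj)
        st = traj.states
        residual = st["glycerol"].iloc[-1] * st["V"].iloc[-1]
        initial = st["glycerol"].iloc[0] * st["V"].iloc[0]
        assert initial + m["glycerol_fed_g"] - residual == pytest.approx(
            m["glycerol_consumed_g"], rel=1e-9)

    def test_ph_coupled_feed_grows_volume_with_activity(self, network):
        feed = FeedPolicy.glycerol_feed("ph_coupled", 5e-4, 40.0)
        spec = excess_batch_spec(network, tf=30.0, n_intervals=300, feed=feed)
        traj = simulate_fedbatch(spec)
        assert traj.states["V"].iloc[-1] > 1.0
        assert "F" in traj.states.columns


class TestMetrics:
    def _synthetic_traj(self, rows):
        states = pd.DataFrame(rows)
        return Trajectory(states, pd.DataFrame({"t": states["t"]}), {})

    def test_simple_arithmetic(self):
        rows = [
            {"t": 0.0, "V": 1.0, "X": 0.1, "glycerol": 20.0, "pdo": 0.0},
            {"t": 10.0, "V": 1.0, "X": 1.0, "glycerol": 0.0, "pdo": 10.0},
        ]
        m = trajectory_metrics(self._synthetic_traj(rows))
        assert m["q_pdo"] == pytest.approx(1.0)
        assert m["final_pdo"] == 10.0
        assert m["y_pdo_mass"] == pytest.approx(0.5)
        assert m["y_pdo_mol"] == pytest.approx(0.5 * 92.09 / 76.09)

    def test_zero_pdo_trajectory(self):
        rows = [
            {"t": 0.0, "V": 1.0, "X": 0.1, "glycerol": 20.0, "pdo": 0.0},
            {"t": 5.0, "V": 1.0, "X": 0.1, "glycerol": 18.0, "pdo": 0.0},
        ]
        m = trajectory_metrics(self._synthetic_traj(rows))
        assert m["q_pdo"] == 0.0
        assert m["y_pdo_mass"] == 0.0

    def test_zero_consumption_flags_undefined_yield(self):
        rows = [
            {"t": 0.0, "V": 1.0, "X": 0.0, "glycerol": 20.0, "pdo": 0.0},
            {"t": 5.0, "V": 1.0, "X": 0.0, "glycerol": 20.0, "pdo": 0.0},
        ]
        m = trajectory_metrics(self._synthetic_traj(rows))
        assert m["yield_defined"] is False

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            trajectory_metrics(Trajectory(pd.DataFrame(), pd.DataFrame(), {}))


def test_csv_roundtrip(tmp_path, network):
    spec = limited_batch_spec(network, n_intervals=10, tf=2.0, approach="SOA")
    traj = simulate(spec)
    p1, p2 = tmp_path / "states.csv", tmp_path / "fluxes.csv"
    traj.to_csv(str(p1), str(p2))
    back = pd.read_csv(p1)
    pd.testing.assert_frame_equal(back, traj.states, check_exact=False)
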