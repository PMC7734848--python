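"""SSA and tau-leap backends against closed-form expectations."""

import numpy as np
import pytest

from ms_essn.essn import (EventSchedule, Marking, ModelError, SimulationError,
                          compile_net, ssa_simulate, tau_leap_simulate)
from ms_essn.essn.simulate import ensemble_summary, ssa_ensemble


def _endpoint_ensemble(model, m0, t_end, n, simulate, **kw):
    net = compile_net(model)
    return np.array([simulate(net, m0, t_end, seed=s, record_grid=[t_end],
                              **kw).states[0, 0] for s in range(n)])


class TestSSA:
    def test_linear_death_matches_analytic_mean(self, death_model):
        """E[X(1)] = 100 exp(-1) for a unit-rate death process."""
        vals = _endpoint_ensemble(death_model, Marking({"X": 100}), 1.0,
                                  1000, ssa_simulate)
        expected = 100 * np.exp(-1.0)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - expected) < 3 * se

    def test_immigration_death_stationary_mean(self, imdeath_model):
        """Long-run mean is lambda/mu = 10."""
        net = compile_net(imdeath_model)
        vals = []
        for s in range(300):
            tr = ssa_simulate(net, Marking({"X": 0}), 40.0, seed=s,
                              record_grid=[20.0, 30.0, 40.0])
            vals.extend(tr.states[:, 0])
        assert np.mean(vals) == pytest.approx(10.0, abs=0.5)

    def test_zero_propensity_state_constant(self, death_model):
        tr = ssa_simulate(death_model, Marking({"X": 0}), 5.0, seed=1,
                          record_grid=np.linspace(0, 5, 6))
        assert (tr.states == 0).all()

    def test_seed_determinism_is_bitwise(self, imdeath_model):
        grid = np.linspace(0, 5, 11)
        a = ssa_simulate(imdeath_model, Marking({"X": 0}), 5.0, seed=7,
                         record_grid=grid)
        b = ssa_simulate(imdeath_model, Marking({"X": 0}), 5.0, seed=7,
                         record_grid=grid)
        assert np.array_equal(a.states, b.states)
        c = ssa_simulate(imdeath_model, Marking({"X": 0}), 5.0, seed=8,
                         record_grid=grid)
        assert not np.array_equal(a.states, c.states)

    def test_events_applied_exactly(self, death_model):
        """+100 tokens at t=2 on a dead system: the jump is sharp."""
        ev = EventSchedule([(2.0, "X", 100)])
        tr = ssa_simulate(death_model, Marking({"X": 0}), 3.0, events=ev,
                          seed=0, record_grid=[1.999, 2.0, 3.0])
        assert tr.states[0, 0] == 0
        assert tr.states[1, 0] == 100  # grid point at the event time
        assert tr.states[2, 0] < 100   # death resumed afterwards

    def test_negative_event_raises_schedule_error(self, death_model):
        ev = EventSchedule([(1.0, "X", -5)])
        with pytest.raises(SimulationError):
            ssa_simulate(death_model, Marking({"X": 0}), 2.0, events=ev,
                         seed=0)

    def test_nonpositive_horizon_rejected(self, death_model):
        with pytest.raises(ModelError):
            ssa_simulate(death_model, Marking({"X": 1}), 0.0)

    def test_no_trajectory_reports_negative_counts(self, imdeath_model):
        for tr in ssa_ensemble(imdeath_model, Marking({"X": 3}), 10.0,
                               seeds=range(20)):
            assert (tr.states >= 0).all()


class TestTauLeap:
    def test_converges_to_analytic_death_mean(self, death_model):
        vals = _endpoint_ensemble(death_model, Marking({"X": 100}), 1.0,
                                  400, tau_leap_simulate, tau=0.01)
        expected = 100 * np.exp(-1.0)
        assert abs(vals.mean() - expected) / expected < 0.05

    def test_zero_propensity_identical_to_ssa(self, death_model):
        grid = np.linspace(0, 5, 6)
        a = ssa_simulate(death_model, Marking({"X": 0}), 5.0, seed=3,
                         record_grid=grid)
        b = tau_leap_simulate(death_model, Marking({"X": 0}), 5.0, seed=3,
                              record_grid=grid, tau=0.5)
        assert np.array_equal(a.states, b.states)

    def test_leap_truncated_at_event_boundary(self, death_model):
        """An event inside a leap window is still applied at its exact time."""
        ev = EventSchedule([(2.5, "X", 50)])
        tr = tau_leap_simulate(death_model, Marking({"X": 0}), 4.0, events=ev,
                               seed=0, record_grid=[2.4999, 2.5, 4.0], tau=1.0)
        assert tr.states[0, 0] == 0
        assert tr.states[1, 0] == 50

    def test_nonpositive_tau_rejected(self, death_model):
        with pytest.raises(ModelError):
            tau_leap_simulate(death_model, Marking({"X": 1}), 1.0, tau=0.0)

    def test_counts_never_negative(self, death_model):
        # coarse tau forces the negativity-halving policy to engage
        for s in range(30):
            tr = tau_leap_simulate(death_model, Marking({"X": 5}), 2.0,
                                   seed=s, record_grid=np.linspace(0, 2, 21),
                                   tau=1.0)
            assert (tr.states >= 0).all()


class TestTrajectoryOutput:
    def test_frame_and_csv_round_trip(self, imdeath_model, tmp_path):
        import pandas as pd

        tr = ssa_simulate(imdeath_model, Marking({"X": 0}), 3.0, seed=1,
                          record_grid=np.linspace(0, 3, 7))
        path = tmp_path / "traj.csv"
        tr.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["time", "X"]
        assert np.array_equal(df["X"].to_numpy(), tr.states[:, 0])

    def test_ensemble_summary_shape(self, imdeath_model):
        trs = ssa_ensemble(imdeath_model, Marking({"X": 0}), 3.0,
                           seeds=range(10), record_grid=np.linspace(0, 3, 4))
        s = ensemble_summary(trs)
        assert set(s.columns) == {"time", "variable", "mean", "median",
                                  "q25", "q75"}
        assert len(s) == 4
        assert (s["q25"] <= s["q75"]).all()
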