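"""Equilibration, death-event detection, censoring, population runs."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tnfpop as tp
from tnfpop.simulate import (
    CellFate,
    SolverSettings,
    Trajectory,
    viability_curve,
)


class TestEquilibrate:
    def test_pure_source_model_has_no_steady_state(self, toy_timer):
        with pytest.raises(tp.EquilibrationError):
            tp.equilibrate(toy_timer)

    def test_resting_state_has_no_death_marker_activity(
        self, receptor_model, receptor_resting_state
    ):
        state = dict(zip(receptor_model.species_ids, receptor_resting_state))
        assert state["C"] == pytest.approx(0.0, abs=1e-9)
        assert state["X"] == pytest.approx(0.0, abs=1e-9)
        assert state["Inh"] == pytest.approx(1.0, rel=1e-6)

    def test_steady_state_persists_unstimulated(self, receptor_model, receptor_resting_state):
        proto = tp.StimulusProtocol(0.0, horizon_hours=100.0)
        traj, fate = tp.simulate_cell(
            receptor_model, None, proto, initial_state=receptor_resting_state.copy()
        )
        assert not fate.died
        drift = np.abs(traj.y - receptor_resting_state[:, None]).max()
        assert drift < 1e-6

    def test_multiplier_covariant_closed_form(self, receptor_model):
        """For the protector's production-degradation pair, Inh* = m·k_i/d_i."""
        cell = tp.CellParameterSet({"k_i": 1.7})
        state = tp.equilibrate(receptor_model, cell)
        inh = state[receptor_model.species_index("Inh")]
        assert inh == pytest.approx(1.7 * 1.0 / 1.0, rel=1e-6)

    def test_activated_death_marker_at_rest_is_rejected(self, receptor_model):
        # force a resting state with death-marker activity: constitutive
        # production of X not balanced by the protector
        net = receptor_model.copy()
        net.reaction("prod_X").rate_law = "k_x*(C + 0.5)"
        with pytest.raises(tp.EquilibrationError, match="activated"):
            tp.equilibrate(net)


class TestDeathDetection:
    def test_event_bracketing(self, receptor_model, receptor_resting_state):
        """Death marker is below threshold just before ToD and at it after."""
        proto = tp.StimulusProtocol(10.0, horizon_hours=100.0)
        traj, fate = tp.simulate_cell(
            receptor_model, None, proto, initial_state=receptor_resting_state.copy()
        )
        assert fate.died
        theta = receptor_model.metadata["death_readout"]["threshold"]
        x_before = np.interp(fate.time_of_death_h - 0.01, traj.t, traj.species("X"))
        x_at = np.interp(fate.time_of_death_h, traj.t, traj.species("X"))
        assert x_before < theta
        assert x_at >= theta - 1e-6

    def test_tolerance_tightening_stability(self, receptor_model):
        """10× tighter solver tolerances move no ToD by more than 0.05 h."""
        spec = tp.EnsembleSpec(n_cells=10, sigma=0.148, seed=17, distributed_ids=("k_x", "k_i"))
        population = tp.sample_population(spec)
        proto = tp.StimulusProtocol(10.0, horizon_hours=100.0)
        default = SolverSettings()
        tight = default.tightened(10.0)
        for cell in population:
            _, f1 = tp.simulate_cell(receptor_model, cell, proto, default)
            _, f2 = tp.simulate_cell(receptor_model, cell, proto, tight)
            assert f1.died and f2.died
            assert abs(f1.time_of_death_h - f2.time_of_death_h) < 0.05

    def test_censoring_consistency(self, receptor_model, receptor_resting_state):
        """Extending the horizon never changes an already-found death time."""
        proto_short = tp.StimulusProtocol(10.0, horizon_hours=50.0)
        proto_long = tp.StimulusProtocol(10.0, horizon_hours=150.0)
        _, f_short = tp.simulate_cell(
            receptor_model, None, proto_short, initial_state=receptor_resting_state.copy()
        )
        _, f_long = tp.simulate_cell(
            receptor_model, None, proto_long, initial_state=receptor_resting_state.copy()
        )
        assert f_short.died and f_long.died
        assert f_long.time_of_death_h == pytest.approx(
            f_short.time_of_death_h, abs=1e-6
        )

    def test_survivor_censored_at_horizon(self, receptor_model, receptor_resting_state):
        proto = tp.StimulusProtocol(1.0, horizon_hours=100.0)  # below death threshold
        _, fate = tp.simulate_cell(
            receptor_model, None, proto, initial_state=receptor_resting_state.copy()
        )
        assert fate.status == "survived"
        assert fate.time_of_death_h is None


class TestCellFate:
    def test_died_requires_valid_time(self):
        with pytest.raises(ValueError):
            CellFate("died", None, 100.0)
        with pytest.raises(ValueError):
            CellFate("died", 101.0, 100.0)

    def test_survived_has_no_time(self):
        with pytest.raises(ValueError):
            CellFate("survived", 5.0, 100.0)


class TestPopulation:
    def test_single_cell_population_matches_simulate_cell(self, toy_timer, no_stimulus):
        cell = tp.CellParameterSet({"k_x": 1.3})
        result = tp.simulate_population(toy_timer, [cell], no_stimulus)
        _, fate = tp.simulate_cell(toy_timer, cell, no_stimulus)
        assert result.fates[0].time_of_death_h == pytest.approx(fate.time_of_death_h)
        assert result.kept_indices == [0]

    def test_zero_dose_population_all_survive(self, receptor_model):
        spec = tp.EnsembleSpec(n_cells=5, sigma=0.148, seed=1, distributed_ids=("k_x", "k_i"))
        pop = tp.sample_population(spec)
        result = tp.simulate_population(
            receptor_model, pop, tp.StimulusProtocol(0.0, horizon_hours=50.0)
        )
        assert all(not f.died for f in result.fates)

    def test_paired_dose_monotonicity_of_viability(self, receptor_model):
        """For the same cells, a higher continuous dose never improves viability."""
        spec = tp.EnsembleSpec(n_cells=60, sigma=0.148, seed=23, distributed_ids=("k_x", "k_i"))
        pop = tp.sample_population(spec)
        states = [tp.equilibrate(receptor_model, c) for c in pop]
        grid = np.linspace(0, 100, 21)
        curves = {}
        for dose in (1.0, 30.0):
            result = tp.simulate_population(
                receptor_model,
                pop,
                tp.StimulusProtocol(dose, horizon_hours=100.0),
                initial_states=states,
            )
            curves[dose] = viability_curve(result.fates, grid)
        assert (curves[30.0] <= curves[1.0] + 1e-12).all()

    def test_empty_population_rejected(self, toy_timer, no_stimulus):
        with pytest.raises(ValueError):
            tp.simulate_population(toy_timer, [], no_stimulus)


class TestViabilityCurve:
    def test_counting_example(self):
        fates = [
            CellFate("died", 2.0, 100.0),
            CellFate("died", 4.0, 100.0),
            CellFate("survived", None, 100.0),
            CellFate("survived", None, 100.0),
        ]
        np.testing.assert_allclose(
            viability_curve(fates, [1.0, 3.0, 5.0]), [1.0, 0.75, 0.5]
        )

    def test_all_survivors_unit_viability(self):
        fates = [CellFate("survived", None, 100.0)] * 4
        np.testing.assert_array_equal(viability_curve(fates, [0, 50, 100]), 1.0)

    @given(
        tods=st.lists(
            st.one_of(st.none(), st.floats(0.1, 99.0)), min_size=1, max_size=40
        )
    )
    def test_non_increasing_and_starts_at_one(self, tods):
        fates = [
            CellFate("survived", None, 100.0)
            if t is None
            else CellFate("died", t, 100.0)
            for t in tods
        ]
        grid = np.linspace(0, 100, 41)
        v = viability_curve(fates, grid)
        assert v[0] == 1.0
        assert (np.diff(v) <= 1e-12).all()


class TestNormalizeTrajectory:
    def _traj(self, values):
        arr = np.asarray(values, dtype=float)
        return Trajectory(
            t=np.arange(len(arr), dtype=float),
            y=arr[None, :],
            species_order=["S"],
        )

    def test_constant_positive_course_is_all_ones(self):
        np.testing.assert_array_equal(
            tp.normalize_trajectory(self._traj([3, 3, 3]), "S"), [1, 1, 1]
        )

    def test_simple_course(self):
        np.testing.assert_allclose(
            tp.normalize_trajectory(self._traj([0, 2, 4]), "S"), [0, 0.5, 1]
        )

    def test_all_zero_course_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            out = tp.normalize_trajectory(self._traj([0, 0, 0]), "S")
        np.testing.assert_array_equal(out, 0.0)

    def test_pulse_leaves_lower_late_death_marker_than_continuous(
        self, receptor_model, receptor_resting_state
    ):
        """After washout the driving complex decays, so the normalized death
        marker settles lower than under continuous stimulation."""
        courses = {}
        for mode in ("continuous", "pulse"):
            proto = tp.StimulusProtocol(1.0, mode, horizon_hours=16.0)
            traj, _ = tp.simulate_cell(
                receptor_model, None, proto, initial_state=receptor_resting_state.copy()
            )
            rel = tp.normalize_trajectory(traj, "X")
            courses[mode] = np.interp(16.0, traj.t, rel)
        assert courses["pulse"] < courses["continuous"]
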