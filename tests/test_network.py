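"""Model core: SBML I/O, production-rate identification, knockouts, RHS."""

import numpy as np
import pytest

import tnfpop as tp
from tnfpop.network import Reaction, ReactionNetwork, Species, build_rhs


class TestLoadSBML:
    def test_minimal_model(self, minimal_sbml):
        net = tp.load_sbml(minimal_sbml)
        assert net.species_ids == ["A"]
        assert [r.id for r in net.reactions] == ["synth"]
        assert net.parameters == {"k_syn": 2.0}
        assert net.production_rate_ids == ["k_syn"]

    def test_round_trip_preserves_structure(self, receptor_model, tmp_path):
        path = tmp_path / "receptor.xml"
        tp.write_sbml(receptor_model, path)
        reloaded = tp.load_sbml(path)
        assert reloaded.parameters == receptor_model.parameters
        assert reloaded.species_ids == receptor_model.species_ids
        for orig, back in zip(receptor_model.reactions, reloaded.reactions):
            assert (orig.reactants, orig.products) == (back.reactants, back.products)
        assert reloaded.production_rate_ids == receptor_model.production_rate_ids
        assert reloaded.metadata == receptor_model.metadata

    def test_round_trip_preserves_rate_semantics(self, receptor_model, tmp_path, rng):
        path = tmp_path / "receptor.xml"
        tp.write_sbml(receptor_model, path)
        reloaded = tp.load_sbml(path)
        f1 = build_rhs(receptor_model)
        f2 = build_rhs(reloaded)
        for _ in range(5):
            y = rng.uniform(0.0, 2.0, size=len(receptor_model.species))
            np.testing.assert_allclose(f1(0.0, y), f2(0.0, y), rtol=1e-12)

    def test_malformed_xml_names_problem(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<sbml level='2'><model><unclosed></model>")
        with pytest.raises(tp.SBMLParseError):
            tp.load_sbml(bad)

    def test_missing_kinetic_law_is_parse_error(self, tmp_path, minimal_sbml):
        text = minimal_sbml.read_text()
        start = text.index("<kineticLaw>")
        end = text.index("</kineticLaw>") + len("</kineticLaw>")
        stripped = tmp_path / "nokl.xml"
        stripped.write_text(text[:start] + text[end:])
        with pytest.raises(tp.SBMLParseError, match="synth"):
            tp.load_sbml(stripped)

    def test_events_are_rejected_not_ignored(self, tmp_path, minimal_sbml):
        text = minimal_sbml.read_text().replace(
            "<listOfReactions>",
            "<listOfEvents><event id='e1'/></listOfEvents><listOfReactions>",
        )
        path = tmp_path / "events.xml"
        path.write_text(text)
        with pytest.raises(tp.UnsupportedSBMLError, match="events"):
            tp.load_sbml(path)

    def test_level_3_rejected(self, tmp_path, minimal_sbml):
        path = tmp_path / "l3.xml"
        path.write_text(minimal_sbml.read_text().replace('level="2"', 'level="3"'))
        with pytest.raises(tp.UnsupportedSBMLError, match="level"):
            tp.load_sbml(path)

    def test_fractional_stoichiometry_rejected(self, tmp_path, minimal_sbml):
        path = tmp_path / "frac.xml"
        path.write_text(
            minimal_sbml.read_text().replace('stoichiometry="1"', 'stoichiometry="1.5"')
        )
        with pytest.raises(tp.SBMLParseError, match="stoichiometry"):
            tp.load_sbml(path)

    def test_against_libsbml_oracle(self, tmp_path, receptor_model):
        """Cross-check structure against the reference SBML library, if present."""
        libsbml = pytest.importorskip("libsbml")
        path = tmp_path / "receptor.xml"
        tp.write_sbml(receptor_model, path)
        doc = libsbml.readSBML(str(path))
        assert doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) == 0
        model = doc.getModel()
        assert model.getNumSpecies() == len(receptor_model.species)
        assert model.getNumReactions() == len(receptor_model.reactions)
        ours = {p: v for p, v in receptor_model.parameters.items()}
        theirs = {
            model.getParameter(i).getId(): model.getParameter(i).getValue()
            for i in range(model.getNumParameters())
        }
        assert ours == theirs


class TestProductionRates:
    def test_receptor_model_ids_in_document_order(self, receptor_model):
        assert tp.identify_production_rates(receptor_model) == ["k_x", "k_i"]

    def test_timer_has_single_production_rate(self, toy_timer):
        assert tp.identify_production_rates(toy_timer) == ["k_x"]

    def test_no_zeroth_order_reactions_gives_empty_list(self):
        net = ReactionNetwork(
            species=[Species("A", "A", 1.0, "cell")],
            reactions=[Reaction("deg", "degradation", {"A": 1}, {}, "kd*A")],
            parameters={"kd": 0.1},
            compartments={"cell": 1.0},
        )
        assert tp.identify_production_rates(net) == []

    def test_ambiguous_rate_constant_raises(self):
        # both k1 and k2 scale the flux linearly: identification must refuse
        net = ReactionNetwork(
            species=[Species("A", "A", 0.0, "cell")],
            reactions=[Reaction("syn", "synth", {}, {"A": 1}, "k1*k2")],
            parameters={"k1": 1.0, "k2": 2.0},
            compartments={"cell": 1.0},
        )
        with pytest.raises(tp.ProductionRateError):
            tp.identify_production_rates(net)


class TestKnockout:
    def test_unknown_reaction_lists_available_ids(self, receptor_model):
        with pytest.raises(KeyError, match="prod_X"):
            tp.apply_knockout(receptor_model, "nonexistent")

    def test_original_untouched_and_idempotent(self, receptor_model):
        ko1 = tp.apply_knockout(receptor_model, "prod_Inh")
        ko2 = tp.apply_knockout(ko1, "prod_Inh")
        assert receptor_model.reaction("prod_Inh").rate_law == "k_i"
        assert ko1.reaction("prod_Inh").rate_law == "0"
        assert ko1.summary() == ko2.summary()

    def test_knocked_out_timer_never_accumulates(self, toy_timer, no_stimulus):
        ko = tp.apply_knockout(toy_timer, "prod_X")
        traj, fate = tp.simulate_cell(ko, None, no_stimulus)
        assert not fate.died
        assert np.allclose(traj.species("X"), 0.0, atol=1e-10)

    def test_zero_flux_knockout_is_noop_on_trajectory(self, toy_timer, no_stimulus):
        # the timer model has no degradation reaction; knocking out a reaction
        # whose flux is zero along the trajectory must not change dynamics
        net = toy_timer.copy()
        net.reactions.append(
            Reaction("deg_X2", "second-order decay", {"X": 2}, {"X": 1}, "0*X")
        )
        traj_wt, _ = tp.simulate_cell(toy_timer, None, no_stimulus)
        traj_ko, _ = tp.simulate_cell(tp.apply_knockout(net, "deg_X2"), None, no_stimulus)
        x_wt = np.interp([1.0, 2.0, 3.0], traj_wt.t, traj_wt.species("X"))
        x_ko = np.interp([1.0, 2.0, 3.0], traj_ko.t, traj_ko.species("X"))
        np.testing.assert_allclose(x_wt, x_ko, rtol=1e-8)


class TestBuildRHS:
    def test_unknown_multiplier_rejected(self, receptor_model):
        with pytest.raises(KeyError, match="k_off"):
            build_rhs(receptor_model, {"k_off": 2.0})

    def test_unit_multipliers_match_nominal(self, receptor_model, rng):
        f_nom = build_rhs(receptor_model)
        f_one = build_rhs(receptor_model, {"k_x": 1.0, "k_i": 1.0})
        for _ in range(3):
            y = rng.uniform(0.0, 2.0, size=5)
            np.testing.assert_array_equal(f_nom(0.0, y), f_one(0.0, y))

    def test_doubling_multiplier_doubles_production_flux(self, receptor_model, rng):
        f1 = build_rhs(receptor_model, {"k_x": 1.0})
        f2 = build_rhs(receptor_model, {"k_x": 2.0})
        j = [r.id for r in receptor_model.reactions].index("prod_X")
        y = rng.uniform(0.1, 2.0, size=5)
        assert f2.fluxes(0.0, y)[j] == pytest.approx(2 * f1.fluxes(0.0, y)[j], rel=1e-12)

    def test_timer_rhs_is_multiplier_times_rate(self, toy_timer):
        f = build_rhs(toy_timer, {"k_x": 3.0})
        assert f(0.0, np.array([17.0]))[0] == pytest.approx(3.0, abs=1e-14)

    def test_zero_state_zero_production_gives_zero_derivative(self, receptor_model):
        f = build_rhs(receptor_model, {"k_x": 1e-300, "k_i": 1e-300})
        np.testing.assert_allclose(f(0.0, np.zeros(5)), 0.0, atol=1e-290)

    def test_finite_difference_oracle(self, receptor_model, rng):
        """Euler finite differences of the integrated flow match the RHS."""
        from scipy.integrate import solve_ivp

        f = build_rhs(receptor_model)
        h = 1e-7
        for _ in range(3):
            y = rng.uniform(0.1, 2.0, size=5)
            sol = solve_ivp(f, (0, h), y, method="RK45", rtol=1e-12, atol=1e-14)
            fd = (sol.y[:, -1] - y) / h
            np.testing.assert_allclose(fd, f(0.0, y), rtol=1e-5, atol=1e-9)


def test_conserved_receptor_moiety(receptor_model):
    """R + C is conserved: the model neither makes nor degrades receptor."""
    proto = tp.StimulusProtocol(dose_ng_ml=10.0, horizon_hours=10.0)
    traj, _ = tp.simulate_cell(receptor_model, None, proto)
    total = traj.species("R") + traj.species("C")
    np.testing.assert_allclose(total, total[0], rtol=1e-6)


class TestValidation:
    def test_negative_initial_amount(self):
        net = ReactionNetwork(
            species=[Species("A", "A", -1.0, "cell")],
            reactions=[],
            parameters={},
        )
        with pytest.raises(tp.TnfpopError, match="finite and >= 0"):
            net.validate()

    def test_rate_law_with_unknown_species(self):
        net = ReactionNetwork(
            species=[Species("A", "A", 1.0, "cell")],
            reactions=[Reaction("r", "r", {"A": 1}, {}, "k*B")],
            parameters={"k": 1.0},
        )
        with pytest.raises(tp.TnfpopError, match="unknown id"):
            net.validate()
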