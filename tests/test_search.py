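import pytest

from fluxredirect import (
    Design,
    SearchConfig,
    ToyNetworkSpec,
    decision_step,
    evaluate_design,
    make_toy_network,
    run_progressive_search,
    update_progressive_growth,
)
from fluxredirect.design import EMPTY_DESIGN
from fluxredirect.fba import FluxState
from fluxredirect.library import CoefficientLibrary, LibraryEntry
from fluxredirect.groups import EnzymeGroup
from fluxredirect.toys import TOY_EXPORT

TOL = 1e-6


class TestDecisionStep:
    @pytest.mark.parametrize(
        "fraction,new_targets,action",
        [
            (0.5, True, "continue"),
            (0.9, False, "increase_gamma"),
            (0.9, True, "save_and_increase"),
            (0.5, False, "terminate"),
            # threshold is inclusive at 0.8
            (0.8, True, "save_and_increase"),
            (0.8, False, "increase_gamma"),
            (0.79999, True, "continue"),
            (0.79999, False, "terminate"),
        ],
    )
    def test_branches(self, fraction, new_targets, action):
        assert decision_step(fraction, new_targets) == action


def _library_one_group(beta=1.0):
    group = EnzymeGroup("g", ("rx",))
    return CoefficientLibrary(
        [LibraryEntry("g", "up", beta), LibraryEntry("g", "down", -beta)],
        {"g": group},
    )


class TestProgressiveUpdate:
    def test_formula_on_one_included_term(self):
        lib = _library_one_group()
        design = Design.from_pairs([("g", "up")])
        fluxes = FluxState({"rx": 10.0}, 0.0, "optimal")
        gamma = update_progressive_growth(design, fluxes, lib, {"rx": 0.0}, 0.1)
        assert gamma == pytest.approx(10.1)

    def test_empty_design_returns_delta(self):
        lib = _library_one_group()
        gamma = update_progressive_growth(
            EMPTY_DESIGN, FluxState({}, 0.0, "optimal"), lib, {}, 1e-4
        )
        assert gamma == pytest.approx(1e-4)

    def test_growth_reference_subtracts(self):
        lib = _library_one_group()
        design = Design.from_pairs([("g", "down")])  # beta = -1
        fluxes = FluxState({"rx": 2.0}, 0.0, "optimal")
        gamma = update_progressive_growth(design, fluxes, lib, {"rx": 8.0}, 0.01)
        # beta * (v - v_maxgrowth) = (-1) * (2 - 8) = 6
        assert gamma == pytest.approx(6.01)

    def test_escalated_gamma_defeats_the_design_that_set_it(self, t1, t1_lib):
        design = Design.from_pairs([("enzp", "up")])
        fluxes, production = evaluate_design(t1, design, 0.02, t1_lib, TOY_EXPORT)
        assert production == pytest.approx(10.0, abs=TOL)
        ref, _ = evaluate_design(t1, EMPTY_DESIGN, 1.0, t1_lib, TOY_EXPORT)
        gamma_new = update_progressive_growth(
            design, fluxes, t1_lib, ref.flux, 1e-4, biomass_scale=10.0
        )
        _, production_after = evaluate_design(t1, design, gamma_new, t1_lib, TOY_EXPORT)
        assert production_after == pytest.approx(0.0, abs=1e-4)


class TestProgressiveSearchDriver:
    def test_branch_toy_saturates_quickly(self, t1):
        res = run_progressive_search(t1, TOY_EXPORT, SearchConfig(k=1, max_iterations=30))
        assert res.production == pytest.approx(10.0, abs=TOL)
        gammas = list(res.history["gamma"])
        assert gammas == sorted(gammas)
        # gamma strictly increases after each save
        saves = res.history[res.history["action"] == "save_and_increase"]
        assert len(saves) >= 1

    def test_chain_recruits_one_enzyme_per_escalation(self, t2):
        res = run_progressive_search(t2, TOY_EXPORT, SearchConfig(k=1, max_iterations=30))
        counts = list(res.history["n_targets"])
        saved = res.history[res.history["action"] == "save_and_increase"]
        assert list(saved["n_targets"]) == [1, 2, 3, 4, 5]
        assert len(res.design) == 5
        assert res.production == pytest.approx(10.0, abs=TOL)
        assert all(b - a in (0, 1) for a, b in zip(counts, counts[1:]))

    def test_zero_iterations_is_a_no_op(self, t1):
        res = run_progressive_search(t1, TOY_EXPORT, SearchConfig(k=1, max_iterations=0))
        assert res.design == EMPTY_DESIGN
        assert len(res.history) == 0

    def test_history_is_deterministic(self, t2):
        cfg = SearchConfig(k=1, max_iterations=30)
        a = run_progressive_search(t2, TOY_EXPORT, cfg)
        b = run_progressive_search(t2, TOY_EXPORT, cfg)
        assert a.history.equals(b.history)
        assert a.design == b.design

    def test_saved_checkpoints_meet_threshold(self, t2):
        cfg = SearchConfig(k=1, max_iterations=30)
        res = run_progressive_search(t2, TOY_EXPORT, cfg)
        for design, gamma, production in res.state.saved_designs:
            assert production / res.state.max_production >= cfg.production_threshold

    def test_gamma_sequence_never_decreases_under_k2(self):
        chain = make_toy_network(ToyNetworkSpec("T2", chain_length=4))
        res = run_progressive_search(chain, TOY_EXPORT, SearchConfig(k=2, max_iterations=30))
        gammas = list(res.history["gamma"])
        assert gammas == sorted(gammas)
        assert res.production == pytest.approx(10.0, abs=TOL)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SearchConfig(production_threshold=0.0)
        with pytest.raises(ValueError):
            SearchConfig(delta_progress=0.0)
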