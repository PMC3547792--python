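import numpy as np
import pytest

from fluxredirect import (
    LinearObjective,
    classify_boundary_targets,
    flux_variability,
    sensitivity_scores,
    solve_fba,
)
from fluxredirect.fba import SolverError, VariabilityBounds
from fluxredirect.toys import TOY_EXPORT

FEAS = 1e-9


class TestSolveFBA:
    def test_growth_optimum_routes_nothing_to_export(self, t1):
        state = solve_fba(t1, LinearObjective({t1.biomass_reaction: 1.0}))
        assert state.optimal
        assert state.objective_value == pytest.approx(10.0, abs=FEAS)
        assert state.flux[TOY_EXPORT] == pytest.approx(0.0, abs=FEAS)

    def test_export_optimum_routes_nothing_to_growth(self, t1):
        state = solve_fba(t1, LinearObjective({TOY_EXPORT: 1.0}))
        assert state.objective_value == pytest.approx(10.0, abs=FEAS)
        assert state.flux[t1.biomass_reaction] == pytest.approx(0.0, abs=FEAS)

    def test_zero_objective_is_trivially_optimal(self, t2):
        state = solve_fba(t2, LinearObjective({}))
        assert state.optimal and state.objective_value == 0.0

    def test_solution_respects_mass_balance_and_bounds(self, t4):
        state = solve_fba(t4, LinearObjective({t4.biomass_reaction: 1.0}))
        v = np.array([state.flux[r] for r in t4.reactions])
        assert np.abs(t4.smatrix() @ v).max() <= 1e-9
        lb, ub = t4.bounds_arrays()
        assert np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9)


class TestFluxVariability:
    def test_full_growth_anchor_pins_export_to_zero(self, t1):
        bounds = flux_variability(t1, LinearObjective({t1.biomass_reaction: 1.0}), 1.0)
        lo, hi = bounds.bounds[TOY_EXPORT]
        assert (lo, hi) == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_full_export_anchor_pins_biomass_to_zero(self, t1):
        bounds = flux_variability(t1, LinearObjective({TOY_EXPORT: 1.0}), 1.0)
        lo, hi = bounds.bounds[t1.biomass_reaction]
        assert (lo, hi) == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_zero_fraction_gives_unconstrained_ranges(self, t1):
        bounds = flux_variability(t1, LinearObjective({t1.biomass_reaction: 1.0}), 0.0)
        assert bounds.bounds["R_up"] == pytest.approx((0.0, 10.0), abs=1e-9)
        assert bounds.bounds[TOY_EXPORT] == pytest.approx((0.0, 10.0), abs=1e-9)

    @pytest.mark.parametrize("f_tight,f_loose", [(1.0, 0.5), (0.8, 0.2), (0.5, 0.0)])
    def test_ranges_nest_with_fraction(self, t1, f_tight, f_loose):
        anchor = LinearObjective({t1.biomass_reaction: 1.0})
        tight = flux_variability(t1, anchor, f_tight)
        loose = flux_variability(t1, anchor, f_loose)
        for rxn in t1.reactions:
            assert tight.bounds[rxn][0] >= loose.bounds[rxn][0] - 1e-9
            assert tight.bounds[rxn][1] <= loose.bounds[rxn][1] + 1e-9

    def test_infeasible_anchor_raises(self, t1):
        bad = t1.copy()
        bad.lower_bound["R_bio"] = 20.0  # above uptake capacity
        bad.upper_bound["R_bio"] = 21.0
        with pytest.raises(SolverError):
            flux_variability(bad, LinearObjective({bad.biomass_reaction: 1.0}), 1.0)


class TestBoundaryClassification:
    def test_label_definitions(self):
        growth = VariabilityBounds({"r": (0.0, 2.0), "s": (1.0, 4.0), "t": (3.0, 5.0)})
        production = VariabilityBounds({"r": (3.0, 5.0), "s": (2.0, 3.0), "t": (0.0, 2.0)})
        assert classify_boundary_targets(growth, production) == {
            "r": "up", "s": "overlap", "t": "down",
        }

    def test_antisymmetric_under_swap(self, t1):
        growth = flux_variability(t1, LinearObjective({t1.biomass_reaction: 1.0}), 1.0)
        produc = flux_variability(t1, LinearObjective({TOY_EXPORT: 1.0}), 1.0)
        fwd = classify_boundary_targets(growth, produc)
        rev = classify_boundary_targets(produc, growth)
        flip = {"up": "down", "down": "up", "overlap": "overlap"}
        assert rev == {r: flip[lab] for r, lab in fwd.items()}

    def test_fully_anchored_toy_labels(self, t1):
        growth = flux_variability(t1, LinearObjective({t1.biomass_reaction: 1.0}), 1.0)
        produc = flux_variability(t1, LinearObjective({TOY_EXPORT: 1.0}), 1.0)
        labels = classify_boundary_targets(growth, produc)
        assert labels[TOY_EXPORT] == "up"
        assert labels[t1.biomass_reaction] == "down"

    def test_mismatched_reaction_sets_rejected(self):
        with pytest.raises(ValueError):
            classify_boundary_targets(
                VariabilityBounds({"r": (0, 1)}), VariabilityBounds({"s": (0, 1)})
            )


class TestSensitivity:
    def test_uptake_marginally_converts_to_product(self, t1):
        scores, degenerate = sensitivity_scores(t1, LinearObjective({TOY_EXPORT: 1.0}))
        assert not degenerate
        assert scores["R_up"] == pytest.approx(1.0, abs=1e-9)
        assert scores[t1.biomass_reaction] == pytest.approx(-1.0, abs=1e-9)

    def test_capacity_fixed_reaction_scores_zero(self, t3):
        for method in ("dual", "finite_difference"):
            scores, _ = sensitivity_scores(
                t3, LinearObjective({TOY_EXPORT: 1.0}), method=method
            )
            assert scores["R_dead"] == 0.0

    @pytest.mark.parametrize("fixture", ["t1", "t3"])
    def test_dual_matches_finite_difference_when_nondegenerate(self, fixture, request):
        net = request.getfixturevalue(fixture)
        objective = LinearObjective({TOY_EXPORT: 1.0})
        dual, degenerate = sensitivity_scores(net, objective)
        assert not degenerate
        fd, _ = sensitivity_scores(net, objective, method="finite_difference")
        for rxn in net.reactions:
            assert dual[rxn] == pytest.approx(fd[rxn], abs=1e-6), rxn

    def test_alternate_dual_vertices_are_flagged(self, t1, t4):
        # reactions at a bound with zero reduced cost signal alternate
        # optima: the growth objective on the branch toy and the export
        # objective on the drain toy both have them
        _, deg_growth = sensitivity_scores(
            t1, LinearObjective({t1.biomass_reaction: 1.0})
        )
        _, deg_drain = sensitivity_scores(t4, LinearObjective({TOY_EXPORT: 1.0}))
        assert deg_growth and deg_drain
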