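import numpy as np
import pytest

import bicarbenv as bv
from bicarbenv.model import INF_BOUND, MetabolicModel, Metabolite, Reaction

from conftest import brute_force_optimum


def _cycle_model():
    """A -> B with a parallel futile cycle B -> A, so the flux through the
    forward reaction is non-unique at the export optimum."""
    m = MetabolicModel()
    for mid, comp in (("A_e", "e"), ("A", "c"), ("B", "c"), ("B_e", "e")):
        m.add_metabolite(Metabolite(mid, formula={"C": 1, "H": 2, "O": 1},
                                    compartment=comp))
    m.add_reaction(Reaction("EX_A", stoichiometry={"A_e": -1},
                            lower_bound=-1.0, upper_bound=0.0, is_exchange=True))
    m.add_reaction(Reaction("At", stoichiometry={"A_e": -1, "A": 1},
                            lower_bound=0.0, upper_bound=INF_BOUND))
    m.add_reaction(Reaction("fwd", stoichiometry={"A": -1, "B": 1},
                            lower_bound=0.0, upper_bound=10.0))
    m.add_reaction(Reaction("rev", stoichiometry={"B": -1, "A": 1},
                            lower_bound=0.0, upper_bound=10.0))
    m.add_reaction(Reaction("Bt", stoichiometry={"B": -1, "B_e": 1},
                            lower_bound=0.0, upper_bound=INF_BOUND))
    m.add_reaction(Reaction("EX_B", stoichiometry={"B_e": -1},
                            lower_bound=0.0, upper_bound=INF_BOUND, is_exchange=True))
    return m


def _parallel_model():
    """Two alternative routes A -> B (direct, or via C); optima are
    degenerate in the route choice."""
    m = MetabolicModel()
    for mid, comp in (("A_e", "e"), ("A", "c"), ("B", "c"), ("C", "c"), ("B_e", "e")):
        m.add_metabolite(Metabolite(mid, formula={"C": 1, "H": 2, "O": 1},
                                    compartment=comp))
    m.add_reaction(Reaction("EX_A", stoichiometry={"A_e": -1},
                            lower_bound=-1.0, upper_bound=0.0, is_exchange=True))
    m.add_reaction(Reaction("At", stoichiometry={"A_e": -1, "A": 1},
                            lower_bound=0.0, upper_bound=INF_BOUND))
    m.add_reaction(Reaction("direct", stoichiometry={"A": -1, "B": 1},
                            lower_bound=0.0, upper_bound=INF_BOUND))
    m.add_reaction(Reaction("via1", stoichiometry={"A": -1, "C": 1},
                            lower_bound=0.0, upper_bound=INF_BOUND))
    m.add_reaction(Reaction("via2", stoichiometry={"C": -1, "B": 1},
                            lower_bound=0.0, upper_bound=INF_BOUND))
    m.add_reaction(Reaction("Bt", stoichiometry={"B": -1, "B_e": 1},
                            lower_bound=0.0, upper_bound=INF_BOUND))
    m.add_reaction(Reaction("EX_B", stoichiometry={"B_e": -1},
                            lower_bound=0.0, upper_bound=INF_BOUND, is_exchange=True))
    return m


class TestSolveFBA:
    def test_linear_chain_max_export(self, toy_linear):
        sol = bv.solve_fba(toy_linear, "EX_B", "max")
        assert sol.optimal
        assert sol.objective_value == pytest.approx(1.0, abs=1e-9)
        assert sol.steady_state_residual <= 1e-6

    def test_atp_audit_16_per_glucose(self, core_model):
        """With P/O = 1, glucose fixed at 1 mmol/gDCW/h and zero growth,
        maximal ATP dissipation is 16 mol/mol: 4 substrate-level + 12
        respiratory (10 NADH + 2 FADH2 at P/O = 1)."""
        m = bv.fix_flux(core_model, "EX_glc", -1.0)
        m = bv.fix_flux(m, "BIOMASS", 0.0)
        sol = bv.solve_fba(m, "ATPM", "max")
        assert sol.objective_value == pytest.approx(16.0, abs=1e-6)

    def test_no_bicarbonate_no_product(self, core_with_pathway):
        m = bv.cap_bicarbonate_formation(core_with_pathway, 0.0, 1.0)
        sol = bv.solve_fba(m, "EX_3hp", "max")
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_is_status_not_exception(self, toy_linear):
        m = bv.set_bounds(toy_linear, "EX_B", 5.0, 10.0)  # demands more than uptake
        sol = bv.solve_fba(m, "EX_B", "max")
        assert sol.status == "infeasible"

    def test_missing_objective_raises(self, toy_linear):
        with pytest.raises(bv.ModelValidationError):
            bv.solve_fba(toy_linear, "nope", "max")

    def test_fluxes_within_bounds(self, core_model):
        m = bv.fix_flux(core_model, "EX_glc", -1.0)
        sol = bv.solve_fba(m, "BIOMASS", "max")
        for rid, v in sol.fluxes.items():
            rxn = m.reactions[rid]
            assert rxn.lower_bound - 1e-9 <= v <= rxn.upper_bound + 1e-9


class TestBoundEdits:
    def test_fix_glucose_uptake(self, core_model):
        m = bv.fix_flux(core_model, "EX_glc", -1.0)
        rxn = m.reactions["EX_glc"]
        assert rxn.lower_bound == rxn.upper_bound == -1.0
        # original untouched
        assert core_model.reactions["EX_glc"].lower_bound == -1.0
        assert core_model.reactions["EX_glc"].upper_bound == 0.0

    def test_knockout(self, toy_linear):
        m = bv.set_bounds(toy_linear, "AB", 0.0, 0.0)
        assert bv.solve_fba(m, "EX_B", "max").objective_value == pytest.approx(0.0)

    def test_fixed_flux_is_honoured_exactly(self, toy_linear):
        m = bv.fix_flux(toy_linear, "AB", 0.5)
        sol = bv.solve_fba(m, "EX_B", "max")
        assert sol["AB"] == pytest.approx(0.5, abs=1e-9)

    def test_inverted_bounds_rejected(self, toy_linear):
        with pytest.raises(bv.ModelValidationError):
            bv.set_bounds(toy_linear, "AB", 1.0, 0.0)


class TestFluxRangeAtOptimum:
    def test_unique_optimum_collapses(self, toy_linear):
        lo, hi = bv.flux_range_at_optimum(toy_linear, "EX_B", "AB")
        assert lo == pytest.approx(hi, abs=1e-6)

    def test_futile_cycle_has_open_range(self):
        m = _cycle_model()
        lo, hi = bv.flux_range_at_optimum(m, "EX_B", "fwd")
        assert lo == pytest.approx(1.0, abs=1e-6)
        assert hi == pytest.approx(10.0, abs=1e-6)
        # brute-force oracle agrees on both extremes
        fixed = bv.fix_flux(m, "EX_B", 1.0)
        assert brute_force_optimum(fixed, "fwd", "min") == pytest.approx(lo, abs=1e-7)
        assert brute_force_optimum(fixed, "fwd", "max") == pytest.approx(hi, abs=1e-7)


class TestParsimonious:
    def test_redundant_route_eliminated(self):
        m = _parallel_model()
        sol = bv.parsimonious_refine(m, "EX_B", "max")
        assert sol.objective_value == pytest.approx(1.0, abs=1e-6)
        # single-step route carries everything; two-step detour unused
        assert sol["direct"] == pytest.approx(1.0, abs=1e-6)
        assert sol["via1"] == pytest.approx(0.0, abs=1e-6)

    def test_matches_plain_fba_when_unique(self, toy_linear):
        plain = bv.solve_fba(toy_linear, "EX_B", "max")
        refined = bv.parsimonious_refine(toy_linear, "EX_B", "max")
        assert refined.objective_value == pytest.approx(
            plain.objective_value, abs=1e-9)
        for rid in toy_linear.reaction_ids:
            assert refined[rid] == pytest.approx(plain[rid], abs=1e-6)


class TestOracleAgreement:
    @pytest.mark.parametrize("builder,objective", [
        (bv.build_toy_linear_model, "EX_B"),
        (bv.build_toy_branch_model, "EX_P"),
        (_cycle_model, "EX_B"),
        (_parallel_model, "EX_B"),
    ])
    def test_matches_vertex_enumeration(self, builder, objective):
        model = builder()
        sol = bv.solve_fba(model, objective, "max")
        oracle = brute_force_optimum(model, objective, "max")
        assert sol.objective_value == pytest.approx(oracle, abs=1e-9)

    def test_optimum_concave_in_uptake_bound(self, toy_branch):
        """The LP optimum as a function of a single bound is concave."""
        values = []
        for u in np.linspace(0.1, 2.0, 9):
            m = bv.set_bounds(toy_branch, "EX_S", -u, 0.0)
            values.append(bv.solve_fba(m, "EX_P", "max").objective_value)
        second = np.diff(values, 2)
        assert np.all(second <= 1e-9)


class TestCarbonBalance:
    @pytest.mark.parametrize("objective", ["BIOMASS", "ATPM", "EX_3hp"])
    def test_exchange_carbon_closes(self, core_with_pathway, objective):
        m = bv.fix_flux(core_with_pathway, "EX_glc", -1.0)
        sol = bv.solve_fba(m, objective, "max")
        assert sol.optimal
        assert abs(bv.exchange_carbon_flux(m, sol.fluxes)) <= 1e-6


def _to_cobra(model):
    import cobra

    cm = cobra.Model("cross_check")
    mets = {mid: cobra.Metabolite(mid, compartment=met.compartment)
            for mid, met in model.metabolites.items()}
    for rxn in model.reactions.values():
        cr = cobra.Reaction(rxn.id, lower_bound=rxn.lower_bound,
                            upper_bound=rxn.upper_bound)
        cm.add_reactions([cr])
        cr.add_metabolites({mets[mid]: c for mid, c in rxn.stoichiometry.items()})
    return cm


class TestCobraCrossCheck:
    @pytest.mark.parametrize("objective", ["BIOMASS", "ATPM"])
    def test_objective_agrees_with_cobrapy(self, core_model, objective):
        cobra = pytest.importorskip("cobra")
        m = bv.fix_flux(core_model, "EX_glc", -1.0)
        if objective == "ATPM":
            m = bv.fix_flux(m, "BIOMASS", 0.0)
        ours = bv.solve_fba(m, objective, "max").objective_value
        cm = _to_cobra(m)
        cm.objective = objective
        theirs = cm.optimize().objective_value
        assert ours == pytest.approx(theirs, abs=1e-6)
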