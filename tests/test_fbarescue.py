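"""Constraint-based rescue analysis: LP correctness, scenarios, ranking."""

import math

import numpy as np
import pandas as pd
import pytest

from offtarget import fbarescue as fr
from offtarget import synthio
from offtarget.fbarescue import (
    InhibitionScenario,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
)

SUPPLEMENTS = ["thymidine", "uridine", "imp", "amp",
               "serine", "glycine", "aspartate", "citrate"]


def cobra_optimum(model, tmp_path) -> float:
    """Independent LP oracle: round-trip through the JSON schema into cobrapy
    (GLPK) and optimize there."""
    import cobra

    path = tmp_path / f"{model.id}.json"
    fr.write_model(model, path)
    cm = cobra.io.load_json_model(str(path))
    sol = cm.optimize()
    if sol.status != "optimal":
        return math.nan
    return float(sol.objective_value)


def chain_model():
    """uptake <= 10, biomass consumes 10 units -> mu = 1.0 closed form."""
    return MetabolicModel(
        id="chain",
        metabolites=[Metabolite("a_e", "e"), Metabolite("a", "c")],
        reactions=[
            Reaction("EX_a_e", {"a_e": -1}, -10, 1000),
            Reaction("At", {"a_e": -1, "a": 1}, 0, 1000),
            Reaction("BIOMASS", {"a": -10}, 0, 1000, objective_coefficient=1.0),
        ],
    )


class TestModelIO:
    def test_round_trip_identity(self, toy_model, tmp_path):
        path = tmp_path / "toy.json"
        fr.write_model(toy_model, path)
        back = fr.read_model(path)
        assert back.reaction_ids() == toy_model.reaction_ids()
        assert back.metabolite_ids() == toy_model.metabolite_ids()
        for r1, r2 in zip(toy_model.reactions, back.reactions):
            assert r1.stoichiometry == r2.stoichiometry
            assert (r1.lower_bound, r1.upper_bound) == \
                (r2.lower_bound, r2.upper_bound)
            assert r1.gene_rule == r2.gene_rule
            assert r1.spontaneous == r2.spontaneous

    def test_bound_inversion_rejected(self, tmp_path):
        m = chain_model()
        m.get_reaction("At").lower_bound = 5.0
        m.get_reaction("At").upper_bound = 1.0
        with pytest.raises(ModelValidationError, match="lower bound"):
            m.validate()

    def test_dangling_metabolite_rejected(self):
        m = chain_model()
        m.reactions.append(Reaction("BAD", {"ghost": -1.0, "a": 1.0}))
        with pytest.raises(ModelValidationError, match="unknown metabolites"):
            m.validate()


class TestFBA:
    def test_linear_chain_closed_form(self):
        sol = fr.fba(chain_model())
        assert sol.objective_value == pytest.approx(1.0, abs=1e-9)

    def test_closed_uptakes_zero_growth(self):
        m = chain_model()
        m.get_reaction("EX_a_e").lower_bound = 0.0
        assert fr.fba(m).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_matches_independent_lp_oracle(self, toy_model, shutoff_model,
                                           tmp_path):
        for i, model in enumerate([chain_model(), toy_model, shutoff_model]):
            model = model.copy()
            model.id = f"oracle_{i}"
            mine = fr.fba(model, parsimonious=False).objective_value
            theirs = cobra_optimum(model, tmp_path)
            assert mine == pytest.approx(theirs, abs=1e-8)

    def test_mass_balance_and_bounds(self, toy_model):
        sol = fr.pfba(toy_model)
        S = toy_model.stoichiometric_matrix()
        residual = S.to_numpy() @ sol.fluxes.to_numpy()
        assert np.abs(residual).max() < 1e-6
        for r in toy_model.reactions:
            v = sol.fluxes[r.id]
            assert r.lower_bound - 1e-9 <= v <= r.upper_bound + 1e-9

    def test_pfba_preserves_optimum(self, toy_model):
        plain = fr.fba(toy_model, parsimonious=False)
        pars = fr.pfba(toy_model)
        assert pars.objective_value == pytest.approx(
            plain.objective_value, abs=1e-7)
        assert pars.fluxes.abs().sum() <= plain.fluxes.abs().sum() + 1e-6


class TestGeneRules:
    def test_and_rule_closes_on_missing_gene(self):
        assert not fr.evaluate_gene_rule("gA and gB", {"gA"})

    def test_or_rule_stays_open(self):
        assert fr.evaluate_gene_rule("gA or gB", {"gA"})

    def test_nested_rule(self):
        assert fr.evaluate_gene_rule("(gA or gB) and gC", {"gA"})
        assert not fr.evaluate_gene_rule("(gA or gB) and gC", {"gA", "gC"})

    def test_unparseable_rule_raises(self):
        with pytest.raises(ModelValidationError):
            fr.evaluate_gene_rule("gA and and gB", set())

    def test_citrate_shutoff_removes_benefit(self, toy_model):
        expressed = fr.growth_benefit(toy_model, None, "citrate")
        shut = fr.apply_expression_shutoff(toy_model, {"citT"}, scope="global")
        assert expressed > 1e-6
        assert fr.growth_benefit(shut, None, "citrate") == \
            pytest.approx(0.0, abs=1e-9)

    def test_neighborhood_scope_only_touches_nearby(self, toy_model):
        # citT transport is adjacent to citrate; a neighborhood shutoff
        # around serine must leave it open
        shut = fr.apply_expression_shutoff(
            toy_model, {"citT"}, scope="neighborhood",
            around_metabolites=["ser"], k=1)
        assert shut.get_reaction("CITt").upper_bound > 0
        shut2 = fr.apply_expression_shutoff(
            toy_model, {"citT"}, scope="neighborhood",
            around_metabolites=["cit"], k=1)
        assert shut2.get_reaction("CITt").upper_bound == 0


class TestInhibitPathway:
    def test_fraction_one_no_change(self, toy_model, baseline_solution):
        capped = fr.inhibit_pathway(toy_model, ["TMDS"], 1.0)
        assert fr.fba(capped).objective_value == pytest.approx(
            baseline_solution.objective_value, abs=1e-7)

    def test_fraction_zero_on_folate_charging_kills(self, toy_model):
        capped = fr.inhibit_pathway(toy_model, ["SHMT"], 0.0)
        assert fr.fba(capped).objective_value == pytest.approx(0.0, abs=1e-8)

    def test_ninety_percent_cap_scales_growth(self, toy_model,
                                              baseline_solution):
        capped = fr.inhibit_pathway(toy_model, ["TMDS"], 0.9)
        assert fr.fba(capped).objective_value == pytest.approx(
            0.9 * baseline_solution.objective_value, abs=1e-7)

    def test_invalid_fraction(self, toy_model):
        with pytest.raises(ValueError):
            fr.inhibit_pathway(toy_model, ["TMDS"], 1.5)


class TestCofactorDrain:
    def test_zero_drain_no_change(self, toy_model, baseline_solution):
        drained = fr.add_cofactor_drain(toy_model, "mlthf", "thf", 0.0)
        assert fr.fba(drained).objective_value == pytest.approx(
            baseline_solution.objective_value, abs=1e-7)

    def test_breakpoint_by_bisection(self, toy_model):
        # ramp the drain until growth hits zero; the breakpoint must match
        # bisection on the feasibility of positive growth
        def mu_at(d):
            m = fr.add_cofactor_drain(toy_model, "mlthf", "thf", d)
            sol = fr.fba(m, parsimonious=False)
            return sol.objective_value if sol.optimal else math.nan

        lo, hi = 0.0, 50.0
        assert mu_at(lo) > 0.5
        assert not mu_at(hi) > 1e-6  # dead or infeasible
        for _ in range(40):
            mid = (lo + hi) / 2
            if mu_at(mid) > 1e-6:
                lo = mid
            else:
                hi = mid
        breakpoint_ = (lo + hi) / 2
        assert 0 < breakpoint_ < 50
        assert mu_at(breakpoint_ * 0.95) > 0
        assert not mu_at(breakpoint_ * 1.05) > 1e-6

    def test_serine_rescues_drain(self, shutoff_model, baseline_solution):
        d = 0.5 * baseline_solution.fluxes["SHMT"]
        sc = InhibitionScenario("drain", "cofactor_drain", charged="mlthf",
                                discharged="thf", drain_rate=d)
        ser = fr.growth_benefit(shutoff_model, sc, "serine")
        gly = fr.growth_benefit(shutoff_model, sc, "glycine")
        assert ser > 1e-6
        assert gly == pytest.approx(0.0, abs=1e-8)
        assert ser > gly

    def test_missing_metabolite_rejected(self, toy_model):
        with pytest.raises(KeyError):
            fr.add_cofactor_drain(toy_model, "nope", "thf", 1.0)


class TestSupplement:
    def test_round_trip_unchanged(self, toy_model):
        supped = fr.supplement(toy_model, "serine", 0.1)
        back = fr.remove_supplement(supped, "serine")
        assert back.get_reaction("EX_serine_e").lower_bound == 0.0
        assert fr.fba(back).objective_value == pytest.approx(
            fr.fba(toy_model).objective_value, abs=1e-9)

    def test_zero_rate_no_change(self, toy_model):
        supped = fr.supplement(toy_model, "thymidine", 0.0)
        assert fr.fba(supped).objective_value == pytest.approx(
            fr.fba(toy_model).objective_value, abs=1e-9)

    def test_thymidine_restores_full_growth_under_mild_cap(self, shutoff_model):
        # salvage bypasses the capped folate-dependent step entirely (and
        # even spares some carbon), so growth returns to at least mu*
        mu_star = fr.fba(shutoff_model).objective_value
        capped = fr.inhibit_pathway(shutoff_model, ["TMDS"], 0.95)
        supped = fr.supplement(capped, "thymidine", 0.1)
        assert fr.fba(supped).objective_value >= mu_star - 1e-7

    def test_absent_metabolite_rejected(self, toy_model):
        with pytest.raises(KeyError):
            fr.supplement(toy_model, "unobtainium")

    def test_supplement_never_decreases_growth(self, shutoff_model):
        # LP relaxation monotonicity over every scenario kind
        scenarios = [
            None,
            InhibitionScenario("t", "pathway_fraction", targets=["TMDS"],
                               fraction=0.9),
            InhibitionScenario("d", "cofactor_drain", charged="mlthf",
                               discharged="thf", drain_rate=1.0),
        ]
        for sc in scenarios:
            for met in SUPPLEMENTS:
                b = fr.growth_benefit(shutoff_model, sc, met)
                assert b >= -1e-9


class TestRescuePattern:
    """The qualitative supplementation distinctions the toy model encodes."""

    def test_thymidine_over_uridine(self, shutoff_model):
        sc = InhibitionScenario("tmds", "pathway_fraction", targets=["TMDS"],
                                fraction=0.9)
        thy = fr.growth_benefit(shutoff_model, sc, "thymidine")
        urd = fr.growth_benefit(shutoff_model, sc, "uridine")
        assert thy > 1e-6
        assert urd == pytest.approx(0.0, abs=1e-8)

    def test_imp_over_amp_after_shutoffs(self, toy_model, shutoff_model):
        sc = InhibitionScenario("aicart", "pathway_fraction",
                                targets=["AICART"], fraction=0.9)
        imp_1 = fr.growth_benefit(toy_model, sc, "imp")
        amp_1 = fr.growth_benefit(toy_model, sc, "amp")
        imp_2 = fr.growth_benefit(shutoff_model, sc, "imp")
        amp_2 = fr.growth_benefit(shutoff_model, sc, "amp")
        # before accounting for expression, AMP looks as good as IMP
        assert amp_1 == pytest.approx(imp_1, abs=1e-8)
        # afterwards only IMP retains its benefit
        assert imp_2 > amp_2 + 1e-6
        assert amp_2 == pytest.approx(0.0, abs=1e-8)


class TestNullAndRanking:
    def test_null_deterministic_under_seed(self, shutoff_model):
        t1 = fr.random_inhibition_null(shutoff_model, SUPPLEMENTS, 5, seed=3)
        t2 = fr.random_inhibition_null(shutoff_model, SUPPLEMENTS, 5, seed=3)
        pd.testing.assert_frame_equal(t1, t2)

    def test_blocked_reaction_knockout_equals_baseline(self, shutoff_model):
        # AMPDA is already closed by the shutoff: knocking it out changes
        # nothing relative to the unconstrained benefits
        sc = InhibitionScenario("ko", "knockout", targets=["AMPDA"])
        ko = fr.benefit_vector(shutoff_model, sc, SUPPLEMENTS)
        base = fr.benefit_vector(shutoff_model, None, SUPPLEMENTS)
        assert np.allclose(ko.to_numpy(), base.to_numpy(), atol=1e-8)

    def test_proportional_benefits_give_unit_correlation(self,
                                                         experimental_rescue):
        bt = pd.DataFrame(
            [experimental_rescue * 0.1, -experimental_rescue],
            index=["prop", "anti"])
        ranked = fr.rank_scenarios(bt, experimental_rescue)
        by_name = ranked.set_index("scenario")["pearson_r"]
        assert by_name["prop"] == pytest.approx(1.0)
        assert by_name["anti"] == pytest.approx(-1.0)

    def test_zero_variance_ranked_last(self, experimental_rescue):
        bt = pd.DataFrame(
            [experimental_rescue * 0.1,
             pd.Series(0.0, index=experimental_rescue.index)],
            index=["good", "flat"])
        ranked = fr.rank_scenarios(bt, experimental_rescue)
        assert ranked.iloc[-1]["scenario"] == "flat"
        assert np.isnan(ranked.iloc[-1]["pearson_r"])

    def test_benefit_scaling_leaves_ranking_unchanged(self, shutoff_model,
                                                      experimental_rescue):
        drain = InhibitionScenario("drain", "cofactor_drain", charged="mlthf",
                                   discharged="thf", drain_rate=2.0)
        tmds = InhibitionScenario("tmds", "pathway_fraction",
                                  targets=["TMDS"], fraction=0.9)
        row_a = fr.benefit_vector(shutoff_model, drain, SUPPLEMENTS)
        row_b = fr.benefit_vector(shutoff_model, tmds, SUPPLEMENTS)
        bt1 = pd.DataFrame([row_a, row_b]).set_axis(["a", "b"])
        bt2 = pd.DataFrame([row_a, row_b * 7.5]).set_axis(["a", "b"])
        r1 = fr.rank_scenarios(bt1, experimental_rescue)
        r2 = fr.rank_scenarios(bt2, experimental_rescue)
        assert list(r1["scenario"]) == list(r2["scenario"])
        assert np.allclose(r1["pearson_r"], r2["pearson_r"])

    def test_folate_drain_beats_random_knockouts(self, shutoff_model,
                                                 baseline_solution,
                                                 experimental_rescue):
        d = 0.5 * baseline_solution.fluxes["SHMT"]
        drain = InhibitionScenario("folate_drain", "cofactor_drain",
                                   charged="mlthf", discharged="thf",
                                   drain_rate=d)
        bt = pd.DataFrame([fr.benefit_vector(shutoff_model, drain, SUPPLEMENTS)])
        ko = fr.enumerate_knockout_benefits(shutoff_model, SUPPLEMENTS)
        ranked = fr.rank_scenarios(pd.concat([bt, ko]), experimental_rescue)
        r_drain = ranked.set_index("scenario").loc["folate_drain", "pearson_r"]
        ko_r = ranked[ranked["scenario"].str.startswith("ko:")]["pearson_r"]
        worse = ((ko_r < r_drain - 1e-9) | ko_r.isna()).mean()
        assert worse >= 0.95
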