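"""Growth scenarios, formate assimilation routes, complex-I limitation
and pathway electron accounting."""

import numpy as np
import pytest

from nitromet.build import RXN_FORMATE_THF_LIGASE, BuildOptions, build_core_model
from nitromet.fba import BoundOverride, FBAError
from nitromet.scenarios import (
    ScenarioSpec,
    compare_formate_assimilation,
    complex_i_limited_formate,
    pathway_electron_cost,
    run_scenario,
    standard_scenarios,
)

from oracles import biomass_electron_content, electron_balance_residual


class TestScenarios:
    def test_scenario_A_reproduces_chemostat_growth(self, calibrated_model):
        res = run_scenario(calibrated_model, standard_scenarios()["A"])
        assert res.status == "optimal"
        assert res.growth == pytest.approx(0.006, rel=0.01)

    def test_all_uptakes_zero_reports_no_growth(self, calibrated_model):
        spec = ScenarioSpec("custom", {"nitrite": 0.0, "formate": 0.0}, ammonia=True)
        res = run_scenario(calibrated_model, spec)  # NGAM cannot be met
        assert res.growth == 0.0
        assert res.status == "infeasible"

    def test_growth_monotone_in_uptake(self, calibrated_model):
        growths = [
            run_scenario(
                calibrated_model,
                ScenarioSpec("custom", {"nitrite": u, "formate": 0.0}, ammonia=True),
            ).growth
            for u in (2.0, 5.0, 8.5)
        ]
        assert growths == sorted(growths)

    def test_mixotrophy_superadditive(self, calibrated_model):
        scen = standard_scenarios()
        gB = run_scenario(calibrated_model, scen["B"]).growth
        gC = run_scenario(calibrated_model, scen["C"]).growth
        gD = run_scenario(calibrated_model, scen["D"]).growth
        assert gD >= max(gB, gC)

    def test_fold_changes_vs_reference(self, calibrated_model):
        scen = standard_scenarios()
        ref = run_scenario(calibrated_model, scen["B"])
        C = run_scenario(calibrated_model, scen["C"], reference=ref)
        D = run_scenario(calibrated_model, scen["D"], reference=ref)
        assert C.fold_vs_reference == pytest.approx(C.growth / ref.growth)
        assert 1.0 < C.fold_vs_reference < D.fold_vs_reference

    def test_electron_balance_on_scenario_solutions(self, calibrated_model):
        """Degree-of-reduction oracle: electrons entering via exchanges
        equal electrons leaving plus electrons fixed into biomass."""
        scen = standard_scenarios()
        content = biomass_electron_content(calibrated_model)
        for label in ("A", "C", "D"):
            res = run_scenario(calibrated_model, scen[label])
            entering = electron_balance_residual(calibrated_model, res.solution)
            assert entering == pytest.approx(res.growth * content, abs=1e-5)


class TestFormateAssimilation:
    def test_rgp_beats_rtca_only(self, calibrated_model):
        cmp_ = compare_formate_assimilation(calibrated_model, 6.0)
        assert cmp_["growth_with_rgp"] >= cmp_["growth_rtca_only"]
        assert cmp_["improvement_percent"] >= 0.0
        assert 0.0 <= cmp_["direct_fraction"] <= 1.0

    def test_direct_fraction_matches_ligase_flux(self, calibrated_model):
        spec = ScenarioSpec("C", {"nitrite": 0.0, "formate": 6.0}, ammonia=True)
        res = run_scenario(calibrated_model, spec)
        assert res.direct_formate_fraction == pytest.approx(
            res.solution.fluxes[RXN_FORMATE_THF_LIGASE] / 6.0
        )

    def test_rgp_absent_improvement_zero(self, line_pairs, nitrite_yield):
        from nitromet.calibration import calibrate

        m0 = build_core_model(options=BuildOptions(rgp_enabled=False))
        m, _ = calibrate(m0, line_pairs, nitrite_yield)
        cmp_ = compare_formate_assimilation(m, 6.0)
        assert cmp_["improvement_percent"] == 0.0
        assert cmp_["direct_fraction"] == 0.0

    def test_zero_formate_rate_rejected(self, calibrated_model):
        with pytest.raises(ValueError):
            compare_formate_assimilation(calibrated_model, 0.0)


class TestComplexILimitation:
    def test_low_growth_requires_secretion(self, calibrated_model):
        sols = complex_i_limited_formate(calibrated_model, 6.0, 0.004)
        assert len(sols) >= 1
        assert all(s.requires_secretion for s in sols)
        for s in sols:
            assert sum(s.secreted.values()) > 1e-6
            # every secreted species is a reduced carbon compound
            for org in s.secreted:
                sp = calibrated_model.get_species(f"{org}_e")
                from oracles import degree_of_reduction

                assert degree_of_reduction(sp.formula, sp.charge) > 0

    def test_electron_closure_with_secretion(self, calibrated_model):
        content = biomass_electron_content(calibrated_model)
        for s in complex_i_limited_formate(calibrated_model, 6.0, 0.004):
            entering = electron_balance_residual(calibrated_model, s.solution)
            mu = s.solution.fluxes["biomass"]
            assert entering == pytest.approx(mu * content, abs=1e-5)

    def test_cap_at_optimum_needs_no_secretion(self, calibrated_model):
        spec = ScenarioSpec("C", {"nitrite": 0.0, "formate": 6.0}, ammonia=True)
        g_opt = run_scenario(calibrated_model, spec).growth
        sols = complex_i_limited_formate(calibrated_model, 6.0, g_opt)
        assert len(sols) == 1
        assert not sols[0].requires_secretion
        assert sols[0].secreted == {}


class TestPathwayElectronCost:
    def test_four_electron_difference(self, model):
        rtca = pathway_electron_cost(model, "rtca_from_co2")
        rgp = pathway_electron_cost(model, "rgp_from_formate")
        assert rtca.electrons - rgp.electrons == pytest.approx(4.0, abs=1e-12)

    def test_route_compared_to_itself_is_zero(self, model):
        a = pathway_electron_cost(model, "rtca_from_co2")
        b = pathway_electron_cost(model, "rtca_from_co2")
        assert a.electrons - b.electrons == 0.0

    def test_ferredoxin_requirement_asymmetry(self, model):
        rtca = pathway_electron_cost(model, "rtca_from_co2")
        rgp = pathway_electron_cost(model, "rgp_from_formate")
        assert rtca.requires_ferredoxin
        assert not rgp.requires_ferredoxin

    def test_route_net_product_is_one_pyruvate(self, model):
        """The route definitions really sum to 1 mol pyruvate."""
        from nitromet.scenarios import ROUTES

        for route, mult in ROUTES.items():
            net = {}
            for rid, k in mult.items():
                for sid, coef in model.get_reaction(rid).stoichiometry.items():
                    net[sid] = net.get(sid, 0.0) + k * coef
            assert net.get("pyr_c", 0.0) == pytest.approx(1.0)
            # pathway intermediates cancel
            for sid in ("oaa_c", "mal_c", "fum_c", "succ_c", "succoa_c",
                        "akg_c", "icit_c", "cit_c", "thf_c", "gly_c", "ser_c"):
                assert net.get(sid, 0.0) == pytest.approx(0.0), (route, sid)

    def test_missing_route_reported(self):
        m = build_core_model(options=BuildOptions(rgp_enabled=False))
        with pytest.raises(FBAError, match="rxn00690"):
            pathway_electron_cost(m, "rgp_from_formate")
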