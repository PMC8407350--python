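"""LP engine: correctness against brute-force vertex enumeration,
steady-state and bound invariants, yields, knockouts, partitions."""

import numpy as np
import pytest

from nitromet.core import ETCStoichiometry, MetabolicModel, Reaction, Species
from nitromet.build import build_core_model
from nitromet.fba import (
    BoundOverride,
    FBAError,
    atp_yield,
    knockout,
    partition_report,
    solve_fba,
)

from oracles import vertex_enumeration_optimum


def _abstract_model(S, lb, ub, objective_idx):
    m, n = S.shape
    species = [Species(f"s{i}", f"s{i}", "cytoplasm", {}) for i in range(m)]
    reactions = []
    for j in range(n):
        stoich = {f"s{i}": float(S[i, j]) for i in range(m) if S[i, j] != 0}
        if not stoich:
            stoich = {"s0": 0.0}
        reactions.append(
            Reaction(f"r{j}", f"r{j}", stoich, float(lb[j]), float(ub[j]))
        )
    return MetabolicModel(species, reactions, f"r{objective_idx}")


def _toy_chain():
    species = [Species("A", "A", "cytoplasm"), Species("B", "B", "cytoplasm")]
    reactions = [
        Reaction("EX_A", "A uptake", {"A": 1.0}, 0.0, 10.0, subsystem="exchange"),
        Reaction("AB", "A->B", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
        Reaction("EX_B", "B export", {"B": -1.0}, 0.0, 1000.0, subsystem="exchange"),
    ]
    return MetabolicModel(species, reactions, "EX_B")


class TestSolver:
    def test_toy_chain_optimum(self):
        sol = solve_fba(_toy_chain())
        assert sol.optimal
        assert sol.objective_value == pytest.approx(10.0, abs=1e-8)

    def test_maintenance_without_substrate_is_infeasible(self):
        species = [Species("atp", "atp", "cytoplasm")]
        reactions = [
            Reaction("SRC", "substrate->atp", {"atp": 1.0}, 0.0, 0.0),
            Reaction("NGAM", "maintenance", {"atp": -1.0}, 0.9, 1000.0),
            Reaction("GROW", "objective", {"atp": -0.1}, 0.0, 1000.0),
        ]
        m = MetabolicModel(species, reactions, "GROW")
        sol = solve_fba(m)
        assert sol.status == "infeasible"
        assert sol.fluxes == {}

    @pytest.mark.parametrize("seed", range(12))
    def test_lp_matches_vertex_enumeration_oracle(self, seed):
        """On random <=6-reaction networks the LP optimum equals the
        brute-force polytope-vertex optimum within 1e-8."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        m = int(rng.integers(1, max(n - 1, 2)))
        S = rng.integers(-2, 3, size=(m, n)).astype(float)
        lb = np.where(rng.random(n) < 0.5, -10.0, 0.0)
        ub = np.full(n, 10.0)
        model = _abstract_model(S, lb, ub, objective_idx=0)
        sol = solve_fba(model, parsimonious=False)
        assert sol.optimal  # v = 0 is always feasible here
        expected = vertex_enumeration_optimum(S, lb, ub, np.eye(n)[0])
        assert sol.objective_value == pytest.approx(expected, abs=1e-8)

    def test_steady_state_and_bounds_invariants(self, calibrated_model):
        ov = [BoundOverride("EX_no2_e", -8.5, -8.5)]
        sol = solve_fba(calibrated_model, ov)
        S = calibrated_model.stoichiometric_matrix()
        v = np.array([sol.fluxes[r] for r in calibrated_model.reaction_ids])
        assert np.max(np.abs(S @ v)) <= 1e-6
        lb, ub = calibrated_model.bounds()
        idx = {rid: i for i, rid in enumerate(calibrated_model.reaction_ids)}
        for o in ov:
            lb[idx[o.reaction_id]], ub[idx[o.reaction_id]] = o.lower, o.upper
        assert np.all(v >= lb - 1e-6) and np.all(v <= ub + 1e-6)
        assert sol.objective_value == pytest.approx(sol.fluxes["biomass"])

    def test_parsimonious_solution_is_sparser(self, model):
        ov = [BoundOverride("EX_no2_e", -8.5, -8.5)]
        plain = solve_fba(model, ov, parsimonious=False)
        pars = solve_fba(model, ov, parsimonious=True)
        assert pars.objective_value == pytest.approx(plain.objective_value, rel=1e-9)
        total = lambda s: sum(abs(x) for x in s.fluxes.values())
        assert total(pars) <= total(plain) + 1e-6

    def test_scale_invariance_without_ngam(self):
        """Doubling all uptake bounds doubles the optimum when NGAM=0."""
        from nitromet.calibration import set_maintenance

        m = set_maintenance(build_core_model(), ngam=0.0)
        g1 = solve_fba(m, [BoundOverride("EX_no2_e", -4.0, -4.0)],
                       parsimonious=False).objective_value
        g2 = solve_fba(m, [BoundOverride("EX_no2_e", -8.0, -8.0)],
                       parsimonious=False).objective_value
        assert g2 == pytest.approx(2 * g1, rel=1e-6)

    def test_unknown_override_rejected(self, model):
        with pytest.raises(FBAError, match="unknown reaction"):
            solve_fba(model, [BoundOverride("nope", 0.0, 0.0)])


class TestYieldAndKnockout:
    def test_nitrite_yield_is_unity(self, model):
        assert atp_yield(model, "nitrite") == pytest.approx(1.0, rel=0.05)

    def test_formate_yield_regression(self, model):
        """Hand P/O bookkeeping with the documented stoichiometry:
        NADH -> complex I (4) + complex III (4) + oxidase (2) = 10
        charges per formate at 4 H+/ATP gives 2.5 ATP per formate."""
        assert atp_yield(model, "formate") == pytest.approx(2.5, abs=1e-6)

    def test_yield_monotone_in_h_per_atp(self):
        y = []
        for h in (4.0, 8.0):
            m = build_core_model(etc=ETCStoichiometry(h_per_atp=h))
            y.append(atp_yield(m, "nitrite"))
        assert y[1] < y[0]

    def test_no_donor_flux_permitted(self, model):
        m = model.copy()
        ex = m.get_reaction("EX_for_e")
        ex.lower_bound = ex.upper_bound = 0.0
        with pytest.raises(FBAError, match="no donor flux"):
            atp_yield(m, "formate")

    def test_knockout_biomass_kills_growth(self, model):
        sol = solve_fba(knockout(model, "biomass"),
                        [BoundOverride("EX_no2_e", -8.5, -8.5)])
        assert (not sol.optimal) or sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_knockout_restore_is_involution(self, model):
        ko = knockout(model, "NUO2M_c0")
        r = ko.get_reaction("NUO2M_c0")
        assert r.lower_bound == r.upper_bound == 0.0
        orig = model.get_reaction("NUO2M_c0")
        r.lower_bound, r.upper_bound = orig.lower_bound, orig.upper_bound
        ov = [BoundOverride("EX_no2_e", -8.5, -8.5)]
        assert solve_fba(ko, ov).objective_value == pytest.approx(
            solve_fba(model, ov).objective_value, rel=1e-9
        )

    def test_knockout_unknown_reaction(self, model):
        with pytest.raises(FBAError):
            knockout(model, "rxn99999_c0")


class TestPartition:
    def test_fractions_sum_to_one(self, calibrated_model):
        sol = solve_fba(calibrated_model, [BoundOverride("EX_no2_e", -8.5, -8.5)])
        rep = partition_report(calibrated_model, sol)
        assert sum(rep.electron_fractions.values()) == pytest.approx(1.0, abs=1e-6)
        assert all(f >= 0 for f in rep.electron_fractions.values())

    def test_formate_only_has_no_nitrite_routing(self, calibrated_model):
        sol = solve_fba(
            calibrated_model,
            [
                BoundOverride("EX_no2_e", 0.0, 0.0),
                BoundOverride("EX_for_e", -6.0, -6.0),
                BoundOverride("EX_nh4_e", -1000.0, 0.0),
            ],
        )
        rep = partition_report(calibrated_model, sol)
        assert rep.reverse_fluxes["NADH"] == pytest.approx(0.0, abs=1e-6)
        assert all(
            f == pytest.approx(0.0, abs=1e-9)
            for f in rep.electron_fractions.values()
        )

    def test_non_optimal_solution_rejected(self, calibrated_model):
        from nitromet.fba import FluxSolution

        with pytest.raises(FBAError):
            partition_report(
                calibrated_model, FluxSolution("infeasible", float("nan"))
            )


class TestCobraCrossCheck:
    def test_sbml_export_agrees_with_cobra_glpk(self, model, tmp_path):
        """Independent solver route: the exported SBML solved by
        COBRApy/GLPK reproduces the in-package HiGHS optimum."""
        cobra = pytest.importorskip("cobra")
        from nitromet.io import write_sbml_model

        path = tmp_path / "model.xml"
        write_sbml_model(model, path)
        cm = cobra.io.read_sbml_model(str(path))
        cm.reactions.get_by_id("EX_no2_e").bounds = (-8.5, -8.5)
        ours = solve_fba(
            model, [BoundOverride("EX_no2_e", -8.5, -8.5)], parsimonious=False
        ).objective_value
        theirs = cm.optimize().objective_value
        assert theirs == pytest.approx(ours, rel=1e-6)
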