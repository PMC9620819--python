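"""Design MILP builder: oracle equivalence for all modes on the fixtures."""

import pytest

from metadesign import (DesignModule, DesignProblem, InterventionCandidate,
                        ModelError, ObjSense, Sense, assemble, fba, fixture,
                        optcouple, optknock, protect, robustknock, solve,
                        suppress)
from metadesign import compute_strain_designs
from metadesign.milp import Status
from oracles import brute_force_mcs, knocked, nested_oracle, region_feasible


def ko_candidates(model, only=None):
    return [InterventionCandidate(r.id) for r in model.reactions
            if only is None or r.id in only]


def mcs_family(solutions):
    return {s.targets for s in solutions}


SUPPRESS_MATRIX = [
    ("coupler6", "R_bio >= 1", 2),
    ("coupler6", "R_bio >= 1", 3),
    ("coupler6", "R_pex >= 1", 2),
    ("chain3", "R3 >= 1", 1),
    ("parallel2", "Rout >= 1", 2),
    ("blocked1", "R3 >= 1", 2),
    ("coupler6", "R_bio >= 1, R_pex <= 0.1", 2),
]


class TestSuppressOracle:
    @pytest.mark.parametrize("name,region,budget", SUPPRESS_MATRIX)
    def test_mcs_equals_brute_force(self, name, region, budget):
        model = fixture(name)
        sols = compute_strain_designs(
            model, modules=[suppress(region, model)],
            candidates=ko_candidates(model), max_cost=budget)
        oracle = brute_force_mcs(model, suppress(region, model).constraints,
                                 [r.id for r in model.reactions], budget)
        assert mcs_family(sols) == oracle
        assert all(s.status == "verified" for s in sols)

    def test_chain_every_link_cuts(self, chain3):
        sols = compute_strain_designs(
            chain3, modules=[suppress("R3 >= 1", chain3)],
            candidates=ko_candidates(chain3), max_cost=1)
        assert mcs_family(sols) == {frozenset({"R1"}), frozenset({"R2"}),
                                    frozenset({"R3"})}

    def test_zero_containing_region_has_no_cut(self, coupler6):
        # the zero flux vector always satisfies R_pex >= 0: no knockout set
        # can exclude it
        sols = compute_strain_designs(
            coupler6, modules=[suppress("R_pex >= 0", coupler6)],
            candidates=ko_candidates(coupler6), max_cost=5)
        assert sols == []

    def test_certificate_and_minimality_witness(self, coupler6):
        mods = [suppress("R_bio >= 1", coupler6)]
        sols = compute_strain_designs(coupler6, modules=mods,
                                      candidates=ko_candidates(coupler6),
                                      max_cost=2)
        for s in sols:
            m = knocked(coupler6, s.targets)
            assert not region_feasible(m, mods[0].constraints)
            for drop in s.targets:
                sub = knocked(coupler6, s.targets - {drop})
                assert region_feasible(sub, mods[0].constraints), \
                    f"{sorted(s.targets)} is not minimal"


NESTED_CASES = [("optknock", 1), ("optknock", 2),
                ("robustknock", 1), ("robustknock", 2),
                ("optcouple", 1), ("optcouple", 2)]


class TestNestedOracle:
    def _modules(self, kind, model):
        if kind == "optknock":
            return [optknock({"R_bio": 1}, {"R_pex": 1}),
                    protect("R_bio >= 1", model)]
        if kind == "robustknock":
            return [robustknock({"R_bio": 1}, {"R_pex": 1}),
                    protect("R_bio >= 1", model)]
        return [optcouple({"R_bio": 1}, "R_pex"), protect("R_bio >= 1", model)]

    @pytest.mark.parametrize("kind,budget", NESTED_CASES)
    def test_optimum_and_optimizers_match_oracle(self, coupler6, kind, budget):
        sols = compute_strain_designs(
            coupler6, modules=self._modules(kind, coupler6),
            candidates=ko_candidates(coupler6), max_cost=budget)
        best, argbest = nested_oracle(
            coupler6, kind, [r.id for r in coupler6.reactions], budget,
            {"R_bio": 1}, {"R_pex": 1}, "R_pex",
            protect_constraints=[protect("R_bio >= 1", coupler6).constraints])
        assert sols, "expected at least one optimal design"
        assert sols[0].objective_value == pytest.approx(best, abs=1e-5)
        assert mcs_family(sols) == argbest
        assert all(s.status == "verified" for s in sols)

    @pytest.mark.parametrize("kind", ["optknock", "robustknock", "optcouple"])
    def test_budget_one_reference_values(self, coupler6, kind):
        sols = compute_strain_designs(
            coupler6, modules=self._modules(kind, coupler6),
            candidates=ko_candidates(coupler6), max_cost=1)
        assert sols[0].targets == {"R_1"}
        assert sols[0].objective_value == pytest.approx(5.0)

    @pytest.mark.parametrize("kind", ["optknock", "robustknock", "optcouple"])
    def test_no_knockouts_gives_zero(self, coupler6, kind):
        mods = self._modules(kind, coupler6)
        best, _ = nested_oracle(coupler6, kind, [], 0, {"R_bio": 1},
                                {"R_pex": 1}, "R_pex")
        assert best == pytest.approx(0.0, abs=1e-5)
        prob = DesignProblem(coupler6, mods, [], 0)
        milp, _ = assemble(prob)
        res = solve(milp)
        assert res.objective_value == pytest.approx(0.0, abs=1e-6)

    def test_strong_duality_residual(self, coupler6):
        """Re-solving the inner LP under the returned interventions must
        reproduce the embedded inner objective value."""
        sols = compute_strain_designs(
            coupler6, modules=self._modules("optknock", coupler6),
            candidates=ko_candidates(coupler6), max_cost=1)
        m = knocked(coupler6, sols[0].targets)
        inner = fba(m, {"R_bio": 1}).objective_value
        assert inner == pytest.approx(5.0, abs=1e-6)

    def test_monotone_in_budget(self, coupler6):
        values = []
        for budget in (1, 2):
            sols = compute_strain_designs(
                coupler6, modules=self._modules("optknock", coupler6),
                candidates=ko_candidates(coupler6), max_cost=budget)
            values.append(sols[0].objective_value)
        assert values[1] >= values[0] - 1e-6

    def test_zero_inner_objective_reduces_to_fba(self, coupler6):
        """With an all-zero inner objective every feasible flux is
        inner-optimal, so optknock degenerates to outer-objective FBA."""
        mods = [DesignModule("optknock", [], {"R_bio": 0.0}, {"R_pex": 1.0})]
        prob = DesignProblem(coupler6, mods,
                             [InterventionCandidate("R_1")], 1)
        milp, _ = assemble(prob)
        res = solve(milp)
        assert res.objective_value == pytest.approx(
            fba(coupler6, {"R_pex": 1}).objective_value)


class TestAssemblyValidation:
    def test_two_nested_modules_rejected(self, coupler6):
        prob = DesignProblem(
            coupler6,
            [optknock({"R_bio": 1}, {"R_pex": 1}),
             optcouple({"R_bio": 1}, "R_pex")],
            ko_candidates(coupler6), 1)
        with pytest.raises(ModelError, match="nested"):
            assemble(prob)

    def test_no_modules_rejected(self, coupler6):
        prob = DesignProblem(coupler6, [], ko_candidates(coupler6), 1)
        with pytest.raises(ModelError, match="no modules"):
            assemble(prob)

    def test_suppress_only_is_cost_minimization(self, coupler6):
        prob = DesignProblem(coupler6, [suppress("R_bio >= 1", coupler6)],
                             ko_candidates(coupler6), 2)
        milp, binaries = assemble(prob)
        sense, obj = milp.objective
        assert sense == ObjSense.MIN and set(obj) == set(binaries.costs)

    def test_budget_below_cheapest_candidate(self, coupler6):
        with pytest.raises(ModelError, match="max_cost"):
            DesignProblem(coupler6, [suppress("R_bio >= 1", coupler6)],
                          [InterventionCandidate("R_1", cost=3.0)], 1).validate()

    def test_missing_inner_objective_rejected(self):
        with pytest.raises(ModelError, match="inner"):
            DesignModule("optknock", [], {}, {"R_pex": 1})

    def test_budget_constraint_enforced(self, coupler6):
        prob = DesignProblem(coupler6, [suppress("R_bio >= 1", coupler6)],
                             ko_candidates(coupler6, {"R_1", "R_3"}), 1)
        milp, _ = assemble(prob)
        # cutting R_bio >= 1 needs both R_1 and R_3 but budget is 1
        assert solve(milp).status == Status.INFEASIBLE


class TestInterventionTypes:
    def test_addition_is_inverse_knockout(self, chain3):
        """A disabled-by-default bypass reaction must be switched on to keep
        the protected phenotype alive after knocking the main route."""
        from metadesign import MetabolicModel, Reaction
        m = MetabolicModel(
            chain3.metabolites,
            [r.copy() for r in chain3.reactions] +
            [Reaction("R_alt", {"A": -1, "B": 1}, 0, 10)],
            dict(chain3.objective), id="chain3_add")
        mods = [suppress("R2 >= 1", m), protect("R3 >= 1", m)]
        cands = [InterventionCandidate("R2"),
                 InterventionCandidate("R_alt", itype="addition")]
        sols = compute_strain_designs(m, modules=mods, candidates=cands,
                                      max_cost=3, use_compression=False)
        # knocking R2 alone starves the protected phenotype; it survives
        # only when the R_alt bypass is added alongside
        assert mcs_family(sols) == {frozenset({"R2", "R_alt"})}
        (sol,) = sols
        assert dict(sol.interventions)["R_alt"] == "addition"
        assert sol.status == "verified"

    def test_regulatory_constraint_switch(self, coupler6):
        """A regulatory cap on uptake suppresses high growth on its own."""
        from metadesign import LinearConstraint
        cap = LinearConstraint({"R_up": 1}, Sense.LE, 2)
        mods = [suppress("R_bio >= 5", coupler6),
                protect("R_bio >= 1", coupler6)]
        cands = [InterventionCandidate(cap, itype="regulatory")]
        sols = compute_strain_designs(coupler6, modules=mods, candidates=cands,
                                      max_cost=1, use_compression=False)
        assert len(sols) == 1
        assert next(iter(sols[0].interventions))[1] == "regulatory"
        assert sols[0].status == "verified"
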