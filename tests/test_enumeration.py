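"""Enumeration pipeline, verification, reporting and the CLI."""

import json

import pytest
from click.testing import CliRunner

from metadesign import (InterventionCandidate, StrainDesignSolution,
                        VoidProblemError, compute_strain_designs, protect,
                        report, suppress, verify_solution)
from metadesign.cli import main as cli_main
from metadesign.design import DesignProblem
from oracles import brute_force_mcs


def ko_candidates(model, only=None):
    return [InterventionCandidate(r.id) for r in model.reactions
            if only is None or r.id in only]


@pytest.fixture
def coupler_problem(coupler6):
    return DesignProblem(coupler6, [suppress("R_bio >= 1", coupler6)],
                         ko_candidates(coupler6), 2)


class TestPipeline:
    def test_mcs_family_and_cost_order(self, coupler6):
        sols = compute_strain_designs(
            coupler6, modules=[suppress("R_bio >= 1", coupler6)],
            candidates=ko_candidates(coupler6), max_cost=2)
        fam = [sorted(s.targets) for s in sols]
        assert fam == [["R_bio"], ["R_up"], ["R_1", "R_3"], ["R_1", "R_pex"]]
        assert [s.cost for s in sols] == [1, 1, 2, 2]

    def test_gene_level_mcs(self, coupler6):
        sols = compute_strain_designs(
            coupler6, modules=[suppress("R_bio >= 1", coupler6)],
            candidates=[InterventionCandidate(g, scope="gene")
                        for g in ("g1", "g2", "g3", "g4")],
            max_cost=4)
        assert {s.targets for s in sols} == {frozenset({"g4"}),
                                             frozenset({"g1", "g2"})}
        oracle = brute_force_mcs(
            coupler6, suppress("R_bio >= 1", coupler6).constraints,
            ["g1", "g2", "g3", "g4"], 4, gene_level=True)
        assert {s.targets for s in sols} == oracle

    def test_compression_does_not_change_solutions(self, coupler6):
        kw = dict(modules=[suppress("R_bio >= 1", coupler6)],
                  candidates=ko_candidates(coupler6), max_cost=2)
        with_c = compute_strain_designs(coupler6, use_compression=True, **kw)
        without = compute_strain_designs(coupler6, use_compression=False, **kw)
        assert {s.targets for s in with_c} == {s.targets for s in without}

    def test_no_returned_solution_is_superset_of_another(self, coupler6):
        sols = compute_strain_designs(
            coupler6, modules=[suppress("R_bio >= 1", coupler6)],
            candidates=ko_candidates(coupler6), max_cost=3)
        fam = [s.targets for s in sols]
        for a in fam:
            for b in fam:
                assert a == b or not a < b

    def test_deterministic_repeat(self, coupler6):
        kw = dict(modules=[suppress("R_bio >= 1", coupler6)],
                  candidates=ko_candidates(coupler6), max_cost=2)
        a = compute_strain_designs(coupler6, **kw)
        b = compute_strain_designs(coupler6, **kw)
        assert [(sorted(s.targets), s.cost) for s in a] == \
               [(sorted(s.targets), s.cost) for s in b]

    def test_max_solutions_truncates(self, coupler6):
        sols = compute_strain_designs(
            coupler6, modules=[suppress("R_bio >= 1", coupler6)],
            candidates=ko_candidates(coupler6), max_cost=2, max_solutions=2)
        assert len(sols) == 2

    def test_void_problem_raises(self, chain3):
        with pytest.raises(VoidProblemError):
            compute_strain_designs(
                chain3, modules=[suppress("R1 >= 1", chain3),
                                 protect("R3 >= 20", chain3)],
                candidates=ko_candidates(chain3), max_cost=1)

    def test_essential_candidates_screened(self, coupler6):
        # R_up and R_bio are essential for the protected phenotype and must
        # not appear in any solution
        sols = compute_strain_designs(
            coupler6, modules=[suppress("R_pex >= 1", coupler6),
                               protect("R_bio >= 1", coupler6)],
            candidates=ko_candidates(coupler6), max_cost=2)
        for s in sols:
            assert not ({"R_up", "R_bio"} & s.targets)
        assert {s.targets for s in sols} == {frozenset({"R_3"}),
                                             frozenset({"R_pex"})}

    def test_allow_non_minimal_flags_solutions(self, coupler6):
        sols = compute_strain_designs(
            coupler6, modules=[suppress("R_bio >= 1", coupler6)],
            candidates=ko_candidates(coupler6), max_cost=2,
            allow_non_minimal=True, max_solutions=3)
        assert sols, "feasibility mode should still return solutions"
        for s in sols:
            assert s.status == "verified"
            assert "minimality" in s.detail

    def test_costs_respected(self, coupler6):
        cands = [InterventionCandidate("R_up", cost=10),
                 InterventionCandidate("R_bio", cost=10),
                 InterventionCandidate("R_1", cost=1),
                 InterventionCandidate("R_3", cost=1),
                 InterventionCandidate("R_pex", cost=1)]
        sols = compute_strain_designs(
            coupler6, modules=[suppress("R_bio >= 1", coupler6)],
            candidates=cands, max_cost=2)
        assert {s.targets for s in sols} == {frozenset({"R_1", "R_3"}),
                                             frozenset({"R_1", "R_pex"})}


class TestVerify:
    def test_valid_cut_verified(self, coupler6, coupler_problem):
        s = StrainDesignSolution(frozenset({("R_up", "knockout")}), 1)
        assert verify_solution(coupler6, coupler_problem, s) == "verified"

    def test_irrelevant_knockout_fails(self, coupler6, coupler_problem):
        s = StrainDesignSolution(frozenset({("R_pex", "knockout")}), 1)
        assert verify_solution(coupler6, coupler_problem, s).startswith(
            "verification_failed")

    def test_nested_objective_recheck(self, coupler6):
        from metadesign import optknock
        prob = DesignProblem(coupler6,
                             [optknock({"R_bio": 1}, {"R_pex": 1}),
                              protect("R_bio >= 1", coupler6)],
                             ko_candidates(coupler6), 1)
        good = StrainDesignSolution(frozenset({("R_1", "knockout")}), 1,
                                    objective_value=5.0)
        assert verify_solution(coupler6, prob, good) == "verified"
        bad = StrainDesignSolution(frozenset({("R_1", "knockout")}), 1,
                                   objective_value=7.0)
        assert verify_solution(coupler6, prob, bad) == \
            "verification_failed:objective_mismatch"


class TestReport:
    def _solutions(self):
        return [StrainDesignSolution(frozenset({("R_up", "knockout")}), 1,
                                     status="verified"),
                StrainDesignSolution(frozenset({("R_1", "knockout"),
                                                ("R_3", "knockout")}), 2,
                                     status="verified")]

    def test_tsv(self, tmp_path):
        p = tmp_path / "out.tsv"
        report(self._solutions(), str(p), "tsv")
        lines = p.read_text().strip().splitlines()
        assert lines[0] == "targets\tcost\tobjective\tstatus"
        assert len(lines) == 3
        assert lines[1].startswith("R_up\t1")
        assert lines[2].startswith("R_1,R_3\t2")

    def test_empty_tsv_has_header(self, tmp_path):
        p = tmp_path / "empty.tsv"
        report([], str(p), "tsv")
        assert p.read_text() == "targets\tcost\tobjective\tstatus\n"

    def test_json_roundtrip(self, tmp_path):
        p = tmp_path / "out.json"
        report(self._solutions(), str(p), "json")
        doc = json.loads(p.read_text())
        assert len(doc) == 2
        assert doc[0]["status"] == "verified"
        assert ["R_up", "knockout"] in doc[0]["interventions"]


class TestCli:
    def test_compute_command(self, tmp_path):
        setup = {"modules": [{"kind": "suppress", "constraints": "R_bio >= 1"}],
                 "candidates": [{"target": t} for t in
                                ("R_up", "R_1", "R_3", "R_bio", "R_pex")],
                 "max_cost": 2}
        sp = tmp_path / "setup.json"
        sp.write_text(json.dumps(setup))
        out = tmp_path / "sols.tsv"
        res = CliRunner().invoke(cli_main, [
            "compute", "--model", "fixture:coupler6", "--setup", str(sp),
            "--out", str(out)])
        assert res.exit_code == 0, res.output
        assert len(out.read_text().strip().splitlines()) == 5

    def test_compute_void_problem_exit_2(self, tmp_path):
        setup = {"modules": [{"kind": "suppress", "constraints": "R1 >= 1"},
                             {"kind": "protect", "constraints": "R3 >= 20"}],
                 "candidates": [{"target": "R1"}], "max_cost": 1}
        sp = tmp_path / "setup.json"
        sp.write_text(json.dumps(setup))
        res = CliRunner().invoke(cli_main, [
            "compute", "--model", "fixture:chain3", "--setup", str(sp),
            "--out", str(tmp_path / "x.tsv")])
        assert res.exit_code == 2

    def test_analyze_fba(self):
        res = CliRunner().invoke(cli_main, [
            "analyze", "--model", "fixture:chain3", "--mode", "fba",
            "--objective", "R3"])
        assert res.exit_code == 0
        assert res.output.splitlines()[0] == "objective\t5"

    def test_analyze_yield(self):
        res = CliRunner().invoke(cli_main, [
            "analyze", "--model", "fixture:coupler6", "--mode", "yield",
            "--numerator", "R_pex", "--denominator", "R_up",
            "--constraints", "R_bio >= 1"])
        assert res.exit_code == 0
        assert "0.5" in res.output

    def test_plot_command(self, tmp_path):
        out = tmp_path / "env.svg"
        tsv = tmp_path / "env.tsv"
        res = CliRunner().invoke(cli_main, [
            "plot", "--model", "fixture:coupler6", "--axes", "R_bio,R_pex",
            "--out", str(out), "--tsv", str(tsv)])
        assert res.exit_code == 0, res.output
        assert out.exists() and tsv.read_text().startswith("axis1")

    def test_nested_setup_file(self, tmp_path):
        setup = {"modules": [
            {"kind": "optknock", "inner_objective": "R_bio",
             "outer_objective": "R_pex"},
            {"kind": "protect", "constraints": "R_bio >= 1"}],
            "candidates": [{"target": t} for t in
                           ("R_up", "R_1", "R_3", "R_bio", "R_pex")],
            "max_cost": 1}
        sp = tmp_path / "setup.json"
        sp.write_text(json.dumps(setup))
        out = tmp_path / "sols.json"
        res = CliRunner().invoke(cli_main, [
            "compute", "--model", "fixture:coupler6", "--setup", str(sp),
            "--out", str(out), "--format", "json"])
        assert res.exit_code == 0, res.output
        doc = json.loads(out.read_text())
        assert doc[0]["objective_value"] == pytest.approx(5.0)
        assert doc[0]["status"] == "verified"
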