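"""Solution enumeration pipeline, verification and reporting.

``compute_strain_designs`` runs the standardized pipeline: optional GPR
integration (when gene-scope candidates are present), FVA essentiality
screening of knockout candidates against every protected phenotype, network
compression, MILP assembly, iterative solving with exclusion cuts, back
expansion of solutions to the original namespace, and an independent LP
re-verification of every reported solution against the un-reformulated
module definitions.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from . import design as dz
from .analysis import InfeasibleError, fba, steady_state_lp, _lp_optimize
from .compress import (CompressionRecord, compress, expand_solutions,
                       screen_essentials, translate_constraint)
from .design import (Binaries, DesignModule, DesignProblem,
                     InterventionCandidate, assemble)
from .gpr import GprExtension, integrate_gpr
from .milp import (MILPProblem, ObjSense, Status, add_exclusion_cut, solve)
from .model import LinearConstraint, MetabolicModel, ModelError, Sense

__all__ = ["StrainDesignSolution", "compute_strain_designs",
           "verify_solution", "report", "VoidProblemError"]

log = logging.getLogger("metadesign")

OPT_TOL = 1e-6


class VoidProblemError(RuntimeError):
    """A protected region is infeasible before any intervention."""


@dataclass
class StrainDesignSolution:
    interventions: FrozenSet[Tuple[str, str]]  # (target label, itype)
    cost: float
    objective_value: Optional[float] = None
    status: str = "feasible"   # optimal | feasible | verified | verification_failed
    namespace: str = "original"
    detail: str = ""

    @property
    def targets(self) -> FrozenSet[str]:
        return frozenset(t for t, _ in self.interventions)

    def sort_key(self):
        return (self.cost, tuple(sorted(self.targets)))


# ---------------------------------------------------------------------------
# Verification (independent LP re-checks on the original model)
# ---------------------------------------------------------------------------

def _apply_interventions(model: MetabolicModel, problem: DesignProblem,
                         solution: StrainDesignSolution) -> Tuple[
                             MetabolicModel, List[LinearConstraint]]:
    """Fresh model with the solution's interventions applied literally."""
    m = model.copy()
    chosen = {(t, it) for t, it in solution.interventions}
    knocked_genes = {t for t, it in chosen
                     if it == "knockout" and t in model.genes()}
    extra: List[LinearConstraint] = []
    for cand in problem.candidates:
        picked = (cand.label, cand.itype) in chosen
        if cand.itype == "knockout":
            if picked and cand.label not in knocked_genes:
                r = m.reaction(cand.target)
                r.lb = r.ub = 0
        elif cand.itype == "addition":
            if not picked:
                r = m.reaction(cand.target)
                r.lb = r.ub = 0
        elif picked:  # regulatory
            extra.append(cand.target.copy())
    if knocked_genes:
        for r in m.reactions:
            if not r.gpr.is_empty and not r.gpr.evaluate(knocked_genes):
                r.lb = r.ub = 0
    return m, extra


def _inner_face_value(model, extra, inner_obj, outer_obj, sense: ObjSense):
    """(inner optimum, outer value optimized over the inner-optimal face)."""
    inner = fba(model, inner_obj, extra=list(extra))
    fix = LinearConstraint(dict(inner_obj), Sense.GE, inner.objective_value - OPT_TOL)
    outer = fba(model, outer_obj, extra=list(extra) + [fix], sense=sense)
    return inner.objective_value, outer.objective_value


def verify_solution(model: MetabolicModel, problem: DesignProblem,
                    solution: StrainDesignSolution) -> str:
    """LP re-check of every module under the applied interventions."""
    m, extra = _apply_interventions(model, problem, solution)
    for module in problem.modules:
        cons = [c.copy() for c in module.constraints]
        if module.kind == "protect":
            try:
                fba(m, {}, extra=extra + cons)
            except InfeasibleError:
                return "verification_failed:protect"
        elif module.kind == "suppress":
            try:
                fba(m, {}, extra=extra + cons)
                return "verification_failed:suppress"
            except InfeasibleError:
                pass
        else:
            try:
                if module.kind == "optknock":
                    _, outer = _inner_face_value(m, extra + cons,
                                                 module.inner_objective,
                                                 module.outer_objective,
                                                 ObjSense.MAX)
                elif module.kind == "robustknock":
                    _, outer = _inner_face_value(m, extra + cons,
                                                 module.inner_objective,
                                                 module.outer_objective,
                                                 ObjSense.MIN)
                else:  # optcouple
                    with_p = fba(m, module.inner_objective, extra=extra + cons)
                    zero = LinearConstraint({module.prod_id: 1}, Sense.EQ, 0)
                    try:
                        wo = fba(m, module.inner_objective,
                                 extra=extra + cons + [zero]).objective_value
                    except InfeasibleError:
                        wo = 0.0
                    outer = with_p.objective_value - wo
            except InfeasibleError:
                return "verification_failed:nested_infeasible"
            if solution.objective_value is not None and \
                    abs(outer - solution.objective_value) > 1e-5:
                return "verification_failed:objective_mismatch"
    return "verified"


def _minimality_witness(model, problem, solution) -> bool:
    """Each single-intervention removal must break some module requirement."""
    if len(solution.interventions) <= 1:
        return True
    for drop in solution.interventions:
        sub = StrainDesignSolution(solution.interventions - {drop}, 0)
        ok = verify_solution(model, problem, sub)
        if ok == "verified":
            return False
    return True


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _resolve_genes(problem: DesignProblem
                   ) -> Tuple[MetabolicModel, Optional[GprExtension],
                              List[InterventionCandidate], Dict[str, str]]:
    """GPR-extend the model when gene candidates are present."""
    gene_cands = [c for c in problem.candidates if c.scope == "gene"]
    if not gene_cands:
        return problem.model, None, list(problem.candidates), {}
    ext = integrate_gpr(problem.model)
    candidates = []
    back: Dict[str, str] = {}
    for c in problem.candidates:
        if c.scope == "gene":
            if c.itype != "knockout":
                raise ModelError("gene candidates support knockout only")
            if c.target not in ext.gene_targets:
                raise ModelError(f"unknown gene {c.target!r}")
            rid = ext.gene_targets[c.target]
            back[rid] = c.target
            candidates.append(InterventionCandidate(rid, "knockout", c.cost))
        else:
            candidates.append(c)
    return ext.extended_model, ext, candidates, back


def compute_strain_designs(model: MetabolicModel,
                           problem: Optional[DesignProblem] = None,
                           *, modules=None, candidates=None, max_cost=None,
                           max_solutions: int = 1000,
                           backend: Optional[str] = None,
                           time_limit: Optional[float] = None,
                           use_compression: bool = True,
                           allow_non_minimal: bool = False,
                           verify: bool = True
                           ) -> List[StrainDesignSolution]:
    """Run the full design pipeline and return solutions in cost order."""
    if problem is None:
        problem = DesignProblem(model, list(modules), list(candidates),
                                max_cost if max_cost is not None else 1e9,
                                max_solutions=max_solutions,
                                allow_non_minimal=allow_non_minimal)
    problem.validate()
    t0 = time.time()

    work_model, ext, candidates, gene_back = _resolve_genes(problem)

    # translate module constraints onto the (possibly GPR-extended) model
    modules = [DesignModule(m.kind, [c.copy() for c in m.constraints],
                            dict(m.inner_objective), dict(m.outer_objective),
                            m.prod_id)
               for m in problem.modules]

    # essentiality screening against every protected phenotype
    essential: Set[str] = set()
    for m in modules:
        if m.kind == "protect":
            try:
                essential |= screen_essentials(work_model, m.constraints)
            except InfeasibleError as exc:
                raise VoidProblemError(str(exc)) from exc
    kept: List[InterventionCandidate] = []
    for c in candidates:
        if c.itype == "knockout" and c.target in essential:
            log.info("dropping essential knockout candidate %s", c.target)
            continue
        kept.append(c)
    candidates = kept
    log.info("screening done (%.2fs); %d candidates", time.time() - t0, len(candidates))

    # compression: ids referenced by constraints/objectives stay atomic
    record: Optional[CompressionRecord] = None
    knockable = {c.target for c in candidates if c.itype == "knockout"}
    costs = {c.target if isinstance(c.target, str) else c.label: c.cost
             for c in candidates}
    if use_compression:
        protected: Set[str] = set()
        for m in modules:
            for c in m.constraints:
                protected |= set(c.coeffs)
            protected |= set(m.inner_objective) | set(m.outer_objective)
            if m.prod_id:
                protected.add(m.prod_id)
        for c in candidates:
            if c.itype == "regulatory":
                protected |= set(c.target.coeffs)
            elif c.itype == "addition":
                protected.add(c.target)
        protected |= set(gene_back)
        comp_model, record = compress(work_model, protected=protected)
        # rebuild candidate list in compressed namespace
        comp_cands: List[InterventionCandidate] = []
        step_of = {s.new_id: s for s in record.steps if s.new_id}
        for r in comp_model.reactions:
            kind = record.kind_of[r.id]
            if kind == "plain":
                continue
            alts = expand_solutions(record, [[r.id]], costs, knockable)
            if not alts:
                continue
            cost = min(c for _, c in alts)
            comp_cands.append(InterventionCandidate(r.id, "knockout", cost))
        for c in candidates:
            if c.itype == "knockout":
                if c.target in record.membership and \
                        record.kind_of[c.target] == "plain":
                    comp_cands.append(c)
            else:
                comp_cands.append(c)
        comp_modules = []
        for m in modules:
            comp_modules.append(DesignModule(
                m.kind, [translate_constraint(c, record) for c in m.constraints],
                dict(m.inner_objective), dict(m.outer_objective), m.prod_id))
        solve_model, solve_modules, solve_cands = comp_model, comp_modules, comp_cands
    else:
        solve_model, solve_modules, solve_cands = work_model, modules, candidates
    log.info("compression done (%.2fs); %d reactions", time.time() - t0,
             len(solve_model.reactions))

    milp_problem = DesignProblem(solve_model, solve_modules, solve_cands,
                                 problem.max_cost,
                                 max_solutions=problem.max_solutions,
                                 allow_non_minimal=allow_non_minimal)
    if not solve_cands:
        return []
    milp, binaries = assemble(milp_problem)
    nested = milp_problem.nested_module is not None
    if allow_non_minimal and not nested:
        milp.objective = (ObjSense.MIN, {})

    # solve loop with exclusion cuts
    raw: List[Tuple[FrozenSet[str], float]] = []  # (compressed target set, objective)
    best_value: Optional[float] = None
    deadline = time.time() + time_limit if time_limit else None
    truncated = False
    for it in range(max(1, problem.max_solutions)):
        tl = None
        if deadline is not None:
            tl = max(0.5, deadline - time.time())
        res = solve(milp, backend=backend, time_limit=tl)
        if res.status in (Status.TIME_LIMIT_FEASIBLE, Status.TIME_LIMIT_NO_SOLUTION):
            truncated = True
            break
        if not res.optimal:
            break
        support = frozenset(
            z for z in binaries.costs if res.assignment.get(z, 0) > 0.5)
        if nested:
            if best_value is None:
                best_value = res.objective_value
                # fix the outer objective at its optimum (float-safe slack)
                milp.add_constraint(dict(milp.objective[1]), Sense.GE,
                                    best_value - OPT_TOL)
            elif res.objective_value < best_value - OPT_TOL:
                break
        raw.append((support, res.objective_value))
        if not support:
            break  # the empty intervention set solves the problem
        add_exclusion_cut(milp, support)
    log.info("enumeration done (%.2fs); %d raw solutions", time.time() - t0, len(raw))

    # expansion to original namespace
    zlabel = {}
    for i, c in enumerate(milp_problem.candidates):
        zname = binaries.by_candidate[i]
        zlabel[zname] = (c.target if isinstance(c.target, str) else c.label,
                         c.itype)
    solutions: List[StrainDesignSolution] = []
    seen: Set[FrozenSet[Tuple[str, str]]] = set()
    for support, objective in raw:
        ko_targets = [zlabel[z][0] for z in support if zlabel[z][1] == "knockout"]
        others = [zlabel[z] for z in support if zlabel[z][1] != "knockout"]
        if record is not None:
            expanded = expand_solutions(record, [ko_targets], costs, knockable)
        else:
            expanded = [(frozenset(ko_targets),
                         sum(costs.get(t, 1.0) for t in ko_targets))]
        for targets, cost in expanded:
            named = frozenset((gene_back.get(t, t), "knockout") for t in targets) \
                | frozenset(others)
            if named in seen:
                continue
            seen.add(named)
            full_cost = cost + sum(
                next(c.cost for c in problem.candidates
                     if c.itype == it and c.label == t)
                for t, it in others) if others else cost
            solutions.append(StrainDesignSolution(
                named, full_cost,
                objective_value=objective if nested else None,
                status="optimal" if not truncated else "feasible"))

    # drop supersets that can arise from cross-solution expansion
    solutions.sort(key=lambda s: s.sort_key())
    pruned: List[StrainDesignSolution] = []
    if not nested and not allow_non_minimal:
        kept_sets: List[FrozenSet] = []
        for s in solutions:
            if any(k < s.interventions for k in kept_sets):
                continue
            kept_sets.append(s.interventions)
            pruned.append(s)
        solutions = pruned

    # independent verification
    if verify:
        for s in solutions:
            status = verify_solution(problem.model, problem, s)
            if status == "verified" and not nested and not allow_non_minimal:
                if not _minimality_witness(problem.model, problem, s):
                    status = "verification_failed:non_minimal"
            s.status = status if status != "verified" else "verified"
            if allow_non_minimal and s.status == "verified":
                s.detail = "minimality not checked (allow_non_minimal)"
    log.info("pipeline finished (%.2fs); %d solutions", time.time() - t0,
             len(solutions))
    return solutions


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def report(solutions: Sequence[StrainDesignSolution], path: str,
           fmt: str = "tsv") -> None:
    """Write solutions as TSV (one per line) or a structured JSON document."""
    solutions = sorted(solutions, key=lambda s: s.sort_key())
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("targets\tcost\tobjective\tstatus\n")
            for s in solutions:
                tgt = ",".join(sorted(s.targets))
                obj = "" if s.objective_value is None else f"{s.objective_value:.6g}"
                fh.write(f"{tgt}\t{s.cost:g}\t{obj}\t{s.status}\n")
    elif fmt == "json":
        doc = [{"interventions": sorted([t, it] for t, it in s.interventions),
                "cost": s.cost, "objective_value": s.objective_value,
                "status": s.status, "namespace": s.namespace,
                "detail": s.detail}
               for s in solutions]
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
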