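"""Independent brute-force oracles used by the test suite.

Every design mode is re-evaluated here by exhaustive enumeration over all
candidate subsets within budget, scoring each subset with plain LPs on a
knocked-out copy of the model.  These routines never touch the MILP
builder; they are the ground truth the MILP answers are compared against.
"""

from __future__ import annotations

import itertools
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from metadesign import (InfeasibleError, LinearConstraint, MetabolicModel,
                        ObjSense, Sense, fba, parse_linear_constraints)

TOL = 1e-6


def knocked(model: MetabolicModel, kos: Iterable[str]) -> MetabolicModel:
    m = model.copy()
    for rid in kos:
        r = m.reaction(rid)
        r.lb = r.ub = 0
    return m


def gene_knocked(model: MetabolicModel, genes: Iterable[str]) -> MetabolicModel:
    m = model.copy()
    genes = set(genes)
    for r in m.reactions:
        if not r.gpr.is_empty and not r.gpr.evaluate(genes):
            r.lb = r.ub = 0
    return m


def region_feasible(model: MetabolicModel, constraints) -> bool:
    try:
        fba(model, {}, extra=constraints)
        return True
    except InfeasibleError:
        return False


def _subsets(candidates: Sequence[str], max_cost: float,
             costs: Optional[Dict[str, float]] = None):
    costs = costs or {}
    for n in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, n):
            if sum(costs.get(c, 1.0) for c in combo) <= max_cost + TOL:
                yield frozenset(combo)


def minimal_sets(family: Iterable[FrozenSet[str]]) -> Set[FrozenSet[str]]:
    fam = sorted(set(family), key=len)
    out: List[FrozenSet[str]] = []
    for s in fam:
        if not any(t < s for t in out):
            out.append(s)
    return set(out)


def brute_force_mcs(model: MetabolicModel, suppress_constraints,
                    candidates: Sequence[str], max_cost: float,
                    costs: Optional[Dict[str, float]] = None,
                    gene_level: bool = False) -> Set[FrozenSet[str]]:
    """All inclusion-minimal cut sets within budget (LP feasibility oracle)."""
    cuts = []
    for subset in _subsets(candidates, max_cost, costs):
        m = gene_knocked(model, subset) if gene_level else knocked(model, subset)
        if not region_feasible(m, suppress_constraints):
            cuts.append(subset)
    return minimal_sets(cuts)


def _inner_face(model, extra, inner_obj, outer_obj, sense):
    inner = fba(model, inner_obj, extra=list(extra))
    fix = LinearConstraint(dict(inner_obj), Sense.GE,
                           inner.objective_value - TOL)
    outer = fba(model, outer_obj, extra=list(extra) + [fix], sense=sense)
    return inner.objective_value, outer.objective_value


def nested_value(model: MetabolicModel, kind: str, kos: FrozenSet[str],
                 inner_obj: Dict[str, float],
                 outer_obj: Optional[Dict[str, float]] = None,
                 prod_id: Optional[str] = None,
                 protect_constraints=()) -> Optional[float]:
    """Objective of one knockout set under a nested design mode.

    Returns None when a protected region is infeasible (subset inadmissible).
    optknock: max outer over the inner-optimal face (optimistic);
    robustknock: min outer over the face (worst case);
    optcouple: inner optimum with production minus with production forced 0.
    """
    m = knocked(model, kos)
    for cons in protect_constraints:
        if not region_feasible(m, cons):
            return None
    try:
        if kind == "optknock":
            _, v = _inner_face(m, [], inner_obj, outer_obj, ObjSense.MAX)
            return v
        if kind == "robustknock":
            _, v = _inner_face(m, [], inner_obj, outer_obj, ObjSense.MIN)
            return v
        if kind == "optcouple":
            with_p = fba(m, inner_obj).objective_value
            zero = LinearConstraint({prod_id: 1}, Sense.EQ, 0)
            try:
                without = fba(m, inner_obj, extra=[zero]).objective_value
            except InfeasibleError:
                without = 0.0
            return with_p - without
    except InfeasibleError:
        return None
    raise ValueError(kind)


def nested_oracle(model, kind, candidates, max_cost, inner_obj,
                  outer_obj=None, prod_id=None, protect_constraints=(),
                  costs=None) -> Tuple[float, Set[FrozenSet[str]]]:
    """(optimal value, inclusion-minimal optimal knockout sets)."""
    best = None
    values: Dict[FrozenSet[str], float] = {}
    for subset in _subsets(candidates, max_cost, costs):
        v = nested_value(model, kind, subset, inner_obj, outer_obj, prod_id,
                         protect_constraints)
        if v is None:
            continue
        values[subset] = v
        if best is None or v > best + TOL:
            best = v
    optimal = [s for s, v in values.items() if abs(v - best) <= 1e-5]
    return best, minimal_sets(optimal)
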