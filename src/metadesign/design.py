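"""Translate design modules into one solver-ready MILP.

Design problems combine *suppress* and *protect* flux regions with at most
one nested bi-level module (OptKnock, RobustKnock or OptCouple) over a
shared vector of intervention binaries (knockouts, additions = inverse
knockouts, regulatory constraint switches).

The builder works on an intermediate representation of linear rows whose
right-hand sides are affine in the intervention binaries ("affine rows"):
a knockout binary scales a reaction's bounds to zero, an addition binary
scales them up from zero, a regulatory binary tightens a big-M-slacked
constraint.  Every block is then one of three standard LP transformations:

* protect:   the affine rows are emitted directly as a primal flux copy;
* suppress:  a Farkas infeasibility certificate of the region is emitted --
  the dual multipliers of the affine rows, the homogeneous column
  equations, and the normalized negativity condition (certificate value
  <= -1); products of binaries with dual variables in the certificate
  value are linearized exactly through gated auxiliary variables;
* nested:    the inner LP is collapsed by strong duality (primal copy +
  dual block + zero-gap equality).  RobustKnock applies the dualization
  twice: the adversarial minimization over the inner-optimal face is an LP
  in the face variables *and* the first-stage duals, and its dual provides
  the max-min certificate that the outer MILP maximizes.

All gated products use indicator constraints; the solver backend rewrites
them with tight big-M terms when the selected solver has no native
indicator support.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

from .milp import (IndicatorConstraint, MILPProblem, ObjSense, VarDef, VarKind)
from .model import (LinearConstraint, MetabolicModel, ModelError, Sense,
                    parse_linear_constraints)

__all__ = [
    "DesignModule", "InterventionCandidate", "DesignProblem",
    "suppress", "protect", "optknock", "robustknock", "optcouple",
    "assemble", "link_interventions", "DUAL_BOUND",
]

DUAL_BOUND = 1e3
EPS_CERT = 1.0  # Farkas certificate normalization: value <= -EPS_CERT


# ---------------------------------------------------------------------------
# Problem description types
# ---------------------------------------------------------------------------

NESTED_KINDS = ("optknock", "robustknock", "optcouple")


@dataclass
class DesignModule:
    kind: str
    constraints: List[LinearConstraint] = field(default_factory=list)
    inner_objective: Dict[str, float] = field(default_factory=dict)
    outer_objective: Dict[str, float] = field(default_factory=dict)
    prod_id: Optional[str] = None

    def __post_init__(self):
        if self.kind not in ("suppress", "protect") + NESTED_KINDS:
            raise ModelError(f"unknown design module kind {self.kind!r}")
        if self.kind in NESTED_KINDS and not self.inner_objective:
            raise ModelError(f"{self.kind} module requires an inner objective")
        if self.kind in ("optknock", "robustknock") and not self.outer_objective:
            raise ModelError(f"{self.kind} module requires an outer objective")
        if self.kind == "optcouple" and not self.prod_id:
            raise ModelError("optcouple module requires prod_id")

    def validate(self, model: MetabolicModel):
        for c in self.constraints:
            c.validate(model)
        for coeffs in (self.inner_objective, self.outer_objective):
            for rid in coeffs:
                model.reaction(rid)
        if self.prod_id:
            model.reaction(self.prod_id)


def suppress(constraints, model=None) -> DesignModule:
    return DesignModule("suppress", _cons(constraints, model))


def protect(constraints, model=None) -> DesignModule:
    return DesignModule("protect", _cons(constraints, model))


def optknock(inner_objective, outer_objective, constraints=(), model=None) -> DesignModule:
    return DesignModule("optknock", _cons(constraints, model),
                        dict(inner_objective), dict(outer_objective))


def robustknock(inner_objective, outer_objective, constraints=(), model=None) -> DesignModule:
    return DesignModule("robustknock", _cons(constraints, model),
                        dict(inner_objective), dict(outer_objective))


def optcouple(inner_objective, prod_id, constraints=(), model=None) -> DesignModule:
    return DesignModule("optcouple", _cons(constraints, model),
                        dict(inner_objective), prod_id=prod_id)


def _cons(constraints, model):
    if isinstance(constraints, str):
        return parse_linear_constraints(constraints, model)
    return [c.copy() for c in constraints]


@dataclass
class InterventionCandidate:
    target: Union[str, LinearConstraint]
    itype: str = "knockout"  # knockout | addition | regulatory
    cost: float = 1.0
    scope: str = "reaction"  # reaction | gene

    def __post_init__(self):
        if self.itype not in ("knockout", "addition", "regulatory"):
            raise ModelError(f"unknown intervention type {self.itype!r}")
        if self.cost <= 0:
            raise ModelError("intervention cost must be positive")
        if self.itype == "regulatory" and not isinstance(self.target, LinearConstraint):
            raise ModelError("regulatory candidate requires a LinearConstraint target")

    @property
    def label(self) -> str:
        if isinstance(self.target, LinearConstraint):
            from .model import format_constraint
            return format_constraint(self.target)
        return str(self.target)


@dataclass
class DesignProblem:
    model: MetabolicModel
    modules: List[DesignModule]
    candidates: List[InterventionCandidate]
    max_cost: float = 1e9
    solution_approach: str = "best"   # any | best | populate
    max_solutions: int = 1000
    time_limit: Optional[float] = None
    allow_non_minimal: bool = False

    def validate(self):
        if not self.modules:
            raise ModelError("design problem has no modules")
        nested = [m for m in self.modules if m.kind in NESTED_KINDS]
        if len(nested) > 1:
            raise ModelError("at most one nested optimization module is allowed")
        for m in self.modules:
            m.validate(self.model)
        seen = set()
        for c in self.candidates:
            key = (c.itype, c.label)
            if key in seen:
                raise ModelError(f"duplicate intervention candidate {key}")
            seen.add(key)
            if c.scope == "gene":
                if c.itype != "knockout":
                    raise ModelError("gene candidates support knockout only")
                if c.target not in self.model.genes():
                    raise ModelError(f"unknown gene {c.target!r}")
            elif c.itype != "regulatory":
                self.model.reaction(c.target)
            else:
                c.target.validate(self.model)
        if self.candidates and self.max_cost < min(c.cost for c in self.candidates):
            raise ModelError("max_cost is below the cheapest candidate")

    @property
    def nested_module(self) -> Optional[DesignModule]:
        for m in self.modules:
            if m.kind in NESTED_KINDS:
                return m
        return None


# ---------------------------------------------------------------------------
# Affine rows
# ---------------------------------------------------------------------------

@dataclass
class AffineRow:
    """``sum coeffs*x  (sense)  const + sum zlin*z`` with z binary."""
    coeffs: Dict[str, float]
    sense: Sense
    const: float
    zlin: Dict[str, float] = field(default_factory=dict)

    def negated(self) -> "AffineRow":
        return AffineRow({k: -v for k, v in self.coeffs.items()},
                         Sense.GE if self.sense == Sense.LE else Sense.LE,
                         -self.const, {k: -v for k, v in self.zlin.items()})


@dataclass
class AffineLP:
    sense: ObjSense
    objective: Dict[str, float]
    var_sign: Dict[str, str]  # name -> 'free' | 'nonneg'
    rows: List[AffineRow]


@dataclass
class Fragment:
    """A set of MILP pieces sharing the global binary vector."""
    variables: Dict[str, VarDef] = field(default_factory=dict)
    rows: List[AffineRow] = field(default_factory=list)
    indicators: List[IndicatorConstraint] = field(default_factory=list)

    def merge(self, other: "Fragment"):
        for name, vd in other.variables.items():
            if name in self.variables:
                raise ModelError(f"fragment variable collision {name!r}")
            self.variables[name] = vd
        self.rows.extend(other.rows)
        self.indicators.extend(other.indicators)


def _emit(problem: MILPProblem, frag: Fragment):
    for name, vd in frag.variables.items():
        problem.add_var(name, vd.kind, vd.lb, vd.ub)
    for row in frag.rows:
        coeffs = dict(row.coeffs)
        for b, a in row.zlin.items():
            coeffs[b] = coeffs.get(b, 0.0) - a
        problem.add_constraint(coeffs, row.sense, row.const)
    problem.ind_constraints.extend(frag.indicators)


# ---------------------------------------------------------------------------
# Intervention linkage
# ---------------------------------------------------------------------------

@dataclass
class Binaries:
    by_candidate: Dict[int, str]                 # candidate index -> z name
    knockouts: Dict[str, str]                    # reaction id -> z name
    additions: Dict[str, str]                    # reaction id -> z name
    regulatory: List[Tuple[str, LinearConstraint]]  # (z name, constraint)
    costs: Dict[str, float]                      # z name -> cost


def link_interventions(problem: DesignProblem) -> Tuple[Binaries, Fragment]:
    """Create one binary per candidate plus the budget constraint."""
    problem.validate()
    frag = Fragment()
    by_candidate, knockouts, additions, regulatory, costs = {}, {}, {}, [], {}
    import re as _re
    for i, cand in enumerate(problem.candidates):
        if cand.scope == "gene":
            raise ModelError(
                "gene candidates must be resolved through a GPR extension "
                "before MILP assembly")
        z = "z::%s::%s" % (cand.itype[:3], _re.sub(r"[^\w.\-]+", "_", cand.label))
        frag.variables[z] = VarDef(VarKind.BINARY, 0, 1)
        by_candidate[i] = z
        costs[z] = float(cand.cost)
        if cand.itype == "knockout":
            knockouts[cand.target] = z
        elif cand.itype == "addition":
            additions[cand.target] = z
        else:
            regulatory.append((z, cand.target))
    if costs:
        frag.rows.append(AffineRow({z: c for z, c in costs.items()},
                                   Sense.LE, float(problem.max_cost)))
    return Binaries(by_candidate, knockouts, additions, regulatory, costs), frag


# ---------------------------------------------------------------------------
# Flux-region rows (shared by primal copies, Farkas blocks, inner LPs)
# ---------------------------------------------------------------------------

def _expr_range(model: MetabolicModel, coeffs: Mapping[str, float],
                upper: bool) -> float:
    total = 0.0
    for rid, a in coeffs.items():
        r = model.reaction(rid)
        a = float(a)
        total += a * float(r.ub if (a > 0) == upper else r.lb)
    return total


def region_rows(model: MetabolicModel, prefix: str, binaries: Binaries,
                constraints: Sequence[LinearConstraint],
                extra_rows: Sequence[AffineRow] = ()
                ) -> Tuple[Dict[str, str], List[AffineRow]]:
    """Steady state + intervention-gated bounds + module + regulatory rows.

    Variables are named ``{prefix}.{reaction id}`` and declared free; all
    bounds appear as rows so the system can be dualized.
    """
    v = lambda rid: f"{prefix}.{rid}"
    var_sign = {v(r.id): "free" for r in model.reactions}
    rows: List[AffineRow] = []
    for m in model.metabolites:
        coeffs = {v(r.id): float(r.stoich[m.id])
                  for r in model.reactions if m.id in r.stoich}
        if coeffs:
            rows.append(AffineRow(coeffs, Sense.EQ, 0.0))
    for r in model.reactions:
        ub, lb = float(r.ub), float(r.lb)
        if r.id in binaries.knockouts:
            z = binaries.knockouts[r.id]
            rows.append(AffineRow({v(r.id): 1.0}, Sense.LE, ub, {z: -ub}))
            rows.append(AffineRow({v(r.id): 1.0}, Sense.GE, lb, {z: -lb}))
        elif r.id in binaries.additions:
            z = binaries.additions[r.id]
            rows.append(AffineRow({v(r.id): 1.0}, Sense.LE, 0.0, {z: ub}))
            rows.append(AffineRow({v(r.id): 1.0}, Sense.GE, 0.0, {z: lb}))
        else:
            rows.append(AffineRow({v(r.id): 1.0}, Sense.LE, ub))
            rows.append(AffineRow({v(r.id): 1.0}, Sense.GE, lb))
    for c in constraints:
        rows.append(AffineRow({v(k): float(a) for k, a in c.coeffs.items()},
                              c.sense, float(c.rhs)))
    for z, c in binaries.regulatory:
        senses = [c.sense] if c.sense != Sense.EQ else [Sense.LE, Sense.GE]
        for sense in senses:
            coeffs = {v(k): float(a) for k, a in c.coeffs.items()}
            if sense == Sense.LE:
                slack = max(0.0, _expr_range(model, c.coeffs, True) - float(c.rhs))
                rows.append(AffineRow(coeffs, Sense.LE,
                                      float(c.rhs) + slack, {z: -slack}))
            else:
                slack = max(0.0, float(c.rhs) - _expr_range(model, c.coeffs, False))
                rows.append(AffineRow(coeffs, Sense.GE,
                                      float(c.rhs) - slack, {z: slack}))
    rows.extend(extra_rows)
    return var_sign, rows


def primal_fragment(model: MetabolicModel, prefix: str, binaries: Binaries,
                    constraints: Sequence[LinearConstraint],
                    extra_rows: Sequence[AffineRow] = ()) -> Fragment:
    """Emit a flux copy directly (box bounds as variable bounds + gated rows)."""
    var_sign, rows = region_rows(model, prefix, binaries, constraints, extra_rows)
    frag = Fragment()
    for r in model.reactions:
        frag.variables[f"{prefix}.{r.id}"] = VarDef(
            VarKind.CONTINUOUS, float(r.lb), float(r.ub))
    frag.rows = rows
    return frag


# ---------------------------------------------------------------------------
# LP dualization with binary-affine right-hand sides
# ---------------------------------------------------------------------------

@dataclass
class DualBlock:
    fragment: Fragment                       # gating='indicator'
    var_sign: Dict[str, str]                 # gating='affine'
    rows: List[AffineRow]                    # gating='affine'
    value_expr: Dict[str, float]
    value_negated: bool

    @property
    def all_rows(self) -> List[AffineRow]:
        return self.rows if self.rows else self.fragment.rows


def dualize(lp: AffineLP, prefix: str, gating: str = "indicator",
            dual_bound: float = DUAL_BOUND) -> DualBlock:
    """LP dual with exact linearization of binary x dual products.

    The primal is canonicalized to a maximization over <= and = rows.  Each
    row gets a dual variable (nonnegative for <=, free for =) bounded by
    ``dual_bound``; each primal variable yields a dual constraint (equality
    for free variables, >= for nonnegative ones).  Every product z_b*pi_r
    occurring in the dual objective is replaced by an auxiliary variable q
    with the exact gating q = pi if z_b = 1 else 0, expressed either as
    indicator constraints (``gating='indicator'``) or as big-M affine rows
    (``gating='affine'``, used when the dual system itself must be
    dualizable again).

    ``value_expr`` is a linear expression over the new variables whose
    optimum under outer pressure equals the primal LP value: for a MAX
    primal it is the dual objective (>= the LP value for any dual-feasible
    point), for a MIN primal its negation (<= the LP value), so embedding
    it in an outer maximization yields a valid lower-bound certificate.
    """
    sign = 1.0
    obj = {k: float(v) for k, v in lp.objective.items()}
    if lp.sense == ObjSense.MIN:
        sign = -1.0
        obj = {k: -v for k, v in obj.items()}
    canon: List[AffineRow] = []
    for row in lp.rows:
        canon.append(row.negated() if row.sense == Sense.GE else row)

    frag = Fragment()
    var_sign: Dict[str, str] = {}
    rows_out: List[AffineRow] = []
    value: Dict[str, float] = {}

    def declare(name: str, nonneg: bool):
        if gating == "indicator":
            frag.variables[name] = VarDef(
                VarKind.CONTINUOUS, 0.0 if nonneg else -dual_bound, dual_bound)
        else:
            var_sign[name] = "nonneg" if nonneg else "free"
            rows_out.append(AffineRow({name: 1.0}, Sense.LE, dual_bound))
            if not nonneg:
                rows_out.append(AffineRow({name: 1.0}, Sense.GE, -dual_bound))

    pis: List[str] = []
    for r, row in enumerate(canon):
        pi = f"{prefix}.pi{r}"
        pis.append(pi)
        declare(pi, nonneg=(row.sense == Sense.LE))
        value[pi] = value.get(pi, 0.0) + row.const
        for b, a in row.zlin.items():
            q = f"{prefix}.q{r}.{b}"
            nonneg = row.sense == Sense.LE
            declare(q, nonneg=nonneg)
            value[q] = value.get(q, 0.0) + a
            if gating == "indicator":
                frag.indicators.append(IndicatorConstraint(
                    b, 1, LinearConstraint({q: 1.0, pi: -1.0}, Sense.EQ, 0.0)))
                frag.indicators.append(IndicatorConstraint(
                    b, 0, LinearConstraint({q: 1.0}, Sense.EQ, 0.0)))
            else:
                # big-M gating: q = z*pi with |pi| <= dual_bound
                K = dual_bound
                rows_out.append(AffineRow({q: 1.0, pi: -1.0}, Sense.LE,
                                          K, {b: -K}))
                rows_out.append(AffineRow({q: 1.0, pi: -1.0}, Sense.GE,
                                          -K, {b: K}))
                rows_out.append(AffineRow({q: 1.0}, Sense.LE, 0.0, {b: K}))
                if nonneg:
                    rows_out.append(AffineRow({q: 1.0}, Sense.GE, 0.0))
                else:
                    rows_out.append(AffineRow({q: 1.0}, Sense.GE, 0.0, {b: -K}))

    # dual constraints: one per primal variable
    col: Dict[str, Dict[str, float]] = {x: {} for x in lp.var_sign}
    for r, row in enumerate(canon):
        for x, a in row.coeffs.items():
            col[x][pis[r]] = col[x].get(pis[r], 0.0) + a
    for x, s in lp.var_sign.items():
        coeffs = col[x]
        rhs = obj.get(x, 0.0)
        if not coeffs and rhs == 0.0:
            continue
        row = AffineRow(dict(coeffs), Sense.EQ if s == "free" else Sense.GE, rhs)
        if gating == "indicator":
            frag.rows.append(row)
        else:
            rows_out.append(row)

    if lp.sense == ObjSense.MIN:
        value = {k: -v for k, v in value.items()}
    return DualBlock(frag, var_sign, rows_out, value, lp.sense == ObjSense.MIN)


# ---------------------------------------------------------------------------
# Module blocks
# ---------------------------------------------------------------------------

_counter = itertools.count()


def build_protect_block(model: MetabolicModel, module: DesignModule,
                        binaries: Binaries, tag: str = None) -> Fragment:
    tag = tag or f"P{next(_counter)}"
    return primal_fragment(model, tag, binaries, module.constraints)


def build_suppress_block(model: MetabolicModel, module: DesignModule,
                         binaries: Binaries, tag: str = None) -> Fragment:
    """Farkas certificate making the suppressed region infeasible."""
    tag = tag or f"S{next(_counter)}"
    var_sign, rows = region_rows(model, tag, binaries, module.constraints)
    lp = AffineLP(ObjSense.MAX, {}, var_sign, rows)
    block = dualize(lp, tag + ".f", gating="indicator")
    frag = block.fragment
    frag.rows.append(AffineRow(dict(block.value_expr), Sense.LE, -EPS_CERT))
    return frag


def build_optknock(model: MetabolicModel, module: DesignModule,
                   binaries: Binaries, tag: str = None
                   ) -> Tuple[Fragment, Dict[str, float]]:
    """Strong-duality single-level OptKnock block + outer objective."""
    tag = tag or f"K{next(_counter)}"
    frag = primal_fragment(model, tag, binaries, module.constraints)
    var_sign, rows = region_rows(model, tag, binaries, module.constraints)
    inner = AffineLP(ObjSense.MAX,
                     {f"{tag}.{k}": float(v) for k, v in module.inner_objective.items()},
                     var_sign, rows)
    block = dualize(inner, tag + ".d", gating="indicator")
    frag.merge(block.fragment)
    gap = {f"{tag}.{k}": float(v) for k, v in module.inner_objective.items()}
    for name, a in block.value_expr.items():
        gap[name] = gap.get(name, 0.0) - a
    frag.rows.append(AffineRow(gap, Sense.EQ, 0.0))
    outer = {f"{tag}.{k}": float(v) for k, v in module.outer_objective.items()}
    return frag, outer


def build_robustknock(model: MetabolicModel, module: DesignModule,
                      binaries: Binaries, tag: str = None
                      ) -> Tuple[Fragment, Dict[str, float]]:
    """Max-min block: worst-case outer objective over the inner-optimal face.

    The face LP minimizes the outer objective over flux copies constrained
    to inner optimality, where inner optimality is certified by a
    dual-feasible block whose objective the face constraint bounds; the
    face LP (including the first-stage duals among its variables) is then
    dualized a second time, so the returned expression -- maximized by the
    outer MILP -- is a valid lower-bound certificate of the worst case.
    """
    tag = tag or f"R{next(_counter)}"
    var_sign, rows = region_rows(model, tag + ".v2", binaries, module.constraints)
    inner_sign, inner_rows = region_rows(model, tag + ".v1", binaries,
                                         module.constraints)
    inner = AffineLP(ObjSense.MAX,
                     {f"{tag}.v1.{k}": float(v)
                      for k, v in module.inner_objective.items()},
                     inner_sign, inner_rows)
    first = dualize(inner, tag + ".d1", gating="affine")
    face_sign = dict(var_sign)
    face_sign.update(first.var_sign)
    face_rows = list(rows) + list(first.rows)
    # face constraint: inner objective of v2 >= first-stage dual objective
    face = {f"{tag}.v2.{k}": float(v) for k, v in module.inner_objective.items()}
    for name, a in first.value_expr.items():
        face[name] = face.get(name, 0.0) - a
    face_rows.append(AffineRow(face, Sense.GE, 0.0))
    face_lp = AffineLP(ObjSense.MIN,
                       {f"{tag}.v2.{k}": float(v)
                        for k, v in module.outer_objective.items()},
                       face_sign, face_rows)
    second = dualize(face_lp, tag + ".d2", gating="indicator")
    return second.fragment, dict(second.value_expr)


def build_optcouple(model: MetabolicModel, module: DesignModule,
                    binaries: Binaries, tag: str = None
                    ) -> Tuple[Fragment, Dict[str, float]]:
    """Growth-coupling potential: gap between the maximal inner objective
    with production enabled and with production disabled."""
    tag = tag or f"C{next(_counter)}"
    frag = Fragment()
    obj: Dict[str, float] = {}
    prod_zero = AffineRow({f"{tag}.wo.{module.prod_id}": 1.0}, Sense.EQ, 0.0)
    for sub, sgn, extra in (("wi", 1.0, ()), ("wo", -1.0, (prod_zero,))):
        prefix = f"{tag}.{sub}"
        frag.merge(primal_fragment(model, prefix, binaries, module.constraints,
                                   extra_rows=list(extra)))
        var_sign, rows = region_rows(model, prefix, binaries,
                                     module.constraints, extra_rows=list(extra))
        inner = AffineLP(ObjSense.MAX,
                         {f"{prefix}.{k}": float(v)
                          for k, v in module.inner_objective.items()},
                         var_sign, rows)
        block = dualize(inner, prefix + ".d", gating="indicator")
        frag.merge(block.fragment)
        gap = {f"{prefix}.{k}": float(v)
               for k, v in module.inner_objective.items()}
        for name, a in block.value_expr.items():
            gap[name] = gap.get(name, 0.0) - a
        frag.rows.append(AffineRow(gap, Sense.EQ, 0.0))
        for k, v in module.inner_objective.items():
            name = f"{prefix}.{k}"
            obj[name] = obj.get(name, 0.0) + sgn * float(v)
    return frag, obj


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble(problem: DesignProblem) -> Tuple[MILPProblem, Binaries]:
    """Concatenate all module fragments over one shared binary vector.

    The MILP objective is the nested module's outer objective when one is
    present, otherwise intervention-cost minimization (MCS mode).
    """
    problem.validate()
    binaries, frag = link_interventions(problem)
    milp = MILPProblem()
    _emit(milp, frag)
    outer_obj: Optional[Dict[str, float]] = None
    for i, module in enumerate(problem.modules):
        tag = f"m{i}"
        if module.kind == "protect":
            _emit(milp, build_protect_block(problem.model, module, binaries, tag))
        elif module.kind == "suppress":
            _emit(milp, build_suppress_block(problem.model, module, binaries, tag))
        else:
            builder = {"optknock": build_optknock,
                       "robustknock": build_robustknock,
                       "optcouple": build_optcouple}[module.kind]
            block_frag, outer_obj = builder(problem.model, module, binaries, tag)
            _emit(milp, block_frag)
    if outer_obj is not None:
        milp.objective = (ObjSense.MAX, outer_obj)
    else:
        milp.objective = (ObjSense.MIN, dict(binaries.costs))
    return milp, binaries
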