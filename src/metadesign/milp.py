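"""Solver-agnostic LP/MILP container and solving.

The container supports plain linear constraints and *indicator constraints*
("if binary z equals its active value, then a linear constraint holds").
None of the bundled backends (GLPK via optlang/swiglpk, HiGHS via
scipy.optimize.milp) natively accepts indicator constraints, so
:func:`solve` automatically rewrites them with :func:`to_bigM` using per
constraint big-M values derived from the variable bounds (tight big-M); a
global override is available.  Commercial backends ("cplex", "gurobi",
"scip") are accepted by name and dispatched through optlang when installed.

Binary variables are reported rounded; an integrality deviation beyond 1e-6
is treated as a numerical failure, never as infeasibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import scipy.optimize as sopt
import scipy.sparse as sp

from .model import LinearConstraint, Sense

__all__ = [
    "VarKind", "ObjSense", "Status", "MILPProblem", "SolverResult",
    "IndicatorConstraint", "solve", "to_bigM", "add_exclusion_cut",
    "available_backends", "SolverError", "NumericalError", "write_lp",
]

INT_TOL = 1e-6
FEAS_TOL = 1e-6


class SolverError(RuntimeError):
    """Backend unavailable or rejected the problem."""


class NumericalError(SolverError):
    """Numerical failure distinct from model infeasibility."""


class VarKind(Enum):
    CONTINUOUS = "continuous"
    BINARY = "binary"


class ObjSense(Enum):
    MIN = "min"
    MAX = "max"


class Status(Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"
    TIME_LIMIT_FEASIBLE = "time_limit_feasible"
    TIME_LIMIT_NO_SOLUTION = "time_limit_no_solution"


@dataclass
class VarDef:
    kind: VarKind = VarKind.CONTINUOUS
    lb: float = -math.inf
    ub: float = math.inf

    def __post_init__(self):
        if self.kind == VarKind.BINARY:
            self.lb = max(0.0, self.lb)
            self.ub = min(1.0, self.ub)
        if self.lb > self.ub:
            raise SolverError(f"variable lb {self.lb} > ub {self.ub}")


@dataclass
class IndicatorConstraint:
    binary: str
    active_value: int  # 0 or 1
    constraint: LinearConstraint


@dataclass
class MILPProblem:
    variables: Dict[str, VarDef] = field(default_factory=dict)
    lin_constraints: List[LinearConstraint] = field(default_factory=list)
    ind_constraints: List[IndicatorConstraint] = field(default_factory=list)
    objective: Tuple[ObjSense, Dict[str, float]] = (ObjSense.MIN, None)

    def __post_init__(self):
        if self.objective[1] is None:
            self.objective = (self.objective[0], {})

    # -- building helpers --------------------------------------------------
    def add_var(self, name: str, kind: VarKind = VarKind.CONTINUOUS,
                lb: float = -math.inf, ub: float = math.inf) -> str:
        if name in self.variables:
            raise SolverError(f"duplicate variable {name!r}")
        self.variables[name] = VarDef(kind, lb, ub)
        return name

    def add_constraint(self, coeffs: Dict[str, float], sense: Sense, rhs: float):
        self.lin_constraints.append(LinearConstraint(dict(coeffs), sense, rhs))

    def add_indicator(self, binary: str, active_value: int,
                      coeffs: Dict[str, float], sense: Sense, rhs: float):
        self.ind_constraints.append(IndicatorConstraint(
            binary, active_value, LinearConstraint(dict(coeffs), sense, rhs)))

    def validate(self):
        for c in self.lin_constraints:
            for v in c.coeffs:
                if v not in self.variables:
                    raise SolverError(f"constraint references unknown variable {v!r}")
        for ic in self.ind_constraints:
            vd = self.variables.get(ic.binary)
            if vd is None or vd.kind != VarKind.BINARY:
                raise SolverError(f"indicator binary {ic.binary!r} is not a declared binary")
            if ic.active_value not in (0, 1):
                raise SolverError("indicator active value must be 0 or 1")
            for v in ic.constraint.coeffs:
                if v not in self.variables:
                    raise SolverError(f"indicator references unknown variable {v!r}")
        for v in self.objective[1]:
            if v not in self.variables:
                raise SolverError(f"objective references unknown variable {v!r}")

    def copy(self) -> "MILPProblem":
        p = MILPProblem()
        p.variables = {k: VarDef(v.kind, v.lb, v.ub) for k, v in self.variables.items()}
        p.lin_constraints = [c.copy() for c in self.lin_constraints]
        p.ind_constraints = [IndicatorConstraint(i.binary, i.active_value,
                                                 i.constraint.copy())
                             for i in self.ind_constraints]
        p.objective = (self.objective[0], dict(self.objective[1]))
        return p


@dataclass
class SolverResult:
    status: Status
    objective_value: Optional[float] = None
    assignment: Optional[Dict[str, float]] = None

    @property
    def optimal(self) -> bool:
        return self.status == Status.OPTIMAL


# ---------------------------------------------------------------------------
# big-M rewriting of indicator constraints
# ---------------------------------------------------------------------------

def _range(coeffs: Dict[str, float], variables: Dict[str, VarDef],
           upper: bool) -> float:
    """Supremum (upper=True) or infimum of sum(coeffs*x) over the bound box."""
    total = 0.0
    for v, a in coeffs.items():
        a = float(a)
        vd = variables[v]
        pick = vd.ub if (a > 0) == upper else vd.lb
        if not math.isfinite(pick) and a != 0:
            return math.inf if upper else -math.inf
        total += a * pick
    return total


def to_bigM(problem: MILPProblem, M: Optional[float] = None) -> MILPProblem:
    """Replace all indicator constraints with big-M linear constraints.

    Without an explicit *M*, a tight per-constraint M is computed from the
    variable bounds; every variable in an indicator constraint must then be
    bounded.  The rewritten problem is feasibility-equivalent within the
    variable bound box.
    """
    out = problem.copy()
    out.ind_constraints = []
    for ic in problem.ind_constraints:
        c = ic.constraint
        senses = [c.sense] if c.sense != Sense.EQ else [Sense.LE, Sense.GE]
        for sense in senses:
            if sense == Sense.LE:
                span = _range(c.coeffs, problem.variables, upper=True) - float(c.rhs)
            else:
                span = float(c.rhs) - _range(c.coeffs, problem.variables, upper=False)
            if M is None:
                if not math.isfinite(span):
                    raise SolverError(
                        f"indicator on binary {ic.binary!r} involves an unbounded "
                        "variable; bound it or pass an explicit M")
                m_val = max(0.0, span)
            else:
                m_val = float(M)
            coeffs = {k: float(v) for k, v in c.coeffs.items()}
            # slack term m_val * s with s = (1-z) if active at 1 else z
            if sense == Sense.LE:
                # lhs <= rhs + m*s
                if ic.active_value == 1:
                    coeffs[ic.binary] = coeffs.get(ic.binary, 0.0) + m_val
                    out.add_constraint(coeffs, Sense.LE, float(c.rhs) + m_val)
                else:
                    coeffs[ic.binary] = coeffs.get(ic.binary, 0.0) - m_val
                    out.add_constraint(coeffs, Sense.LE, float(c.rhs))
            else:
                # lhs >= rhs - m*s
                if ic.active_value == 1:
                    coeffs[ic.binary] = coeffs.get(ic.binary, 0.0) - m_val
                    out.add_constraint(coeffs, Sense.GE, float(c.rhs) - m_val)
                else:
                    coeffs[ic.binary] = coeffs.get(ic.binary, 0.0) + m_val
                    out.add_constraint(coeffs, Sense.GE, float(c.rhs))
    return out


def add_exclusion_cut(problem: MILPProblem, binaries_at_one: Iterable[str]) -> MILPProblem:
    """Exclude a binary support set and all its supersets.

    Appends ``sum_{i in set} (1 - z_i) >= 1``, i.e. every later solution must
    set at least one member to zero.
    """
    names = sorted(set(binaries_at_one))
    if not names:
        raise SolverError("exclusion cut over the empty set would forbid everything")
    for n in names:
        vd = problem.variables.get(n)
        if vd is None or vd.kind != VarKind.BINARY:
            raise SolverError(f"{n!r} is not a binary variable of the problem")
    problem.add_constraint({n: 1.0 for n in names}, Sense.LE, float(len(names) - 1))
    return problem


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------

def available_backends() -> List[str]:
    names = ["highs"]
    try:
        import optlang
        if optlang.available_solvers.get("GLPK"):
            names.insert(0, "glpk")
        for opt_name, our in (("CPLEX", "cplex"), ("GUROBI", "gurobi")):
            if optlang.available_solvers.get(opt_name):
                names.append(our)
    except ImportError:  # pragma: no cover
        pass
    return names


DEFAULT_BACKEND = "glpk"


def solve(problem: MILPProblem, backend: str = None,
          time_limit: Optional[float] = None,
          mip_gap: Optional[float] = None,
          bigM: Optional[float] = None) -> SolverResult:
    """Solve a MILP/LP, rewriting indicators with big-M when needed."""
    problem.validate()
    backend = backend or DEFAULT_BACKEND
    if backend not in available_backends():
        raise SolverError(f"backend {backend!r} unavailable; "
                          f"have {available_backends()}")
    if problem.ind_constraints:
        problem = to_bigM(problem, M=bigM)
    if backend == "highs":
        res = _solve_highs(problem, time_limit, mip_gap)
    else:
        res = _solve_optlang(problem, backend, time_limit, mip_gap)
    return _postprocess(problem, res)


def _postprocess(problem: MILPProblem, res: SolverResult) -> SolverResult:
    if res.assignment is None:
        return res
    rounded = {}
    for name, val in res.assignment.items():
        if problem.variables[name].kind == VarKind.BINARY:
            r = round(val)
            if abs(val - r) > 1e-5:  # glpk reports binaries loosely on big-M models
                raise NumericalError(
                    f"binary {name!r} = {val} violates integrality tolerance")
            rounded[name] = float(r)
        else:
            rounded[name] = float(val)
    res.assignment = rounded
    return res


def _solve_highs(problem: MILPProblem, time_limit, mip_gap) -> SolverResult:
    names = list(problem.variables)
    idx = {n: i for i, n in enumerate(names)}
    n = len(names)
    sense, obj = problem.objective
    c = np.zeros(n)
    for v, a in obj.items():
        c[idx[v]] = float(a)
    if sense == ObjSense.MAX:
        c = -c
    lb = np.array([problem.variables[v].lb for v in names])
    ub = np.array([problem.variables[v].ub for v in names])
    integrality = np.array(
        [1 if problem.variables[v].kind == VarKind.BINARY else 0 for v in names])
    rows, cols, vals, bl, bu = [], [], [], [], []
    for i, con in enumerate(problem.lin_constraints):
        for v, a in con.coeffs.items():
            rows.append(i); cols.append(idx[v]); vals.append(float(a))
        r = float(con.rhs)
        bl.append(r if con.sense in (Sense.GE, Sense.EQ) else -math.inf)
        bu.append(r if con.sense in (Sense.LE, Sense.EQ) else math.inf)
    constraints = []
    if problem.lin_constraints:
        A = sp.csr_matrix((vals, (rows, cols)),
                          shape=(len(problem.lin_constraints), n))
        constraints = [sopt.LinearConstraint(A, np.array(bl), np.array(bu))]
    options = {}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    if mip_gap is not None:
        options["mip_rel_gap"] = float(mip_gap)
    res = sopt.milp(c=c, constraints=constraints,
                    integrality=integrality, bounds=sopt.Bounds(lb, ub),
                    options=options)
    if res.status == 0:
        val = float(res.fun)
        if sense == ObjSense.MAX:
            val = -val
        return SolverResult(Status.OPTIMAL, val, dict(zip(names, res.x)))
    if res.status == 2:
        return SolverResult(Status.INFEASIBLE)
    if res.status == 3:
        return SolverResult(Status.UNBOUNDED)
    if res.status == 1:  # iteration/time limit
        if res.x is not None:
            val = float(res.fun) if sense == ObjSense.MIN else -float(res.fun)
            return SolverResult(Status.TIME_LIMIT_FEASIBLE, val,
                                dict(zip(names, res.x)))
        return SolverResult(Status.TIME_LIMIT_NO_SOLUTION)
    raise NumericalError(f"HiGHS numerical failure: {res.message}")


def _solve_optlang(problem: MILPProblem, backend: str,
                   time_limit, mip_gap) -> SolverResult:
    from importlib import import_module
    iface = {"glpk": "glpk_interface",
             "cplex": "cplex_interface",
             "gurobi": "gurobi_interface"}[backend]
    iface_mod = import_module(f"optlang.{iface}")
    m = iface_mod.Model()
    if time_limit is not None:
        m.configuration.timeout = float(time_limit)
    variables = {}
    for name, vd in problem.variables.items():
        lb = None if not math.isfinite(vd.lb) else float(vd.lb)
        ub = None if not math.isfinite(vd.ub) else float(vd.ub)
        vtype = "binary" if vd.kind == VarKind.BINARY else "continuous"
        variables[name] = iface_mod.Variable(name, lb=lb, ub=ub, type=vtype)
    m.add(list(variables.values()))
    cons = []
    for i, con in enumerate(problem.lin_constraints):
        expr = sum(float(a) * variables[v] for v, a in con.coeffs.items())
        lb = float(con.rhs) if con.sense in (Sense.GE, Sense.EQ) else None
        ub = float(con.rhs) if con.sense in (Sense.LE, Sense.EQ) else None
        cons.append(iface_mod.Constraint(expr, lb=lb, ub=ub, name=f"c{i}"))
    m.add(cons)
    sense, obj = problem.objective
    expr = sum(float(a) * variables[v] for v, a in obj.items()) if obj else 0
    m.objective = iface_mod.Objective(
        expr, direction="max" if sense == ObjSense.MAX else "min")
    status = m.optimize()
    if status == "optimal":
        return SolverResult(Status.OPTIMAL, float(m.objective.value),
                            {n: v.primal for n, v in variables.items()})
    if status == "infeasible":
        return SolverResult(Status.INFEASIBLE)
    if status in ("unbounded", "infeasible_or_unbounded"):
        return SolverResult(Status.UNBOUNDED)
    if status == "time_limit":
        try:
            return SolverResult(Status.TIME_LIMIT_FEASIBLE, float(m.objective.value),
                                {n: v.primal for n, v in variables.items()})
        except Exception:
            return SolverResult(Status.TIME_LIMIT_NO_SOLUTION)
    if status == "undefined":
        # GLPK reports 'undefined' both for presolved-out infeasibility and
        # genuine numerical trouble; disambiguate with a feasibility re-solve.
        m.objective = iface_mod.Objective(0, direction="min")
        st2 = m.optimize()
        if st2 == "optimal":
            raise NumericalError("GLPK failed on the objective but the model is feasible")
        if st2 in ("infeasible", "undefined"):
            return SolverResult(Status.INFEASIBLE)
        if st2 == "unbounded":  # pragma: no cover
            return SolverResult(Status.UNBOUNDED)
    raise NumericalError(f"backend {backend!r} returned status {status!r}")


# ---------------------------------------------------------------------------
# LP-format export (debugging aid)
# ---------------------------------------------------------------------------

def write_lp(problem: MILPProblem, path: str) -> None:
    """Write the problem (indicators rewritten via big-M) in CPLEX LP format."""
    if problem.ind_constraints:
        problem = to_bigM(problem)
    sense, obj = problem.objective

    def expr(coeffs):
        parts = []
        for v, a in coeffs.items():
            a = float(a)
            parts.append(f"{'+' if a >= 0 else '-'} {abs(a):g} {v}")
        return " ".join(parts) if parts else "0 dummy"

    lines = ["Maximize" if sense == ObjSense.MAX else "Minimize",
             f" obj: {expr(obj)}", "Subject To"]
    for i, c in enumerate(problem.lin_constraints):
        op = {"<=": "<=", ">=": ">=", "=": "="}[c.sense.value]
        lines.append(f" c{i}: {expr(c.coeffs)} {op} {float(c.rhs):g}")
    lines.append("Bounds")
    for n, vd in problem.variables.items():
        lo = f"{vd.lb:g}" if math.isfinite(vd.lb) else "-inf"
        hi = f"{vd.ub:g}" if math.isfinite(vd.ub) else "+inf"
        lines.append(f" {lo} <= {n} <= {hi}")
    bins = [n for n, vd in problem.variables.items() if vd.kind == VarKind.BINARY]
    if bins:
        lines.append("Binary")
        lines.extend(f" {n}" for n in bins)
    lines.append("End")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
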