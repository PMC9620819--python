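"""Canonical LP analyses of the steady-state flux space.

Implements flux balance analysis (FBA), flux variability analysis (FVA),
true yield optimization of linear-fractional terms (c.v)/(d.v) via the
Charnes-Cooper transformation, and 2D/3D projections of the flux space onto
user-selected rates or yields (production envelopes / yield spaces).

All operations reduce to LPs solved through :mod:`metadesign.milp`; FVA is a
pure map over independent per-reaction LPs whose results do not depend on
evaluation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .milp import MILPProblem, ObjSense, SolverResult, Status, VarKind, solve
from .model import (LinearConstraint, MetabolicModel, ModelError, Sense,
                    parse_linear_constraints)

__all__ = [
    "FluxDistribution", "RatioExpression", "ProjectedRegion",
    "InfeasibleError", "UnboundedError",
    "fba", "fva", "yield_opt", "flux_space_projection", "plot_projection",
]

TOL = 1e-6


class InfeasibleError(RuntimeError):
    """The steady-state system with the given constraints has no solution."""


class UnboundedError(RuntimeError):
    """The requested objective or ratio is unbounded over the feasible set."""


@dataclass
class FluxDistribution:
    values: Dict[str, float]
    objective_value: float

    def __getitem__(self, rid: str) -> float:
        return self.values[rid]


@dataclass
class RatioExpression:
    """A linear rate c.v, or a yield term (c.v)/(d.v) when denominator set."""

    numerator: Dict[str, float]
    denominator: Dict[str, float] = field(default_factory=dict)

    @classmethod
    def rate(cls, rid: str) -> "RatioExpression":
        return cls({rid: 1.0})

    @property
    def is_ratio(self) -> bool:
        return bool(self.denominator)

    def evaluate(self, flux: Mapping[str, float]) -> float:
        num = sum(a * flux[r] for r, a in self.numerator.items())
        if not self.is_ratio:
            return num
        den = sum(a * flux[r] for r, a in self.denominator.items())
        return num / den


@dataclass
class ProjectedRegion:
    axes: Sequence[RatioExpression]
    boundary: List  # 2D: list of (x, y) vertices; 3D: list of facet vertex lists
    feasible: bool = True

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            if len(self.axes) == 2:
                fh.write("axis1\taxis2\n")
                for x, y in self.boundary:
                    fh.write(f"{x:.10g}\t{y:.10g}\n")
            else:
                fh.write("facet\taxis1\taxis2\taxis3\n")
                for i, facet in enumerate(self.boundary):
                    for x, y, z in facet:
                        fh.write(f"{i}\t{x:.10g}\t{y:.10g}\t{z:.10g}\n")


# ---------------------------------------------------------------------------
# LP assembly
# ---------------------------------------------------------------------------

def _as_constraints(model, extra) -> List[LinearConstraint]:
    if extra is None:
        return []
    if isinstance(extra, str):
        return parse_linear_constraints(extra, model)
    out = list(extra)
    for c in out:
        c.validate(model)
    return out


def steady_state_lp(model: MetabolicModel,
                    extra: Sequence[LinearConstraint] = ()) -> MILPProblem:
    """LP skeleton: variables = reaction fluxes, S v = 0, bounds, extras."""
    p = MILPProblem()
    for r in model.reactions:
        p.add_var(r.id, VarKind.CONTINUOUS, float(r.lb), float(r.ub))
    for m in model.metabolites:
        coeffs = {r.id: float(r.stoich[m.id])
                  for r in model.reactions if m.id in r.stoich}
        if coeffs:
            p.add_constraint(coeffs, Sense.EQ, 0.0)
    for c in extra:
        p.add_constraint({k: float(v) for k, v in c.coeffs.items()},
                         c.sense, float(c.rhs))
    return p


def _lp_optimize(p: MILPProblem, objective: Dict[str, float],
                 sense: ObjSense, backend=None) -> SolverResult:
    p.objective = (sense, {k: float(v) for k, v in objective.items()})
    return solve(p, backend=backend)


# ---------------------------------------------------------------------------
# FBA / FVA
# ---------------------------------------------------------------------------

def fba(model: MetabolicModel, objective: Optional[Mapping[str, float]] = None,
        extra=None, sense: ObjSense = ObjSense.MAX,
        backend: Optional[str] = None) -> FluxDistribution:
    """Maximize a linear flux objective over the steady-state flux space."""
    obj = dict(objective) if objective is not None else \
        {k: float(v) for k, v in model.objective.items()}
    for rid in obj:
        if rid not in model.reaction_index:
            raise ModelError(f"objective references unknown reaction {rid!r}")
    p = steady_state_lp(model, _as_constraints(model, extra))
    res = _lp_optimize(p, obj, sense, backend)
    if res.status == Status.INFEASIBLE:
        raise InfeasibleError("steady-state system infeasible under the given constraints")
    if res.status == Status.UNBOUNDED:
        raise UnboundedError("FBA objective is unbounded")
    if not res.optimal:
        raise RuntimeError(f"solver returned {res.status}")
    return FluxDistribution({r.id: res.assignment[r.id] for r in model.reactions},
                            res.objective_value)


def fva(model: MetabolicModel, reaction_ids: Optional[Sequence[str]] = None,
        extra=None, backend: Optional[str] = None
        ) -> Dict[str, Tuple[float, float]]:
    """Exact per-reaction flux minima and maxima.

    The per-reaction LPs are independent; a parallel driver may evaluate
    them concurrently without changing any result.
    """
    cons = _as_constraints(model, extra)
    ids = list(reaction_ids) if reaction_ids is not None else \
        [r.id for r in model.reactions]
    for rid in ids:
        model.reaction(rid)
    base = steady_state_lp(model, cons)
    feas = _lp_optimize(base.copy(), {}, ObjSense.MIN, backend)
    if feas.status == Status.INFEASIBLE:
        raise InfeasibleError("constraint set infeasible; no FVA performed")
    out: Dict[str, Tuple[float, float]] = {}
    for rid in ids:
        lo = _lp_optimize(base.copy(), {rid: 1.0}, ObjSense.MIN, backend)
        hi = _lp_optimize(base.copy(), {rid: 1.0}, ObjSense.MAX, backend)
        lo_v = -math.inf if lo.status == Status.UNBOUNDED else lo.objective_value
        hi_v = math.inf if hi.status == Status.UNBOUNDED else hi.objective_value
        out[rid] = (lo_v, hi_v)
    return out


# ---------------------------------------------------------------------------
# Linear-fractional (yield) optimization
# ---------------------------------------------------------------------------

def _denominator_sign(model, den: Dict[str, float], extra, backend) -> int:
    rng = {}
    base = steady_state_lp(model, extra)
    lo = _lp_optimize(base.copy(), den, ObjSense.MIN, backend)
    hi = _lp_optimize(base.copy(), den, ObjSense.MAX, backend)
    if lo.status == Status.INFEASIBLE or hi.status == Status.INFEASIBLE:
        raise InfeasibleError("feasible set empty")
    dmin = -math.inf if lo.status == Status.UNBOUNDED else lo.objective_value
    dmax = math.inf if hi.status == Status.UNBOUNDED else hi.objective_value
    if dmin < -TOL and dmax > TOL:
        raise ModelError("yield denominator attains both signs over the feasible set")
    if dmax <= TOL and dmin >= -TOL:
        raise ModelError("yield denominator is identically zero over the feasible set")
    return 1 if dmax > TOL else -1


def yield_opt(model: MetabolicModel, ratio: RatioExpression,
              sense: ObjSense = ObjSense.MAX, extra=None,
              backend: Optional[str] = None) -> Tuple[float, FluxDistribution]:
    """Optimize (c.v)/(d.v) via the Charnes-Cooper substitution.

    With scaled variables ``w = e*v`` and ``e >= 0`` normalized by
    ``d.w = 1``, the homogeneous system ``S w = 0``, ``lb*e <= w <= ub*e``
    plus homogenized extra constraints turns the fractional program into an
    LP in (w, e); the optimizer is de-scaled as ``v = w / e``.
    """
    if not ratio.is_ratio:
        raise ModelError("yield_opt requires a non-empty denominator")
    cons = _as_constraints(model, extra)
    sign = _denominator_sign(model, dict(ratio.denominator), cons, backend)
    num = {k: sign * v for k, v in ratio.numerator.items()}
    den = {k: sign * v for k, v in ratio.denominator.items()}

    p = MILPProblem()
    big = 1e9  # w and e are only implicitly bounded by the homogenized rows
    for r in model.reactions:
        p.add_var("w:" + r.id, VarKind.CONTINUOUS, -big, big)
    p.add_var("e", VarKind.CONTINUOUS, 0.0, big)
    for m in model.metabolites:
        coeffs = {"w:" + r.id: float(r.stoich[m.id])
                  for r in model.reactions if m.id in r.stoich}
        if coeffs:
            p.add_constraint(coeffs, Sense.EQ, 0.0)
    for r in model.reactions:
        p.add_constraint({"w:" + r.id: 1.0, "e": -float(r.ub)}, Sense.LE, 0.0)
        p.add_constraint({"w:" + r.id: 1.0, "e": -float(r.lb)}, Sense.GE, 0.0)
    for c in cons:
        coeffs = {"w:" + k: float(v) for k, v in c.coeffs.items()}
        coeffs["e"] = -float(c.rhs)
        p.add_constraint(coeffs, c.sense, 0.0)
    p.add_constraint({"w:" + k: float(v) for k, v in den.items()}, Sense.EQ, 1.0)
    res = _lp_optimize(p, {"w:" + k: float(v) for k, v in num.items()},
                       sense, backend)
    if res.status == Status.INFEASIBLE:
        raise InfeasibleError(
            "no feasible flux with nonzero denominator; ratio undefined")
    if res.status == Status.UNBOUNDED:
        raise UnboundedError("yield ratio is unbounded")
    e = res.assignment["e"]
    if e < 1e-9:
        raise UnboundedError("yield optimum attained only in the limit of "
                             "vanishing denominator")
    flux = {r.id: res.assignment["w:" + r.id] / e for r in model.reactions}
    return res.objective_value, FluxDistribution(flux, res.objective_value)


# ---------------------------------------------------------------------------
# Flux-space projections
# ---------------------------------------------------------------------------

def _axis_problem(model: MetabolicModel, axes: Sequence[RatioExpression],
                  extra: Sequence[LinearConstraint], backend):
    """Return (MILP skeleton, list of linear axis coefficient maps).

    Rate axes live in flux coordinates.  Yield axes require one shared
    denominator; the projection then happens in Charnes-Cooper coordinates,
    where every axis is again linear.
    """
    ratios = [a for a in axes if a.is_ratio]
    if ratios:
        dens = {tuple(sorted((k, float(v)) for k, v in a.denominator.items()))
                for a in ratios}
        if len(dens) > 1 or len(ratios) != len(axes):
            raise ModelError("yield-space axes must all share one denominator")
        sign = _denominator_sign(model, dict(ratios[0].denominator), list(extra),
                                 backend)
        p = MILPProblem()
        big = 1e9
        for r in model.reactions:
            p.add_var("w:" + r.id, VarKind.CONTINUOUS, -big, big)
        p.add_var("e", VarKind.CONTINUOUS, 0.0, big)
        for m in model.metabolites:
            coeffs = {"w:" + r.id: float(r.stoich[m.id])
                      for r in model.reactions if m.id in r.stoich}
            if coeffs:
                p.add_constraint(coeffs, Sense.EQ, 0.0)
        for r in model.reactions:
            p.add_constraint({"w:" + r.id: 1.0, "e": -float(r.ub)}, Sense.LE, 0.0)
            p.add_constraint({"w:" + r.id: 1.0, "e": -float(r.lb)}, Sense.GE, 0.0)
        for c in extra:
            coeffs = {"w:" + k: float(v) for k, v in c.coeffs.items()}
            coeffs["e"] = -float(c.rhs)
            p.add_constraint(coeffs, c.sense, 0.0)
        p.add_constraint({"w:" + k: sign * float(v)
                          for k, v in ratios[0].denominator.items()},
                         Sense.EQ, 1.0)
        lin_axes = [{"w:" + k: sign * float(v) for k, v in a.numerator.items()}
                    for a in axes]
        return p, lin_axes
    p = steady_state_lp(model, extra)
    return p, [{k: float(v) for k, v in a.numerator.items()} for a in axes]


def _opt_axis(p: MILPProblem, axis: Dict[str, float], sense: ObjSense,
              backend, fixed: Sequence[Tuple[Dict[str, float], float]] = ()):
    q = p.copy()
    for coeffs, val in fixed:
        q.add_constraint(dict(coeffs), Sense.EQ, val)
    return _lp_optimize(q, axis, sense, backend)


def _convex_hull_2d(points: np.ndarray) -> List[Tuple[float, float]]:
    """Monotone-chain hull; returns CCW vertices, handles degenerate input."""
    pts = sorted(set((round(float(x), 9), round(float(y), 9)) for x, y in points))
    if len(pts) <= 2:
        return [tuple(map(float, p)) for p in pts]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for pt in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], pt) <= 1e-12:
            lower.pop()
        lower.append(pt)
    for pt in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], pt) <= 1e-12:
            upper.pop()
        upper.append(pt)
    return [tuple(map(float, p)) for p in lower[:-1] + upper[:-1]]


def flux_space_projection(model: MetabolicModel, axes: Sequence[RatioExpression],
                          n_grid: int = 40, extra=None,
                          method: str = "auto",
                          backend: Optional[str] = None) -> ProjectedRegion:
    """Project the flux space onto 2 or 3 rate/yield axes.

    2D uses an exact support-point mode by default ("vertex"): the extreme
    points of the projected polytope are found by recursively maximizing
    outward normals of candidate hull edges until no edge can be pushed out
    by more than 1e-6.  A "grid" mode sweeping axis 1 over ``n_grid`` values
    is also available and is the only mode for 3D.
    """
    axes = list(axes)
    if len(axes) not in (2, 3):
        raise ModelError("projection requires 2 or 3 axes")
    cons = _as_constraints(model, extra)
    p, lin = _axis_problem(model, axes, cons, backend)
    feas = _lp_optimize(p.copy(), {}, ObjSense.MIN, backend)
    if feas.status == Status.INFEASIBLE:
        return ProjectedRegion(axes, [], feasible=False)
    if method == "auto":
        method = "vertex" if len(axes) == 2 else "grid"
    if len(axes) == 2:
        if method == "vertex":
            verts = _project_2d_vertex(p, lin, backend)
        else:
            verts = _project_2d_grid(p, lin, n_grid, backend)
        return ProjectedRegion(axes, verts)
    return ProjectedRegion(axes, _project_3d_grid(p, lin, n_grid, backend))


def _axis_value(axis: Dict[str, float], assignment: Dict[str, float]) -> float:
    return sum(a * assignment[v] for v, a in axis.items())


def _support(p, lin, direction: Tuple[float, float], backend):
    """Maximize d1*axis1 + d2*axis2; return the optimizer's (axis1, axis2)."""
    obj: Dict[str, float] = {}
    for d, axis in zip(direction, lin):
        for v, a in axis.items():
            obj[v] = obj.get(v, 0.0) + d * a
    res = _lp_optimize(p.copy(), obj, ObjSense.MAX, backend)
    if res.status == Status.UNBOUNDED:
        raise UnboundedError("projection axis is unbounded; bound the network first")
    if not res.optimal:
        raise RuntimeError(f"support LP returned {res.status}")
    return (_axis_value(lin[0], res.assignment), _axis_value(lin[1], res.assignment))


def _project_2d_vertex(p, lin, backend, tol: float = 1e-6):
    seeds = [_support(p, lin, d, backend)
             for d in ((1, 0), (-1, 0), (0, 1), (0, -1))]
    hull = _convex_hull_2d(np.array(seeds))
    if len(hull) <= 1:
        return hull
    # sandwich refinement: push each hull edge outward along its normal
    changed = True
    guard = 0
    while changed and guard < 200:
        changed = False
        guard += 1
        new_pts = list(hull)
        m = len(hull)
        for i in range(m if m > 2 else 1):
            a = hull[i]
            b = hull[(i + 1) % m]
            nx, ny = (b[1] - a[1], a[0] - b[0])  # outward normal for CCW hull
            norm = math.hypot(nx, ny)
            if norm < 1e-12:
                continue
            nx, ny = nx / norm, ny / norm
            q = _support(p, lin, (nx, ny), backend)
            dist = (q[0] - a[0]) * nx + (q[1] - a[1]) * ny
            if dist > tol:
                new_pts.append(q)
                changed = True
        if changed:
            hull = _convex_hull_2d(np.array(new_pts))
    return hull


def _project_2d_grid(p, lin, n_grid, backend):
    lo = _lp_optimize(p.copy(), lin[0], ObjSense.MIN, backend)
    hi = _lp_optimize(p.copy(), lin[0], ObjSense.MAX, backend)
    if lo.status == Status.UNBOUNDED or hi.status == Status.UNBOUNDED:
        raise UnboundedError("projection axis 1 is unbounded")
    pts = []
    for x in np.linspace(lo.objective_value, hi.objective_value, n_grid):
        for sense in (ObjSense.MIN, ObjSense.MAX):
            res = _opt_axis(p, lin[1], sense, backend, fixed=[(lin[0], float(x))])
            if res.optimal:
                pts.append((float(x), res.objective_value))
    return _convex_hull_2d(np.array(pts))


def _project_3d_grid(p, lin, n_grid, backend):
    lo = _lp_optimize(p.copy(), lin[0], ObjSense.MIN, backend)
    hi = _lp_optimize(p.copy(), lin[0], ObjSense.MAX, backend)
    facets = []
    xs = np.linspace(lo.objective_value, hi.objective_value, n_grid)
    for ia in range(len(xs)):
        x = float(xs[ia])
        qlo = _opt_axis(p, lin[1], ObjSense.MIN, backend, fixed=[(lin[0], x)])
        qhi = _opt_axis(p, lin[1], ObjSense.MAX, backend, fixed=[(lin[0], x)])
        if not (qlo.optimal and qhi.optimal):
            continue
        strip_lo, strip_hi = [], []
        for y in np.linspace(qlo.objective_value, qhi.objective_value, n_grid):
            zlo = _opt_axis(p, lin[2], ObjSense.MIN, backend,
                            fixed=[(lin[0], x), (lin[1], float(y))])
            zhi = _opt_axis(p, lin[2], ObjSense.MAX, backend,
                            fixed=[(lin[0], x), (lin[1], float(y))])
            if zlo.optimal and zhi.optimal:
                strip_lo.append((x, float(y), zlo.objective_value))
                strip_hi.append((x, float(y), zhi.objective_value))
        if strip_lo:
            facets.append(strip_lo)
            facets.append(strip_hi)
    return facets


def plot_projection(region: ProjectedRegion, path: str,
                    xlabel: str = "axis 1", ylabel: str = "axis 2") -> None:
    """Render a 2D projection polygon (or 3D facet cloud) to SVG/PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig = plt.figure(figsize=(5, 4))
    if len(region.axes) == 2:
        ax = fig.add_subplot(111)
        if region.boundary:
            xs = [v[0] for v in region.boundary] + [region.boundary[0][0]]
            ys = [v[1] for v in region.boundary] + [region.boundary[0][1]]
            ax.fill(xs, ys, alpha=0.3)
            ax.plot(xs, ys, "o-")
        ax.set_xlabel(xlabel)
        ax.set_ylabel(ylabel)
    else:
        ax = fig.add_subplot(111, projection="3d")
        for facet in region.boundary:
            xs, ys, zs = zip(*facet)
            ax.plot(xs, ys, zs, alpha=0.5)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
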