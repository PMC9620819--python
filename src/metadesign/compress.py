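"""Lossless network compression and candidate screening.

Three stages, applied to a fixpoint: removal of blocked reactions (zero in
every steady state, detected by FVA), lumping of fully coupled reaction
sets ("enzyme subsets": fluxes proportional with fixed rational ratios in
every steady state, detected from the rational nullspace of S), and merging
of parallel reactions (columns that are positive rational multiples of one
another).  All scale factors are exact rationals.

A :class:`CompressionRecord` keeps an invertible map between compressed and
original reaction spaces, expands intervention sets back to the original
namespace (knockout of a lumped column = any one member; knockout of a
merged parallel column = all members together) and recomputes costs (lump:
min over members; parallel: sum).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import sympy

from .analysis import InfeasibleError, fva
from .model import (LinearConstraint, MetabolicModel, Metabolite, ModelError,
                    Reaction)

__all__ = [
    "CompressionRecord", "CompressionStep",
    "remove_blocked", "lump_coupled", "merge_parallel", "compress",
    "screen_essentials", "expand_solutions", "translate_constraint",
]

BLOCKED_TOL = 1e-9


@dataclass
class CompressionStep:
    kind: str                       # blocked_removed | lumped | parallel_merged
    new_id: Optional[str]           # None for blocked_removed
    members: List[Tuple[str, Fraction]]  # (original reaction id, cumulative scale)
    # pre-step namespace bookkeeping, used to replay fluxes backwards:
    local_members: List[Tuple[str, Fraction]] = field(default_factory=list)
    local_bounds: List[Tuple[Fraction, Fraction]] = field(default_factory=list)


@dataclass
class CompressionRecord:
    steps: List[CompressionStep] = field(default_factory=list)
    # current compressed id -> [(original id, scale)]
    membership: Dict[str, List[Tuple[str, Fraction]]] = field(default_factory=dict)
    removed: Set[str] = field(default_factory=set)
    kind_of: Dict[str, str] = field(default_factory=dict)  # compressed id -> kind

    @classmethod
    def identity(cls, model: MetabolicModel) -> "CompressionRecord":
        rec = cls()
        rec.membership = {r.id: [(r.id, Fraction(1))] for r in model.reactions}
        rec.kind_of = {r.id: "plain" for r in model.reactions}
        return rec

    @property
    def forward_map(self) -> Dict[str, Optional[str]]:
        fmap: Dict[str, Optional[str]] = {rid: None for rid in self.removed}
        for cid, members in self.membership.items():
            for orig, _ in members:
                fmap[orig] = cid
        return fmap

    def expand_flux(self, flux: Mapping[str, float]) -> Dict[str, float]:
        """Expand a compressed flux distribution to the original namespace.

        Steps are replayed in reverse.  Lumped members are determined
        uniquely by their coupling ratios; a merged parallel column is
        distributed over its members deterministically (fill in member
        order, respecting member bounds).  Blocked reactions get flux 0.
        """
        out: Dict[str, float] = {k: float(v) for k, v in flux.items()}
        for step in reversed(self.steps):
            if step.kind == "blocked_removed":
                for pid, _ in step.local_members:
                    out[pid] = 0.0
                continue
            u = out.pop(step.new_id)
            if step.kind == "lumped":
                for pid, lam in step.local_members:
                    out[pid] = float(lam) * u
            else:  # parallel_merged: u = sum scale_j * v_j within bounds
                residual = u - sum(float(s) * float(lo) for (_, s), (lo, _)
                                   in zip(step.local_members, step.local_bounds))
                for (pid, s), (lo, hi) in zip(step.local_members, step.local_bounds):
                    inc = min(max(residual / float(s), 0.0), float(hi) - float(lo))
                    out[pid] = float(lo) + inc
                    residual -= float(s) * inc
        return out

    def to_json(self) -> str:
        return json.dumps({
            "steps": [{"kind": s.kind, "new_id": s.new_id,
                       "members": [[m, str(f)] for m, f in s.members]}
                      for s in self.steps],
            "forward_map": self.forward_map,
        }, indent=2)


def _record_from(model: MetabolicModel) -> CompressionRecord:
    return CompressionRecord.identity(model)


# ---------------------------------------------------------------------------
# Stage 1: blocked reactions
# ---------------------------------------------------------------------------

def remove_blocked(model: MetabolicModel,
                   fixed_constraints: Sequence[LinearConstraint] = (),
                   record: Optional[CompressionRecord] = None
                   ) -> Tuple[MetabolicModel, CompressionRecord]:
    """Remove reactions with FVA interval within 1e-9 of zero."""
    record = record or _record_from(model)
    try:
        ranges = fva(model, extra=list(fixed_constraints))
    except InfeasibleError:
        raise InfeasibleError("base steady-state system infeasible; cannot compress")
    blocked = [rid for rid, (lo, hi) in ranges.items()
               if abs(lo) <= BLOCKED_TOL and abs(hi) <= BLOCKED_TOL]
    if not blocked:
        return model, record
    keep = [r.copy() for r in model.reactions if r.id not in set(blocked)]
    used_mets = set().union(*(set(r.stoich) for r in keep)) if keep else set()
    mets = [m for m in model.metabolites if m.id in used_mets]
    objective = {k: v for k, v in model.objective.items() if k not in set(blocked)}
    new_model = MetabolicModel(mets, keep, objective, id=model.id)
    for rid in blocked:
        originals = record.membership.pop(rid)
        record.kind_of.pop(rid)
        record.removed.update(o for o, _ in originals)
        record.steps.append(CompressionStep(
            "blocked_removed", None, originals,
            local_members=[(rid, Fraction(0))]))
    return new_model, record


# ---------------------------------------------------------------------------
# Stage 2: coupled-reaction lumping (rational nullspace of S)
# ---------------------------------------------------------------------------

def _kernel_rows(model: MetabolicModel) -> List[Tuple[Fraction, ...]]:
    S = sympy.Matrix(len(model.metabolites), len(model.reactions),
                     lambda i, j: sympy.Rational(0))
    midx = model.metabolite_index
    for j, r in enumerate(model.reactions):
        for m, c in r.stoich.items():
            S[midx[m], j] = sympy.Rational(c.numerator, c.denominator)
    basis = S.nullspace()
    rows = []
    for j in range(len(model.reactions)):
        rows.append(tuple(Fraction(int(sympy.nsimplify(v[j]).p),
                                   int(sympy.nsimplify(v[j]).q))
                          for v in basis))
    return rows


def _proportional(a: Tuple[Fraction, ...], b: Tuple[Fraction, ...]
                  ) -> Optional[Fraction]:
    """Return lambda with a = lambda * b, or None."""
    if all(x == 0 for x in b):
        return None
    lam = None
    for x, y in zip(a, b):
        if y == 0:
            if x != 0:
                return None
            continue
        r = x / y
        if lam is None:
            lam = r
        elif lam != r:
            return None
    if lam is None or lam == 0:
        return None
    for x, y in zip(a, b):
        if x != lam * y:
            return None
    return lam


def lump_coupled(model: MetabolicModel,
                 record: Optional[CompressionRecord] = None,
                 protected: Iterable[str] = ()
                 ) -> Tuple[MetabolicModel, CompressionRecord]:
    """Lump maximal fully coupled reaction sets into single columns.

    Reactions i, j are fully coupled when their rows in a rational kernel
    basis of S are proportional; the coupling ratio is then fixed in every
    steady state.  Reactions in *protected* are never lumped.
    """
    record = record or _record_from(model)
    protected = set(protected)
    rows = _kernel_rows(model)
    n = len(model.reactions)
    groups: List[List[int]] = []
    assigned = [False] * n
    for i in range(n):
        if assigned[i] or model.reactions[i].id in protected:
            continue
        if all(x == 0 for x in rows[i]):
            continue  # kernel-blocked; FVA stage handles these
        group = [i]
        assigned[i] = True
        for j in range(i + 1, n):
            if assigned[j] or model.reactions[j].id in protected:
                continue
            if _proportional(rows[j], rows[i]) is not None:
                group.append(j)
                assigned[j] = True
        if len(group) > 1:
            groups.append(group)
    if not groups:
        return model, record
    grouped = {j for g in groups for j in g}
    new_rxns: List[Reaction] = []
    consumed: Set[int] = set()
    for i, r in enumerate(model.reactions):
        if i in consumed:
            continue
        group = next((g for g in groups if g[0] == i), None)
        if group is None:
            if i not in grouped:
                new_rxns.append(r.copy())
            continue
        consumed.update(group)
        rep = group[0]
        ratios = [(_proportional(rows[j], rows[rep]), j) for j in group]
        stoich: Dict[str, Fraction] = {}
        lo, hi = None, None
        members: List[Tuple[str, Fraction]] = []
        orig_members: List[Tuple[str, Fraction]] = []
        for lam, j in ratios:
            rj = model.reactions[j]
            for m, c in rj.stoich.items():
                stoich[m] = stoich.get(m, Fraction(0)) + lam * c
            # member bound: lb_j <= lam * u <= ub_j
            if lam > 0:
                mlo, mhi = rj.lb / lam, rj.ub / lam
            else:
                mlo, mhi = rj.ub / lam, rj.lb / lam
            lo = mlo if lo is None else max(lo, mlo)
            hi = mhi if hi is None else min(hi, mhi)
            members.append((rj.id, lam))
            for orig, scale in record.membership[rj.id]:
                orig_members.append((orig, scale * lam))
        if lo > hi:
            raise ModelError("coupled set has empty bound intersection; "
                             "blocked reactions must be removed first")
        new_id = "*".join(m for m, _ in members)
        stoich = {m: c for m, c in stoich.items() if c != 0}
        new_rxns.append(Reaction(new_id, stoich, lo, hi))
        for rid, _ in members:
            record.membership.pop(rid)
            record.kind_of.pop(rid)
        record.membership[new_id] = orig_members
        record.kind_of[new_id] = "lumped"
        record.steps.append(CompressionStep("lumped", new_id, orig_members,
                                            local_members=list(members)))
    used = set().union(*(set(r.stoich) for r in new_rxns)) if new_rxns else set()
    mets = [m for m in model.metabolites if m.id in used]
    rid_set = {r.id for r in new_rxns}
    objective = {k: v for k, v in model.objective.items() if k in rid_set}
    return MetabolicModel(mets, new_rxns, objective, id=model.id), record


# ---------------------------------------------------------------------------
# Stage 3: parallel-column merging
# ---------------------------------------------------------------------------

def merge_parallel(model: MetabolicModel,
                   record: Optional[CompressionRecord] = None,
                   protected: Iterable[str] = ()
                   ) -> Tuple[MetabolicModel, CompressionRecord]:
    """Merge reactions whose columns are positive rational multiples.

    The merged flux is the scaled sum of member fluxes; merged bounds are
    the sums of the scaled member bounds.
    """
    record = record or _record_from(model)
    protected = set(protected)
    n = len(model.reactions)

    def canon(r: Reaction):
        if not r.stoich:
            return None
        first_met = sorted(r.stoich)[0]
        pivot = r.stoich[first_met]
        return (tuple(sorted((m, c / pivot) for m, c in r.stoich.items())),
                pivot > 0), pivot

    buckets: Dict[object, List[Tuple[int, Fraction]]] = {}
    for i, r in enumerate(model.reactions):
        if r.id in protected:
            continue
        key = canon(r)
        if key is None:
            continue
        (shape, _), pivot = key
        buckets.setdefault(shape, []).append((i, pivot))
    # group by sign of pivot within a shape bucket: positive ratio required
    groups: List[List[Tuple[int, Fraction]]] = []
    for shape, entries in buckets.items():
        pos = [(i, p) for i, p in entries if p > 0]
        neg = [(i, p) for i, p in entries if p < 0]
        for sub in (pos, neg):
            if len(sub) > 1:
                groups.append(sub)
    if not groups:
        return model, record
    merged_idx = {i for g in groups for i, _ in g}
    new_rxns: List[Reaction] = []
    done: Set[int] = set()
    for i, r in enumerate(model.reactions):
        if i in done:
            continue
        if i not in merged_idx:
            new_rxns.append(r.copy())
            continue
        group = next(g for g in groups if g[0][0] == i)
        done.update(j for j, _ in group)
        rep_idx, rep_pivot = group[0]
        rep = model.reactions[rep_idx]
        # scale_j such that column_j = scale_j * column_rep  (scale_j > 0)
        lo = Fraction(0)
        hi = Fraction(0)
        members: List[Tuple[str, Fraction]] = []
        local_bounds: List[Tuple[Fraction, Fraction]] = []
        orig_members: List[Tuple[str, Fraction]] = []
        for j, pivot in group:
            rj = model.reactions[j]
            scale = pivot / rep_pivot
            lo += scale * rj.lb
            hi += scale * rj.ub
            members.append((rj.id, scale))
            local_bounds.append((rj.lb, rj.ub))
            for orig, s in record.membership[rj.id]:
                orig_members.append((orig, s * scale))
        new_id = "+".join(m for m, _ in members)
        new_rxns.append(Reaction(new_id, dict(rep.stoich), lo, hi))
        for rid, _ in members:
            record.membership.pop(rid)
            record.kind_of.pop(rid)
        record.membership[new_id] = orig_members
        record.kind_of[new_id] = "parallel_merged"
        record.steps.append(CompressionStep("parallel_merged", new_id, orig_members,
                                            local_members=list(members),
                                            local_bounds=local_bounds))
    used = set().union(*(set(r.stoich) for r in new_rxns)) if new_rxns else set()
    mets = [m for m in model.metabolites if m.id in used]
    rid_set = {r.id for r in new_rxns}
    objective = {k: v for k, v in model.objective.items() if k in rid_set}
    return MetabolicModel(mets, new_rxns, objective, id=model.id), record


# ---------------------------------------------------------------------------
# Fixpoint driver, essentiality screening, expansion
# ---------------------------------------------------------------------------

def compress(model: MetabolicModel,
             fixed_constraints: Sequence[LinearConstraint] = (),
             protected: Iterable[str] = ()
             ) -> Tuple[MetabolicModel, CompressionRecord]:
    """Blocked removal, then alternate lumping and merging to a fixpoint."""
    model, record = remove_blocked(model, fixed_constraints)
    for _ in range(50):
        n_before = len(model.reactions)
        model, record = lump_coupled(model, record, protected)
        model, record = merge_parallel(model, record, protected)
        if len(model.reactions) == n_before:
            break
    return model, record


def screen_essentials(model: MetabolicModel,
                      protect_constraints: Sequence[LinearConstraint]
                      ) -> Set[str]:
    """Reactions whose FVA interval under the protected phenotype excludes 0.

    These are essential for the protected region and are excluded as
    knockout candidates (they are not removed from the model).
    """
    try:
        ranges = fva(model, extra=list(protect_constraints))
    except InfeasibleError:
        raise InfeasibleError(
            "protected system infeasible without interventions; design problem is void")
    return {rid for rid, (lo, hi) in ranges.items()
            if lo > BLOCKED_TOL or hi < -BLOCKED_TOL}


def translate_constraint(c: LinearConstraint,
                         record: CompressionRecord) -> LinearConstraint:
    """Rewrite an original-namespace constraint in compressed coordinates.

    Lumped members substitute their coupling relation; removed (blocked)
    reactions contribute zero.  Coefficients on merged parallel members are
    only translatable when consistent across the merge.
    """
    back: Dict[str, Tuple[str, Fraction]] = {}
    for cid, members in record.membership.items():
        for orig, scale in members:
            back[orig] = (cid, scale)
    coeffs: Dict[str, Fraction] = {}
    merged_checks: Dict[str, Dict[str, Fraction]] = {}
    for rid, a in c.coeffs.items():
        if rid in record.removed:
            continue
        if rid not in back:
            raise ModelError(f"constraint reaction {rid!r} unknown to the record")
        cid, scale = back[rid]
        if record.kind_of[cid] == "parallel_merged":
            merged_checks.setdefault(cid, {})[rid] = a
            continue
        coeffs[cid] = coeffs.get(cid, Fraction(0)) + a * scale
    for cid, per_member in merged_checks.items():
        members = record.membership[cid]
        ratios = {per_member[orig] / scale for orig, scale in members
                  if orig in per_member}
        if len(per_member) != len(members) or len(ratios) != 1:
            raise ModelError(
                f"constraint not translatable through parallel merge {cid!r}")
        coeffs[cid] = coeffs.get(cid, Fraction(0)) + next(iter(ratios))
    if not coeffs:
        # constraint collapsed to "0 sense rhs": keep as trivially checkable
        raise ModelError("constraint vanished under compression (all terms blocked)")
    return LinearConstraint(coeffs, c.sense, c.rhs)


def expand_solutions(record: CompressionRecord,
                     compressed_solutions: Sequence[Iterable[str]],
                     costs: Optional[Mapping[str, float]] = None,
                     knockable: Optional[Iterable[str]] = None
                     ) -> List[Tuple[FrozenSet[str], float]]:
    """Expand compressed intervention sets to the original namespace.

    Knockout of a lumped column expands to the alternatives "any one
    member" (cartesian product across targets), of a merged parallel column
    to "all members together".  Duplicates and supersets of other expanded
    solutions are dropped.  Costs are recomputed from *costs* (original
    candidate costs, default 1 each).
    """
    costs = dict(costs or {})
    knockable = set(knockable) if knockable is not None else None
    step_of = {s.new_id: s for s in record.steps if s.new_id is not None}

    def alternatives(cid: str) -> List[FrozenSet[str]]:
        """All original-namespace sets whose knockout disables *cid*."""
        if cid in record.removed:
            raise ModelError(f"intervention on removed (blocked) reaction {cid!r}")
        step = step_of.get(cid)
        if step is None:
            if knockable is not None and cid not in knockable:
                return []
            return [frozenset([cid])]
        if step.kind == "lumped":
            # a serial chain is cut by disabling any single member
            out: List[FrozenSet[str]] = []
            for pid, _ in step.local_members:
                out.extend(alternatives(pid))
            return out
        # parallel paths are only cut by disabling all members at once
        per_member = [alternatives(pid) for pid, _ in step.local_members]
        out = []
        for combo in itertools.product(*per_member):
            out.append(frozenset().union(*combo))
        return out

    expanded: List[FrozenSet[str]] = []
    for sol in compressed_solutions:
        alts = [alternatives(cid) for cid in sol]
        for combo in itertools.product(*alts) if alts else [()]:
            full = frozenset().union(*combo) if combo else frozenset()
            expanded.append(full)
    # dedupe and drop supersets
    expanded = sorted(set(expanded), key=lambda s: (len(s), sorted(s)))
    minimal: List[FrozenSet[str]] = []
    for s in expanded:
        if not any(t < s or t == s for t in minimal):
            minimal.append(s)
    return [(s, sum(costs.get(t, 1.0) for t in s)) for s in minimal]
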