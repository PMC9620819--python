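"""Integration of GPR rules into the network structure.

Gene-level interventions are reduced to reaction-level ones by extending
the stoichiometric matrix with pseudo-metabolites and pseudo-reactions that
mirror the boolean structure of each rule:

* every gene ``g`` receives one *supply* pseudo-reaction
  ``GX_g:  -> gpool_g`` shared by all reactions citing ``g`` -- bounding it
  to zero is the gene knockout;
* a reaction with a rule consumes an *enzyme pool* metabolite at a rate
  equal to its flux; OR nodes contribute parallel supply routes into the
  pool (any branch suffices), AND nodes contribute a single route consuming
  every child pool at once (all branches required).

Under any gene knockout set G the maximal attainable |flux| of a reaction
is zero exactly when its rule evaluates false with the genes in G absent,
and is unchanged otherwise (the pseudo-reaction capacities are chosen to
never bind).  Reversible reactions are split into two irreversible
directions before rule attachment so that enzyme-pool consumption is
sign-free; the split is re-fused when reporting fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Mapping, Tuple

from .model import (GprRule, MetabolicModel, Metabolite, ModelError, Reaction)

__all__ = ["GprExtension", "simplify_gpr", "integrate_gpr"]

GENE_PREFIX = "GX_"


def simplify_gpr(rule: GprRule) -> GprRule:
    """Conservative boolean simplification, preserving logical equivalence.

    Flattens nested same-kind nodes, removes duplicate children, collapses
    single-child nodes and applies the absorption laws
    ``X or (X and Y) -> X`` and ``X and (X or Y) -> X``.
    """
    if rule.is_empty or rule.kind == GprRule.LIT:
        return rule
    # simplify and flatten children
    flat: List[GprRule] = []
    for child in (simplify_gpr(c) for c in rule.children):
        if child.kind == rule.kind:
            flat.extend(child.children)
        else:
            flat.append(child)
    # dedupe by canonical key
    seen = {}
    for c in flat:
        seen.setdefault(c.canonical_key(), c)
    children = list(seen.values())

    # absorption: for OR, drop child c when some sibling's conjunct set is a
    # subset of c's; dually for AND with disjunct sets.  Only literal /
    # flat-literal children participate (deeper nesting is left intact).
    def literal_set(node: GprRule, inner_kind: str):
        if node.kind == GprRule.LIT:
            return frozenset([node.gene])
        if node.kind == inner_kind and all(c.kind == GprRule.LIT
                                           for c in node.children):
            return frozenset(c.gene for c in node.children)
        return None

    inner = GprRule.AND if rule.kind == GprRule.OR else GprRule.OR
    sets = [literal_set(c, inner) for c in children]
    keep = []
    for i, c in enumerate(children):
        absorbed = False
        if sets[i] is not None:
            for j, s in enumerate(sets):
                if j != i and s is not None and s < sets[i]:
                    absorbed = True
                    break
                if j < i and s is not None and s == sets[i]:
                    absorbed = True  # duplicate under commutativity
                    break
        if not absorbed:
            keep.append(c)
    if len(keep) == 1:
        return keep[0]
    return GprRule(rule.kind, children=keep)


@dataclass
class GprExtension:
    extended_model: MetabolicModel
    gene_targets: Dict[str, str]          # gene id -> supply pseudo-reaction id
    origin_map: Dict[str, str]            # pseudo-reaction id -> description
    split_reactions: Dict[str, Tuple[str, str]] = field(default_factory=dict)
    original_ids: List[str] = field(default_factory=list)

    def project(self, flux: Mapping[str, float]) -> Dict[str, float]:
        """Project an extended-model flux onto the original reactions."""
        out = {}
        for rid in self.original_ids:
            if rid in self.split_reactions:
                fwd, rev = self.split_reactions[rid]
                out[rid] = flux[fwd] - flux[rev]
            else:
                out[rid] = flux[rid]
        return out


def integrate_gpr(model: MetabolicModel, simplify: bool = True) -> GprExtension:
    """Build the GPR-extended model (see module docstring for the scheme)."""
    genes = model.genes()
    rids = set(r.id for r in model.reactions)
    for g in genes:
        if g in rids:
            raise ModelError(f"gene id {g!r} collides with a reaction id")

    mets = [Metabolite(m.id, m.name) for m in model.metabolites]
    rxns: List[Reaction] = []
    gene_targets: Dict[str, str] = {}
    origin_map: Dict[str, str] = {}
    split: Dict[str, Tuple[str, str]] = {}

    # gene supply capacity: sum of absolute flux bounds of citing reactions,
    # so the supply never binds unless knocked out
    cap: Dict[str, Fraction] = {g: Fraction(0) for g in genes}
    for r in model.reactions:
        for g in r.gpr.genes():
            cap[g] += max(abs(r.lb), abs(r.ub))
    for g in sorted(genes):
        mets.append(Metabolite(f"gpool_{g}"))
        rid = GENE_PREFIX + g
        rxns.append(Reaction(rid, {f"gpool_{g}": Fraction(1)}, 0, cap[g]))
        gene_targets[g] = rid
        origin_map[rid] = f"gene {g}"

    counter = [0]

    def new_id(base: str) -> str:
        counter[0] += 1
        return f"GT_{base}_{counter[0]}"

    def build_node(node: GprRule, base: str, capacity: Fraction) -> str:
        """Return the pool-metabolite id supplying this rule node."""
        if node.kind == GprRule.LIT:
            return f"gpool_{node.gene}"
        pool = new_id(base) + "_pool"
        mets.append(Metabolite(pool))
        if node.kind == GprRule.AND:
            stoich = {pool: Fraction(1)}
            for child in node.children:
                child_pool = build_node(child, base, capacity)
                stoich[child_pool] = stoich.get(child_pool, Fraction(0)) - 1
            rid = new_id(base)
            rxns.append(Reaction(rid, stoich, 0, capacity))
            origin_map[rid] = f"GPR term (AND) of {base}"
        else:  # OR: one parallel supply route per child
            for child in node.children:
                child_pool = build_node(child, base, capacity)
                rid = new_id(base)
                rxns.append(Reaction(rid, {child_pool: Fraction(-1),
                                           pool: Fraction(1)}, 0, capacity))
                origin_map[rid] = f"GPR term (OR branch) of {base}"
        return pool

    def attach(rid: str, stoich: Dict[str, Fraction], ub: Fraction,
               rule: GprRule) -> Reaction:
        capacity = ub if ub > 0 else Fraction(1)
        pool = build_node(rule, rid, capacity)
        stoich = dict(stoich)
        stoich[pool] = stoich.get(pool, Fraction(0)) - 1
        return Reaction(rid, stoich, 0, ub)

    for r in model.reactions:
        rule = simplify_gpr(r.gpr) if simplify else r.gpr
        if rule.is_empty:
            rxns.append(r.copy())
            continue
        if r.reversible:
            fwd_id, rev_id = r.id, r.id + "__rev"
            rxns.append(attach(fwd_id, r.stoich, max(r.ub, Fraction(0)), rule))
            rev_stoich = {m: -c for m, c in r.stoich.items()}
            rxns.append(attach(rev_id, rev_stoich, -r.lb, rule))
            split[r.id] = (fwd_id, rev_id)
            origin_map[rev_id] = f"reverse direction of {r.id}"
        else:
            rxns.append(attach(r.id, r.stoich, r.ub, rule))

    objective = {}
    for rid, coef in model.objective.items():
        if rid in split:
            fwd, rev = split[rid]
            objective[fwd] = coef
            objective[rev] = -coef
        else:
            objective[rid] = coef
    ext = MetabolicModel(mets, rxns, objective, id=model.id + "_gpr")
    return GprExtension(ext, gene_targets, origin_map, split,
                        [r.id for r in model.reactions])
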