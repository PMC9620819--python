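"""SBML Level 3 / FBC input and output, mapped through COBRApy.

Stoichiometric coefficients are converted to exact rationals from their
shortest decimal representation, so round-tripping a model with decimal
coefficients is lossless.
"""

from __future__ import annotations

import os
from fractions import Fraction

from .model import (GprRule, LinearConstraint, MetabolicModel, Metabolite,
                    ModelError, Reaction)

__all__ = ["read_sbml", "write_sbml", "from_cobra", "to_cobra"]


def _gpr_from_cobra(rule_string: str) -> GprRule:
    return GprRule.from_string(rule_string or "")


def from_cobra(cmodel) -> MetabolicModel:
    """Convert a ``cobra.Model`` to a :class:`MetabolicModel`."""
    mets = [Metabolite(m.id, m.name or "") for m in cmodel.metabolites]
    declared = {m.id for m in mets}
    rxns = []
    for r in cmodel.reactions:
        if r.lower_bound is None or r.upper_bound is None:  # pragma: no cover
            raise ModelError(f"reaction {r.id!r} has no flux bounds")
        stoich = {}
        for met, coef in r.metabolites.items():
            if met.id not in declared:  # pragma: no cover - cobra validates this
                raise ModelError(
                    f"reaction {r.id!r} references undeclared metabolite {met.id!r}")
            stoich[met.id] = Fraction(str(float(coef)))
        rxns.append(Reaction(r.id, stoich, Fraction(str(float(r.lower_bound))),
                             Fraction(str(float(r.upper_bound))),
                             gpr=_gpr_from_cobra(r.gene_reaction_rule),
                             name=r.name or ""))
    objective = {}
    for r in cmodel.reactions:
        coef = r.objective_coefficient
        if coef:
            objective[r.id] = Fraction(str(float(coef)))
    return MetabolicModel(mets, rxns, objective, id=cmodel.id or "model")


def to_cobra(model: MetabolicModel):
    """Convert to a ``cobra.Model`` (floats at the boundary)."""
    import cobra

    cmodel = cobra.Model(model.id)
    cmets = {m.id: cobra.Metabolite(m.id, name=m.name, compartment="c")
             for m in model.metabolites}
    crxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name,
                            lower_bound=float(r.lb), upper_bound=float(r.ub))
        crxns.append(cr)
    cmodel.add_reactions(crxns)
    for r, cr in zip(model.reactions, crxns):
        cr.add_metabolites({cmets[m]: float(c) for m, c in r.stoich.items()})
        if not r.gpr.is_empty:
            cr.gene_reaction_rule = r.gpr.to_string()
    cmodel.objective = {cmodel.reactions.get_by_id(rid): float(c)
                        for rid, c in model.objective.items()} or \
        cmodel.problem.Objective(0)
    if model.objective:
        cmodel.objective = sum(float(c) * cmodel.reactions.get_by_id(rid).flux_expression
                               for rid, c in model.objective.items())
    return cmodel


def read_sbml(path: str) -> MetabolicModel:
    """Read an SBML Level 3 + FBC model file."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"SBML file not found: {path}")
    import cobra.io

    try:
        cmodel = cobra.io.read_sbml_model(path)
    except Exception as exc:
        raise ModelError(f"malformed SBML in {path!r}: {exc}") from exc
    return from_cobra(cmodel)


def write_sbml(model: MetabolicModel, path: str) -> None:
    """Write the model as SBML Level 3 + FBC."""
    import cobra.io

    cobra.io.write_sbml_model(to_cobra(model), path)
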