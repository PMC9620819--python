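"""Core data model for constraint-based metabolic networks.

A metabolic network is a stoichiometric matrix S (rows = metabolites,
columns = reactions) together with flux bounds ``lb <= v <= ub`` and,
optionally, boolean gene-protein-reaction (GPR) rules per reaction.  The
steady-state flux space is ``{v : S v = 0, lb <= v <= ub}``.

Stoichiometric coefficients and constraint coefficients are stored as exact
:class:`fractions.Fraction` values; floating point enters only at the solver
boundary.  This makes the downstream network compression (which relies on
rational nullspace computations) exact by construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

Number = Union[int, float, Fraction]

__all__ = [
    "Sense",
    "Metabolite",
    "GprRule",
    "Reaction",
    "MetabolicModel",
    "LinearConstraint",
    "ModelError",
    "ConstraintSyntaxError",
    "parse_linear_constraints",
    "format_constraint",
    "fixture",
    "FIXTURE_NAMES",
]


class ModelError(ValueError):
    """Raised for structurally invalid models or unresolvable identifiers."""


class ConstraintSyntaxError(ModelError):
    """Raised when a linear-constraint string cannot be parsed."""


def _frac(x: Number) -> Fraction:
    """Convert a number to an exact Fraction.

    Floats are converted through their shortest decimal representation so
    that e.g. ``0.1`` becomes ``1/10`` rather than its binary expansion.
    """
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, float):
        if x != x or x in (float("inf"), float("-inf")):
            raise ModelError(f"non-finite coefficient {x!r}")
        return Fraction(str(x))
    raise ModelError(f"cannot interpret {x!r} as a rational number")


class Sense(Enum):
    """Direction of a linear constraint."""

    LE = "<="
    GE = ">="
    EQ = "="

    @classmethod
    def parse(cls, token: str) -> "Sense":
        token = token.strip()
        for s in cls:
            if token == s.value:
                return s
        if token == "==":
            return cls.EQ
        raise ConstraintSyntaxError(f"unknown constraint sense {token!r}")


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""

    def __post_init__(self):
        if not self.id:
            raise ModelError("metabolite id must be non-empty")


class GprRule:
    """Boolean gene-protein-reaction association.

    A rule is a finite tree whose nodes are AND, OR or gene literals.  An
    empty rule (``GprRule.empty()``) means the reaction is not gene
    associated and can never be disabled through gene interventions.
    """

    AND = "and"
    OR = "or"
    LIT = "lit"

    __slots__ = ("kind", "gene", "children")

    def __init__(self, kind: str, gene: Optional[str] = None,
                 children: Sequence["GprRule"] = ()):
        self.kind = kind
        self.gene = gene
        self.children = tuple(children)
        if kind == self.LIT:
            if not gene:
                raise ModelError("literal GPR node requires a gene id")
        elif kind in (self.AND, self.OR):
            if len(self.children) < 2:
                raise ModelError(f"{kind.upper()} node requires >= 2 children")
        elif kind != "empty":
            raise ModelError(f"unknown GPR node kind {kind!r}")

    # -- constructors ------------------------------------------------------
    @classmethod
    def empty(cls) -> "GprRule":
        return cls("empty")

    @classmethod
    def lit(cls, gene: str) -> "GprRule":
        return cls(cls.LIT, gene=gene)

    @classmethod
    def and_(cls, *children: "GprRule") -> "GprRule":
        return cls(cls.AND, children=children)

    @classmethod
    def or_(cls, *children: "GprRule") -> "GprRule":
        return cls(cls.OR, children=children)

    @classmethod
    def from_string(cls, text: str) -> "GprRule":
        """Parse a rule string such as ``"g1 and (g2 or g3)"``."""
        text = text.strip()
        if not text:
            return cls.empty()
        tokens = re.findall(r"\(|\)|\band\b|\bor\b|&&?|\|\|?|[^\s()&|]+", text)
        pos = 0

        def peek():
            return tokens[pos] if pos < len(tokens) else None

        def take():
            nonlocal pos
            tok = tokens[pos]
            pos += 1
            return tok

        def parse_or():
            node = parse_and()
            parts = [node]
            while peek() in ("or", "|", "||"):
                take()
                parts.append(parse_and())
            return parts[0] if len(parts) == 1 else cls.or_(*parts)

        def parse_and():
            parts = [parse_atom()]
            while peek() in ("and", "&", "&&"):
                take()
                parts.append(parse_atom())
            return parts[0] if len(parts) == 1 else cls.and_(*parts)

        def parse_atom():
            tok = take()
            if tok == "(":
                node = parse_or()
                if peek() != ")":
                    raise ModelError(f"unbalanced parentheses in GPR {text!r}")
                take()
                return node
            if tok in (")", "and", "or"):
                raise ModelError(f"malformed GPR rule {text!r}")
            return cls.lit(tok)

        node = parse_or()
        if pos != len(tokens):
            raise ModelError(f"trailing tokens in GPR rule {text!r}")
        return node

    # -- queries -----------------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return self.kind == "empty"

    def genes(self) -> frozenset:
        if self.is_empty:
            return frozenset()
        if self.kind == self.LIT:
            return frozenset([self.gene])
        return frozenset().union(*(c.genes() for c in self.children))

    def evaluate(self, knocked: Iterable[str]) -> bool:
        """Truth value when genes in *knocked* are absent and all others present."""
        knocked = set(knocked)
        if self.is_empty:
            return True
        if self.kind == self.LIT:
            return self.gene not in knocked
        vals = (c.evaluate(knocked) for c in self.children)
        return all(vals) if self.kind == self.AND else any(vals)

    def to_string(self) -> str:
        if self.is_empty:
            return ""
        if self.kind == self.LIT:
            return self.gene
        sep = f" {self.kind} "
        parts = []
        for c in self.children:
            s = c.to_string()
            if c.kind in (self.AND, self.OR) and c.kind != self.kind:
                s = f"({s})"
            elif c.kind == self.kind:
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)

    def canonical_key(self):
        """Hashable key identical for rules equal up to commutative reordering."""
        if self.is_empty:
            return ("empty",)
        if self.kind == self.LIT:
            return (self.LIT, self.gene)
        return (self.kind, tuple(sorted(c.canonical_key() for c in self.children)))

    def __eq__(self, other):
        return isinstance(other, GprRule) and self.canonical_key() == other.canonical_key()

    def __hash__(self):
        return hash(self.canonical_key())

    def __repr__(self):
        return f"GprRule({self.to_string() or 'empty'})"


@dataclass
class Reaction:
    id: str
    stoich: Dict[str, Fraction]
    lb: Fraction = Fraction(0)
    ub: Fraction = Fraction(0)
    gpr: GprRule = field(default_factory=GprRule.empty)
    name: str = ""

    def __post_init__(self):
        if not self.id:
            raise ModelError("reaction id must be non-empty")
        self.lb = _frac(self.lb)
        self.ub = _frac(self.ub)
        if self.lb > self.ub:
            raise ModelError(f"reaction {self.id}: lb {self.lb} > ub {self.ub}")
        self.stoich = {m: _frac(c) for m, c in self.stoich.items() if _frac(c) != 0}

    @property
    def reversible(self) -> bool:
        return self.lb < 0

    def copy(self) -> "Reaction":
        return Reaction(self.id, dict(self.stoich), self.lb, self.ub, self.gpr, self.name)


@dataclass
class LinearConstraint:
    """A row ``sum_i coeffs[i] * x_i  (sense)  rhs`` over named variables."""

    coeffs: Dict[str, Fraction]
    sense: Sense
    rhs: Fraction

    def __post_init__(self):
        self.coeffs = {k: _frac(v) for k, v in self.coeffs.items()}
        self.rhs = _frac(self.rhs)
        if not self.coeffs:
            raise ModelError("constraint has an empty left-hand side")

    def validate(self, model: "MetabolicModel") -> None:
        for rid in self.coeffs:
            if rid not in model.reaction_index:
                raise ModelError(f"unknown reaction id {rid!r} in constraint")

    def copy(self) -> "LinearConstraint":
        return LinearConstraint(dict(self.coeffs), self.sense, self.rhs)


class MetabolicModel:
    """Ordered metabolites + reactions + a linear flux objective."""

    def __init__(self, metabolites: Sequence[Metabolite],
                 reactions: Sequence[Reaction],
                 objective: Optional[Mapping[str, Number]] = None,
                 id: str = "model"):
        self.id = id
        self.metabolites: List[Metabolite] = list(metabolites)
        self.reactions: List[Reaction] = list(reactions)
        self.objective: Dict[str, Fraction] = {
            k: _frac(v) for k, v in (objective or {}).items()
        }
        self._validate()

    def _validate(self):
        mids = [m.id for m in self.metabolites]
        if len(set(mids)) != len(mids):
            raise ModelError("duplicate metabolite ids")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise ModelError("duplicate reaction ids")
        mset = set(mids)
        for r in self.reactions:
            for m in r.stoich:
                if m not in mset:
                    raise ModelError(
                        f"reaction {r.id!r} references undeclared metabolite {m!r}")
        for rid in self.objective:
            if rid not in set(rids):
                raise ModelError(f"objective references unknown reaction {rid!r}")

    # -- lookups -----------------------------------------------------------
    @property
    def metabolite_index(self) -> Dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    @property
    def reaction_index(self) -> Dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[self.reaction_index[rid]]
        except KeyError:
            raise ModelError(f"unknown reaction id {rid!r}") from None

    def genes(self) -> frozenset:
        return frozenset().union(*(r.gpr.genes() for r in self.reactions)) \
            if self.reactions else frozenset()

    # -- matrices ----------------------------------------------------------
    def stoichiometric_matrix(self, exact: bool = False):
        """S with rows = metabolites (model order), columns = reactions.

        With ``exact=True`` the entries are Fractions (object dtype),
        otherwise float64.
        """
        midx = self.metabolite_index
        if exact:
            S = [[Fraction(0)] * len(self.reactions) for _ in self.metabolites]
            for j, r in enumerate(self.reactions):
                for m, c in r.stoich.items():
                    S[midx[m]][j] = c
            return S
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, c in r.stoich.items():
                S[midx[m], j] = float(c)
        return S

    def bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        lb = np.array([float(r.lb) for r in self.reactions])
        ub = np.array([float(r.ub) for r in self.reactions])
        return lb, ub

    def copy(self) -> "MetabolicModel":
        return MetabolicModel([Metabolite(m.id, m.name) for m in self.metabolites],
                              [r.copy() for r in self.reactions],
                              dict(self.objective), id=self.id)

    def __repr__(self):
        return (f"MetabolicModel(id={self.id!r}, {len(self.metabolites)} metabolites, "
                f"{len(self.reactions)} reactions)")


# ---------------------------------------------------------------------------
# Linear-constraint strings
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(
    r"\s*(?P<sign>[+-])?\s*(?P<num>\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)?\s*\*?\s*"
    r"(?P<id>[A-Za-z_][\w.\-\[\]]*)\s*")
_SENSE_RE = re.compile(r"(<=|>=|==|=)")


def parse_linear_constraints(text: str,
                             model: Optional[MetabolicModel] = None
                             ) -> List[LinearConstraint]:
    """Parse constraint strings like ``"2 R1 + 3 R2 <= 6, -R3 = 0"``.

    Constraints are separated by newlines or commas.  Each consists of signed
    terms (``2 R1``, ``-R2``, ``1.5 R3``) joined by ``+``/``-``, a sense
    (``<=``, ``>=``, ``=``), and a numeric right-hand side.  Duplicate terms
    are summed.  Identifiers are validated against *model* when given.
    """
    out: List[LinearConstraint] = []
    for chunk in re.split(r"[\n,]", text):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = _SENSE_RE.split(chunk)
        if len(parts) != 3:
            raise ConstraintSyntaxError(
                f"expected exactly one of <=, >=, = in {chunk!r}")
        lhs, sense_tok, rhs_tok = parts
        try:
            rhs = _frac(float(rhs_tok.strip()))
        except ValueError:
            raise ConstraintSyntaxError(f"right-hand side {rhs_tok!r} is not a number")
        coeffs: Dict[str, Fraction] = {}
        pos = 0
        first = True
        lhs_s = lhs.strip()
        if not lhs_s:
            raise ConstraintSyntaxError(f"empty left-hand side in {chunk!r}")
        while pos < len(lhs_s):
            m = _TERM_RE.match(lhs_s, pos)
            if not m or (not first and m.group("sign") is None):
                raise ConstraintSyntaxError(f"malformed expression {chunk!r}")
            coef = _frac(float(m.group("num"))) if m.group("num") else Fraction(1)
            if m.group("sign") == "-":
                coef = -coef
            rid = m.group("id")
            coeffs[rid] = coeffs.get(rid, Fraction(0)) + coef
            pos = m.end()
            first = False
        c = LinearConstraint(coeffs, Sense.parse(sense_tok), rhs)
        if model is not None:
            c.validate(model)
        out.append(c)
    return out


def format_constraint(c: LinearConstraint) -> str:
    """Canonical printer; ``parse_linear_constraints`` is its left inverse."""
    terms = []
    for rid in sorted(c.coeffs):
        coef = c.coeffs[rid]
        sign = "-" if coef < 0 else "+"
        mag = abs(coef)
        body = rid if mag == 1 else f"{float(mag)!r} {rid}"
        terms.append((sign, body))
    first_sign, first_body = terms[0]
    s = (first_sign if first_sign == "-" else "") + first_body
    for sign, body in terms[1:]:
        s += f" {sign} {body}"
    return f"{s} {c.sense.value} {float(c.rhs)!r}"


# ---------------------------------------------------------------------------
# Bundled toy networks
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("chain3", "coupler6", "parallel2", "blocked1")


def fixture(name: str) -> MetabolicModel:
    """Return one of the bundled toy networks.

    ``chain3``   – linear 3-step pathway with a middle bottleneck.
    ``coupler6`` – branched network where one branch co-produces a product P;
                   carries GPR rules on the internal reactions.
    ``parallel2`` – two identical parallel routes A -> B.
    ``blocked1`` – chain3 plus an isolated (blocked) reaction C -> D.
    """
    F = Fraction
    if name == "chain3":
        return MetabolicModel(
            [Metabolite("A"), Metabolite("B")],
            [Reaction("R1", {"A": F(1)}, 0, 10),
             Reaction("R2", {"A": F(-1), "B": F(1)}, 0, 5),
             Reaction("R3", {"B": F(-1)}, 0, 10)],
            objective={"R3": 1}, id="chain3")
    if name == "coupler6":
        return MetabolicModel(
            [Metabolite("A"), Metabolite("B"), Metabolite("P")],
            [Reaction("R_up", {"A": F(1)}, 0, 10),
             Reaction("R_1", {"A": F(-1), "B": F(1)}, 0, 10,
                      gpr=GprRule.from_string("g1 or g2")),
             Reaction("R_3", {"A": F(-2), "B": F(1), "P": F(1)}, 0, 10,
                      gpr=GprRule.from_string("g2 and g3")),
             Reaction("R_bio", {"B": F(-1)}, 0, 10, gpr=GprRule.from_string("g4")),
             Reaction("R_pex", {"P": F(-1)}, 0, 10)],
            objective={"R_bio": 1}, id="coupler6")
    if name == "parallel2":
        return MetabolicModel(
            [Metabolite("A"), Metabolite("B")],
            [Reaction("Ra", {"A": F(-1), "B": F(1)}, 0, 10),
             Reaction("Rb", {"A": F(-1), "B": F(1)}, 0, 10),
             Reaction("Rin", {"A": F(1)}, 0, 10),
             Reaction("Rout", {"B": F(-1)}, 0, 10)],
            objective={"Rout": 1}, id="parallel2")
    if name == "blocked1":
        base = fixture("chain3")
        return MetabolicModel(
            base.metabolites + [Metabolite("C"), Metabolite("D")],
            base.reactions + [Reaction("Rx", {"C": F(-1), "D": F(1)}, 0, 10)],
            objective=dict(base.objective), id="blocked1")
    raise ModelError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
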