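# metadesign

MILP-based computational design of metabolic networks: one framework that
unites the nested strain-optimization methods **OptKnock**, **RobustKnock**
and **OptCouple** with the more general **minimal cut set (MCS)** approach,
on top of the usual constraint-based analysis toolkit (FBA, FVA, true yield
optimization, production envelopes).

## Who this is for

Metabolic engineers and systems biologists who want to compute intervention
strategies — reaction or gene knockouts, reaction additions, regulatory
constraints — that force a microbial host into a desired behaviour (e.g.
growth-coupled production of a target chemical), and to analyse the
resulting designs with standard LP tools, all from Python or a small CLI.

## The model

A metabolic network is a stoichiometric matrix S with flux bounds; its
steady-state flux space is

    F = { v : S v = 0,  lb <= v <= ub }.

A design problem combines *modules* over a shared vector of binary
intervention variables z (knockout z_i = 1 forces v_i = 0; an addition is
the inverse; a regulatory intervention switches a linear constraint on):

- **protect** — a desired region D v <= d that must stay feasible; encoded
  as a primal flux copy.
- **suppress** — an undesired region T v <= t that must become infeasible;
  encoded by a Farkas infeasibility certificate: multipliers y >= 0 (and
  free u for S v = 0) with yᵀA = 0 and certificate value yᵀb <= −1, where
  the knockout binaries scale the bound rows of b to zero.
- **optknock** — max over z of the product rate at the cell's growth
  optimum (optimistic tie-breaking); the inner LP `max c·v` is collapsed to
  a single level by strong duality (primal copy + dual block + zero-gap
  equality c·v = b(z)ᵀλ).
- **robustknock** — the pessimistic counterpart `max_z min{p·v : v in
  argmax c·v}`; the adversarial minimization over the inner-optimal face is
  itself an LP (in the face fluxes *and* the first-stage duals) and is
  dualized a second time, so the MILP maximizes a valid lower-bound
  certificate of the worst-case production rate.
- **optcouple** — maximizes the growth-coupling potential, the gap between
  maximal growth with production enabled and with production disabled.

All products of binaries with dual variables are linearized exactly through
gated auxiliary variables (indicator constraints, rewritten with tight
big-M terms for solvers without native indicator support).

The pipeline around the MILP: boolean gene–protein–reaction (GPR) rules are
integrated into the network as pseudo-metabolites/-reactions so gene
knockouts become reaction knockouts; FVA screens out candidates essential
for protected phenotypes; exact rational network compression (blocked-
reaction removal, fully-coupled lumping via the rational nullspace of S,
parallel-column merging) shrinks the MILP, and solutions are expanded back
losslessly (lumped column: any one member; merged column: all members).
Enumeration proceeds with exclusion cuts in non-decreasing cost order, and
every reported solution is re-verified by plain LPs against the original,
un-reformulated module definitions.

## Worked example

The bundled `coupler6` toy network takes up substrate A (`R_up`, up to 10),
converts it to biomass precursor B either directly (`R_1: A -> B`) or via a
product-coupled route (`R_3: 2A -> B + P`), grows (`R_bio: B ->`) and
exports the product (`R_pex: P ->`).

```python
import metadesign as md

m = md.fixture("coupler6")

# all minimal cut sets (budget 2) against growth >= 1
sols = md.compute_strain_designs(
    m, modules=[md.suppress("R_bio >= 1", m)],
    candidates=[md.InterventionCandidate(r.id) for r in m.reactions],
    max_cost=2)
for s in sols:
    print(sorted(s.targets), s.cost, s.status)
```

prints

```
['R_bio'] 1.0 verified
['R_up'] 1.0 verified
['R_1', 'R_3'] 2.0 verified
['R_1', 'R_pex'] 2.0 verified
```

i.e. growth is cut by removing uptake or biomass formation alone, or by
removing both routes to B — where cutting the product-coupled route either
at `R_3` itself or at its obligatorily coupled export `R_pex` works.

```python
ok = md.compute_strain_designs(
    m, modules=[md.optknock({"R_bio": 1}, {"R_pex": 1}),
                md.protect("R_bio >= 1", m)],
    candidates=[md.InterventionCandidate(r.id) for r in m.reactions],
    max_cost=1)
print(sorted(ok[0].targets), ok[0].objective_value)   # ['R_1'] 5.0
```

Knocking out the direct route `R_1` forces all growth through the
product-coupled branch: at the new growth optimum (5) the strain exports 5
units of product, against 0 for the wild type.  RobustKnock and OptCouple
return the same design with worst-case product 5 and growth-coupling gap 5.

```python
env = md.flux_space_projection(
    m, [md.RatioExpression.rate("R_bio"), md.RatioExpression.rate("R_pex")])
print(env.boundary)    # [(0.0, 0.0), (10.0, 0.0), (5.0, 5.0)]
```

The production envelope is the triangle (0,0)–(10,0)–(5,5); the maximal
product yield `R_pex/R_up` under growth is 0.5.

The same computations are available from the shell:

```bash
metadesign compute --model model.xml --setup setup.json --out solutions.tsv
metadesign analyze --model fixture:coupler6 --mode yield \
    --numerator R_pex --denominator R_up --constraints "R_bio >= 1"
metadesign plot --model fixture:coupler6 --axes R_bio,R_pex --out envelope.svg
```

## Layout

- `metadesign.model` — network data model, constraint grammar, toy fixtures
- `metadesign.io` — SBML Level 3 / FBC input and output (via COBRApy)
- `metadesign.milp` — solver-agnostic MILP container, indicator/big-M, backends
- `metadesign.analysis` — FBA, FVA, yield optimization, projections
- `metadesign.gpr` — GPR simplification and network integration
- `metadesign.compress` — exact compression and solution expansion
- `metadesign.design` — module-to-MILP builders (Farkas, strong duality)
- `metadesign.enumerate` — pipeline, enumeration, verification, reporting
- `metadesign.cli` — `metadesign` command line

See `docs/methods.md` for the mathematical background and design choices.
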