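# Methods

## Scope and model assumptions

The package operates on constraint-based (stoichiometric) models: a network
of m metabolites and n reactions with stoichiometric matrix S, flux bounds
`lb <= v <= ub` (conventionally mmol·gDW⁻¹·h⁻¹; dimensionless in the toy
networks) and the steady-state assumption `S v = 0`.  No thermodynamic,
loopless or kinetic constraints are modelled.  Stoichiometric and
constraint coefficients are stored as exact rationals (`fractions.Fraction`,
converted from the shortest decimal representation of SBML doubles); floats
appear only at the solver boundary.  This makes the compression stage exact
and reproducible.

## Design problems

A design problem is a list of modules over one shared vector of binary
intervention variables z with costs and a budget `Σ cost_i z_i <= max_cost`:

* knockout of reaction i: z_i = 1 forces v_i = 0 in every flux copy,
  encoded by scaling the bound rows, `v_i <= ub_i (1 − z_i)` and
  `v_i >= lb_i (1 − z_i)`;
* addition (inverse knockout): bounds scale with z_i instead of 1 − z_i,
  so the reaction is disabled unless bought;
* regulatory intervention: a linear constraint `g·v <= r` attached through
  a big-M slack `g·v <= r + M(1 − z)` with M computed from the bound box,
  active in every flux copy when z = 1;
* gene knockout: resolved to the knockout of the gene's supply
  pseudo-reaction after GPR integration (below).

### Suppress modules (minimal cut sets)

A region `{v : S v = 0, bounds(z), T v <= t}` is infeasible iff a Farkas
certificate exists: multipliers `u` (free, steady state), `y >= 0` (bound
and region rows) with `Sᵀu + Aᵀy = 0` and certificate value `bᵀy <= −1`.
The value −1 is an arbitrary negative normalization (certificates are
scale-invariant); dual variables are bounded by ±10³ by default, which is
far beyond any certificate needed on bounded networks of the tested size
but keeps the MILP bounded.  Because the knockout binaries appear in the
right-hand sides b(z), the certificate value contains products z·y; each
product is replaced by an auxiliary variable q with the exact gating
`q = y if z = 1 else 0`, expressed as indicator constraints.  This
bound-scaling encoding is equivalent to relaxing the knocked column's dual
equality and was chosen because it makes all four module types instances of
one generic "dualize an LP with binary-affine right-hand sides" routine.

Suppress regions are closed (`<=`, `>=` only): where the classical cut-set
setting needs "flux strictly positive", the user writes an explicit
threshold (the bundled problems use `v >= 1`).  A region that is already
infeasible without interventions makes the module vacuous, not an error.

### Nested modules

*OptKnock* embeds the inner LP `max c·v` by strong duality: the primal flux
copy, the dual system of the z-parametrized inner LP, and the zero-gap
equality `c·v = b(z)ᵀλ` (products again gated).  The outer objective
maximizes `p·v` over the primal copy, i.e. the optimistic value on the
inner-optimal face; RobustKnock is the pessimistic counterpart.

*RobustKnock* needs `max_z min {p·v : v ∈ argmax c·v}`.  The inner-optimal
face is described by primal feasibility, dual feasibility and the zero-gap
inequality `c·v >= b(z)ᵀλ` (the reverse direction holds automatically),
with all binary products pre-linearized as big-M rows so every right-hand
side stays affine in z.  The adversarial minimization over this system —
whose variables include both the face fluxes and the first-stage duals —
is an LP for fixed z and is dualized a second time; by weak duality the
resulting expression is a lower bound on the worst case for every feasible
point and attains it at the optimum, so the outer MILP simply maximizes
it.  Both dualizations bound their multipliers by ±10³; the second-stage
truncation is harmless at the tested problem sizes but is the first
parameter to raise on larger networks (symptom: MILP optimum below the
LP-verified worst case).

*OptCouple* maximizes the growth-coupling potential
`max c·v (production enabled) − max c·v (v_prod = 0)`.  Both inner maxima
get a primal copy + dual block + zero-gap equality, so each term is pinned
exactly for every z; published OptCouple refinements beyond this gap
objective (e.g. a minimum production rate at the reference state) are not
implemented.

### Assembly, enumeration, verification

Fragments share the binary vector; the objective is the nested module's
outer objective when present, otherwise cost minimization (MCS mode).
Enumeration adds an exclusion cut `Σ_{i∈support}(1 − z_i) >= 1` after each
solution: in MCS mode with positive costs this yields exactly the
inclusion-minimal cut sets in non-decreasing cost order; in nested modes
the outer objective is first fixed at its optimum minus 1e−6 and
alternative optimal supports are enumerated the same way.  `populate`-style
solver solution pools are deliberately not used — iterative cuts behave
identically across backends.

Every solution is re-verified on the original model with plain LPs
(protect feasible, suppress infeasible, nested objective reproduced within
1e−6) and, in MCS mode, a minimality witness (every single-intervention
removal restores the suppressed region).  With `allow_non_minimal` the MCS
objective is dropped (any feasible support within budget) and the
minimality check is skipped and reported as skipped.

## GPR integration

Each gene g gets one supply pseudo-reaction `GX_g: ∅ -> gpool_g` shared by
all reactions citing g; its capacity is the sum of absolute flux bounds of
those reactions, so it never binds unless knocked out.  A reaction with a
rule consumes an enzyme-pool pseudo-metabolite at a rate equal to its flux;
OR nodes supply the pool through parallel routes (any branch suffices), AND
nodes through a single route consuming all child pools (all branches
required), recursively for arbitrary finite trees.  Reversible reactions
are split into two irreversible directions before attachment (enzyme
consumption must be sign-free) and re-fused in reporting.  The contract is
behavioural, verified exhaustively on the fixtures: for every gene subset
the maximal attainable |flux| in the extended network is zero exactly when
the rule evaluates false, and unchanged otherwise.  Rules are first
simplified conservatively (flattening, deduplication, absorption), which
never changes the truth table.

## Network compression

Three stages to a fixpoint, after an initial FVA-based removal of blocked
reactions (|flux| <= 1e−9 in every steady state):

* **lumping** of fully coupled sets: reactions whose rows in a rational
  kernel basis of S are proportional carry proportional flux in *every*
  steady state; each set becomes one column (the ratio-weighted sum) with
  the tightest intersection of scaled member bounds;
* **merging** of parallel columns that are positive rational multiples of
  one another, with summed scaled bounds.

Interventions expand back losslessly: a serial (lumped) chain is cut by
any one member, parallel paths only by cutting all members; costs are
recomputed from the original candidates (min over a lump, sum over a
merge), and nested structures (a lump containing a merge) expand
recursively through the step tree.  In the design pipeline, reactions
referenced by module constraints, objectives, production ids,
addition/regulatory targets or gene pseudo-reactions are kept atomic
(excluded from lumping/merging): this forgoes some compression but makes
constraint translation trivial and keeps intervention identities intact.
Losslessness is asserted end-to-end in the tests by comparing full design
families computed with and without compression.

## Analysis layer

FBA and FVA are plain LPs over the steady-state space; FVA is a pure map
over independent per-reaction LPs whose results are order-independent (a
parallel driver may evaluate them concurrently; none is bundled).  Yield
optimization solves `opt (c·v)/(d·v)` via the Charnes–Cooper substitution
`w = e·v, e >= 0, d·w = 1` with homogenized constraints; the denominator
must be sign-definite over the feasible set (checked by two LPs; a
negative-definite denominator is handled by negating both terms), and an
optimizer with e -> 0 is reported as an unbounded ratio.

2D flux-space projections default to an exact support-point mode: starting
from four axis-aligned extreme points, each candidate hull edge is pushed
along its outward normal by an LP until no edge moves by more than 1e−6 —
so polygon vertices are found exactly regardless of any grid.  A grid
sweep (default 40 points per axis) is available and is the only mode in
3D, where the boundary is returned as sweep-strip facets (no
triangulation).  Yield axes must share one denominator; the projection is
then computed in Charnes–Cooper coordinates where both axes are linear.
Plot rendering (SVG/PNG via matplotlib) is a thin layer over the tested
boundary data.

## Solvers and numerics

Backends: GLPK (optlang/swiglpk; default) and HiGHS (scipy.optimize.milp);
CPLEX and Gurobi are dispatched through optlang when installed.  None of
the bundled backends supports native indicator constraints, so `solve`
rewrites them with per-constraint tight big-M values computed from the
variable bounds (a global override is available); every variable inside an
indicator constraint must therefore be bounded.  Binary integrality is
accepted within 1e−6 and reported rounded; a larger deviation raises a
numerical error, never "infeasible".  Constraint feasibility tolerance is
1e−6 throughout; compression uses 1e−9 (blocked detection and projection
equality), consistent with exact rational arithmetic inside the
compression itself.

## What the toy networks do and do not show

The four bundled networks (a 3-step chain, a branched product-coupler with
GPR rules, two parallel routes, and a chain plus a blocked reaction) are
chosen so that every design mode has a hand-checkable answer and every
brute-force oracle (exhaustive subset enumeration with LP scoring, 2⁴–2⁸
subsets) runs in seconds.  Passing these tests shows the reformulations
(Farkas, single and double strong duality, GPR encoding, compression
expansion) are *correct*; it does not exercise genome-scale numerics
(big-M conditioning on wide bound ranges, dual-bound truncation,
degeneracy), solver time limits, or SBML models with exotic annotations.
The dual bound (±10³), big-M slacks and the 1e−6 tolerances are the knobs
to revisit on large models.
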