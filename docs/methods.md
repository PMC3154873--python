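# Methods

## Model

A polynomial dynamical system (PDS) over the prime field `F_p` is a map
`f = (f_1, …, f_n) : F_p^n → F_p^n` with polynomial coordinates; iterating
`f` gives a deterministic, time-discrete dynamical system on the `p^n`
states.  All model types handled here are special cases after conversion:

* **Boolean networks** (`p = 2`): `NOT a = a+1`, `a AND b = a·b`,
  `a OR b = a+b+a·b`.
* **Multi-valued logical models**: each variable has levels `0..m_i`; the
  model is embedded over a single field `F_p` with `p ≥ max m_i + 1` (see
  *Table extension* below).
* **Probabilistic systems**: a nonempty set of candidate polynomials per
  coordinate with a probability distribution (uniform by default).

Fields are restricted to prime order.  Every conversion target uses `≤ p`
consecutive levels per variable, so non-prime `GF(p^k)` would buy nothing
and would cost an irreducible-polynomial construction.

### Canonical form

All polynomials are kept reduced modulo the field equations
`x_i^p − x_i` (exponent rule `x^e ↦ x^((e−1) mod (p−1) + 1)` for `e ≥ 1`,
coefficients mod `p`).  This canonical representative is the unique
polynomial of per-variable degree `≤ p−1` computing a given function, so:

* equality of term maps ⇔ equality as functions;
* `x_i` occurs in the canonical `f_j` ⇔ `f_j` genuinely depends on `x_i`
  (there is a witness state).  The wiring diagram is read directly off the
  canonical supports; the exhaustive witness search is kept only as a test
  oracle.

Tables are turned into polynomials by finite-field Lagrange interpolation,
applied one axis at a time through the inverse Vandermonde matrix of
`F_p` — `O(s·p^s·p)` for an `s`-input table instead of expanding `p^s`
indicator products.

## Attractors as polynomial systems

Steady states solve `{f_i(x) − x_i = 0}`; states of period dividing `m`
solve `f^m(x) = x`.

### The solver

`solve_system` finds *all* `F_p`-rational roots of a polynomial system by
elimination in the quotient ring `F_p[x]/(x_i^p − x_i)`:

1. **unit propagation** — any equation whose support shrank to a single
   variable is solved by scanning the `p` candidate values; a unique root
   is substituted everywhere, no root kills the branch;
2. **branching** — otherwise pick the equation with the smallest support
   (fail-first), in it the variable occurring in most equations (ties to
   the lowest index), and branch on its possible values;
3. variables whose equations vanish identically are genuinely free and are
   enumerated at emission.

Because branching only ever assigns field values and the canonical form
already encodes the field equations, the ideal is radical and
zero-dimensional by construction: the search is exact and complete — the
same guarantee a lexicographic Gröbner basis provides — while the
propagation step exploits sparseness (biological rules have few inputs).
The engine never enumerates the `p^n` state space; on sparse random
networks with 150 variables and implanted fixed points, steady-state
calls return in well under a second.

Worst-case behaviour is still exponential (solving polynomial systems over
`F_2` contains SAT); dense systems with many attractors will be slow.

### Limit cycles without dense composition

Symbolically composing `f^m` densifies rapidly (the canonical form of a
composed coordinate can involve every reachable variable).  Limit cycles of
length `d ≥ 2` are therefore solved in **time-unrolled** form: variables
`z^0, …, z^{d−1}` for the successive states and sparse equations
`f_i(z^t) − z^{(t+1) mod d}_i = 0`.  Solutions project onto `z^0` exactly
as the fixed points of `f^d`.  `compose` is still provided (and the two
routes are cross-checked in the tests), but the solver path never needs it.

For a bound `m`, the systems for every `d = 1..m` are solved, solutions are
grouped into orbits by applying `f`, and each orbit is reported once with
its **exact period** (printed from its lexicographically smallest state).
Since every period `≤ m` is itself searched, no short cycle is missed.
Composition/unrolling cost grows with `m`; biological limit cycles are
short, so the CLI default caps `m` at 10 (overridable).

### Exhaustive mode

For `p^n ≤ 2^20` (configurable) the full phase space is available as a
directed graph (out-degree 1), with attractors extracted from its
attracting components; above the threshold the operation refuses and
points at the algebraic route.  The enumeration path doubles as the
independent oracle for the algebraic one in the test suite.

## Update schemes

Synchronous updates are the default.  A **sequential schedule** σ (a
permutation of `1..n`) is compiled into the equivalent synchronous system
by substituting already-updated coordinates into later rules, one sweep =
one step.  Fixed points are invariant under the schedule — updating any
variable at a steady state changes nothing — and this is verified
algebraically in the acceptance suite.  Fully asynchronous (random
single-variable) semantics are deliberately out of scope: they yield a
non-deterministic system of a different character.

## Structure analysis

Boolean edge signs come from the cofactors `d0 = f_j|x_i=0`,
`d1 = f_j|x_i=1`: an activating context exists iff `(1+d0)·d1 ≢ 0`, an
inhibiting one iff `d0·(1+d1) ≢ 0` (non-zero is syntactic on canonical
forms).  Both present ⇒ non-unate.

Elementary circuits are enumerated with networkx's simple-cycle algorithm
(Johnson's algorithm), capped at 10^5 circuits with a truncation warning
since counts grow exponentially.  A circuit with all-unate edges carries
the product sign; a circuit through a non-unate edge is reported
*unsigned*.  For the multistationarity condition (≥ 2 fixed points ⇒ a
positive circuit) a non-unate edge counts as either sign — each sign is
witnessed in some context, and the theorem holds only under that reading.
A "functional circuit" is a circuit all of whose edges are functional;
circuit-level functionality beyond that is not defined here.  Multi-valued
circuit analysis is not implemented.

## Table extension for multi-valued models

When variables have different maximum levels, the model is embedded over a
common `F_p` by extending each coordinate's transition table: per input
variable independently, input levels above that variable's maximum repeat
the last defined row (clamping); outputs are then clamped to the target
variable's own maximum (repeat-then-clamp; with single-input tables the
two orders coincide, and the multi-input generalization is this package's
choice).  The extra states are reachable in the embedded PDS;
`out_of_range_states` flags attractor states containing out-of-range
levels as embedding artifacts rather than silently dropping them.
Continuity in the logical-model sense (no variable jumps more than one
level per step) is *not* enforced on conversion; `is_continuous` reports
it separately (exhaustive check, small models only).

## Probabilistic semantics

Updates are synchronous with the rule for each coordinate chosen
independently; a state's successor distribution is the product of
per-coordinate value distributions.  (The alternative "context" semantics —
one global function selection per step — is out of scope.)  Probabilities
are exact `Fraction`s, so out-weights sum to exactly 1.  **True steady
states** (fixed for every rule choice) are computed by solving the union of
equations `f_{i,j} − x_i` over all rules — equivalent to intersecting the
fixed-point sets of all deterministic selections, but solvable at scale.

## Conjunctive / disjunctive fast path

For networks whose rules are pure ANDs (resp. ORs) of their inputs and
whose wiring diagram is strongly connected, dynamics follow from structure:
steady states are exactly all-0 and all-1 (verified by evaluation before
reporting), and every limit-cycle period divides the **loop number** — the
gcd of directed cycle lengths, computed from BFS level differences in
linear time.  Disjunctive networks are handled by the 0↔1 duality
`g_i(x) = f_i(x+1)+1`, not separate code.  The number of cycles per
admissible period has a known closed form in the strongly connected case,
but it is not reproduced here; counting is deferred to the general solver.
Outside the preconditions the routine falls back to the general solver
with a warning.

## Synthetic networks

The generator emulates the sparse biological regime: in-degrees drawn from
a truncated Poisson with mean **1.6848** (the benchmark average of average
in-degrees; the original generator is undescribed, so truncated Poisson is
this package's stand-in), capped at `min(4, n)` by default, with uniformly
random truth tables over the chosen inputs; tables that fail to depend on
every chosen input are redrawn, so all edges are functional by
construction.  Everything is reproducible from the seed.

`implant_fixed_points` plants prescribed steady states by editing each
coordinate's *local* truth table at the implanted rows only.  When two
implanted states collide on a coordinate's input projection but demand
different outputs, the input set is minimally enlarged with a variable
distinguishing them.  (A global-indicator edit would be exact row surgery
on the full 2^n table but has 2^n terms — useless at the n = 150 scale this
operation exists for.)

What a green test on these fixtures does **not** establish: real
regulatory networks have correlated topology (motifs, hubs) and canalyzing
rules that random tables lack; runtime and attractor-count statistics on
generated networks transfer to real models only qualitatively.
Correctness claims, by contrast, are checked against exhaustive oracles
and are topology-independent.

## Numerical and interface choices

* All arithmetic is exact (ints mod p, `Fraction` probabilities); there is
  no floating point anywhere in the core.
* Deterministic output everywhere: solutions sorted lexicographically,
  cycles sorted by (period, smallest state), circuits by (length, node
  sequence).
* States print as digit strings with `x1` leftmost (`"010"` ⇒ x1=0, x2=1,
  x3=0) — stated prominently because reversed conventions are a classic
  interoperability bug.  Digit strings require `p ≤ 7`.
* Model files: `fi = expr` per line; `n` is inferred from the largest
  f/x index and undeclared coordinates default to the identity update.
  External gene names are supported through an alias table mapping names
  to `x_i`; computation always uses indices.
* CLI exit codes: 0 success, 2 parse error, 3 capability refusal
  (simulation requested above the exhaustive threshold), 4 precondition
  violation.

## Known limitations

* Worst-case exponential solving (inherent); practical speed relies on
  sparseness and few attractors, as in biological systems.
* No GINsim XML / SBML-qual / Petri-net import; text formats only.
* No asynchronous-update semantics, no PBN stationary distributions or
  perturbation dynamics, no heuristic/sampling attractor search.
* Circuit analysis (signs, positivity) is Boolean-only.
* Conjunctive fast path requires strong connectivity; no cycle counting.
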