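# polydyn

Attractor and structure analysis of discrete models of biological systems —
Boolean networks, multi-valued logical models and probabilistic Boolean
networks — by computer algebra instead of state-space enumeration.

## The problem and the approach

Qualitative regulatory models update each species `x_i` (a gene, protein,
or signal, with a small number of discrete levels) by a logical rule.  The
dynamics live on a state space of size `p^n`, so exhaustive simulation dies
quickly: a 60-variable Boolean model already has more than 10^18 states.

polydyn expresses every supported model type as a **polynomial dynamical
system** (PDS) `f = (f_1, …, f_n) : F_p^n → F_p^n` over a prime field.
Every function on `F_p^n` is a polynomial, and reducing modulo the field
equations `x_i^p − x_i` gives a *canonical form* in which syntactic equality
is functional equality.  Dynamic questions then become systems of polynomial
equations:

* **steady states** are the solutions of `f_i(x) − x_i = 0, i = 1…n`;
* states on a **limit cycle of length m** solve `f^m(x) = x`.

These systems are solved exactly over the finite field by sparse
elimination (unit propagation plus branching in the quotient ring — the
role a lexicographic Gröbner basis plays in a general-purpose computer
algebra system), which exploits the sparseness of biological networks:
each rule depends on only a handful of regulators.  Steady states of
150-variable sparse networks resolve in well under a second, far beyond
anything enumerable.

Also included:

* **wiring diagrams** whose edges are all *functional* (an edge `i → j`
  exists iff some state witnesses that toggling `x_i` changes the next
  value of `x_j` — equivalently, `x_i` occurs in the canonical `f_j`),
  with activation/inhibition/non-unate signs for Boolean models;
* **functional circuits** (elementary cycles) with signs; positive
  circuits are a necessary condition for multistationarity;
* **multi-valued logical models** embedded over a common field by table
  extension, with out-of-range artifact states flagged;
* **sequential update schedules** (steady states are schedule-invariant);
* **probabilistic systems**: several rules per variable with exact rational
  probabilities, all-transitions graphs, and "true" steady states fixed
  under every rule choice;
* a **conjunctive/disjunctive fast path**: for strongly connected all-AND
  (all-OR) networks the steady states and the admissible cycle periods
  (divisors of the loop number) follow from the wiring diagram alone;
* a seeded **generator** of sparse random networks with implantable fixed
  points, used by the test suite as a ground-truth factory.

## Worked example

A two-gene toggle switch (mutual repression):

```sh
$ cat toggle.txt
f1 = NOT x2
f2 = NOT x1
$ polydyn analyze toggle.txt --format bool --cycle-length 2
steady states (2):
  01
  10
limit cycle, period 2: 00 -> 11
```

States are digit strings with `x1` leftmost.  The two steady states `01`
and `10` are the expected bistable expression patterns (exactly one gene
on); the synchronous update also admits the period-2 oscillation
`00 ↔ 11`.  The JSON report that follows shows the wiring diagram — two
inhibiting edges (`sign: -1`), forming one functional circuit of sign
`(−1)·(−1) = +1`: the positive feedback loop required for the observed
bistability.

The same analysis runs on polynomial files (`--format poly --states 3` for
three-level logic), logical transition tables (`--format table`), and
probabilistic rule files (`--format prob`, `fi = expr # prob` lines).
`polydyn generate --n 50 --seed 1` emits a random sparse benchmark network;
`--mode simulation` builds the full phase space for small models and
refuses politely for large ones.

Library use mirrors the CLI:

```python
from polydyn import boolean_rules_to_pds, steady_states, limit_cycles
f = boolean_rules_to_pds(["NOT x2", "NOT x1"])
steady_states(f)          # [(0, 1), (1, 0)]
limit_cycles(f, 2).cycles  # ((2, ((0, 0), (1, 1))),)
```

## Acceptance script

`scripts/acceptance.py` regenerates the package's reference quantities from
scratch: it builds a sparse 60-variable Boolean benchmark network with
implanted fixed points, solves it algebraically end to end (verifying
soundness and completeness of the returned steady states), and reports the
state-space sizes of the benchmark model classes as JSON.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the underlying model, algorithmic choices and
their limitations.
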