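# Methods

## Model and assumptions

A Boolean network `G(V, A)` has one binary variable per gene, updated
synchronously: `v_i(t+1) = f_i(v_{i1}(t), …, v_{ik}(t))`. The update
class is deliberately restricted to signed conjunctions and
disjunctions: every `f_i` is the AND or the OR of its regulators'
literals, each literal either the regulator's state or its negation,
or a constant for input-free genes. This coarse rule class trades
expressiveness (no XOR-like logic, no mixed gates) for a searchable
space — exactly `2^{|S|+1}` rules over a regulator set `S` — and is the
class the inference enumerates exhaustively per candidate set.

Time is 1-based. All prediction quality is measured on transitions,
i.e. over `t = 2..T`; the initial row is input only.

## Inference procedure

Each gene is solved independently on its one-step-lagged problem:
target = the gene's states at `t = 2..T`; candidates = all genes'
states at `t = 1..T−1`, the target's own lagged series included
(self-regulation is permitted — real cell-cycle wirings contain
self-loops, and the N² evaluation pair space includes self-pairs).

**Zero-entropy shortcut.** If the lagged target series is constant its
plug-in entropy is zero and no regulator carries information about it;
the gene receives a constant rule, no regulators, consistency 1. The
lagged series (not the full column) is used because it is exactly the
series a rule must predict.

**MIFS.** Greedy selection under the relevance-minus-redundancy score
`I(v_O; w) − Σ_{s∈S} I(w; s)`, with the redundancy sum unweighted (the
original selection heuristic's β fixed at 1). Entropies and mutual
information are plug-in estimates on binary series, log base 2, `0·log
0 := 0`, no pseudocounts; the base only scales scores and never changes
a ranking. Argmax ties break to the lowest candidate index.

**Rule search.** For a candidate set `S`, all `2^{|S|}` sign patterns ×
{AND, OR} are evaluated vectorised; the first rule (gates AND-then-OR,
sign patterns in ascending binary order, bit j flipping regulator j in
`S`'s stored order) attaining the maximal gene-wise consistency wins.

**SWAP.** Both `S` and its complement are kept ordered by descending
mutual information with the target. Each sweep examines every pair
`(s ∈ S, w ∉ S)` and applies the single swap yielding the largest
*strict* increase in best achievable consistency (ties to the earliest
scanned pair); sweeps repeat until consistency reaches 1 or no swap
improves. Best-improvement rather than first-improvement is a
deliberate choice: with first-improvement-and-restart, a mediocre early
swap can carry the set away from a perfect set one swap away, and
seeded sweeps showed roughly one such miss per hundred problems on
random 6–8-gene inputs; with best-improvement, 500/500 seeded problems
whose exhaustive size-≤2 optimum is perfect were also solved perfectly
by the greedy search. Termination is guaranteed (consistency strictly
increases on a finite set); a 10·N accepted-swap cap stands as a safety
valve that never binds.

**Outer loop.** `k` grows from 1 to `K` (default 10, the cap on
inferred in-degree), each `k` running MIFS then SWAP; the loop stops at
the first perfect rule. If none is found the best consistency over all
`k` tried is returned, ties to the smallest `k` (parsimony — the
stopping rule itself says nothing about the fallback).

## Evaluation metrics

Structural: candidate space = all `N²` ordered (regulator, target)
pairs including self-pairs; an inferred edge matches on the pair alone,
ignoring sign, by default (a strict signed mode exists behind a flag).
The N² convention is forced by arithmetic: published 10-gene case
counts of 7 TP / 4 FP / 4 FN with structural accuracy 0.9200 solve to
TN = 85 only on a 100-pair space, and likewise 14/3/9 with 0.8800 give
TN = 74. Undefined precision/recall (zero denominator) returns 0 with a
warning rather than an error.

Dynamics: per-gene consistency `E(v, v′)` over `t = 2..T`, averaged
unweighted over genes. Predictions are **teacher-forced** — each step
is predicted from the *observed* previous state — because that is the
quantity the SWAP objective optimises during training and the only
reading consistent with near-1 benchmark accuracies; free-running
prediction (rolling the model forward from the initial state) is
available as an option everywhere but is not the default.

## Synthetic benchmark generator

Emulates the standard protocol: directed scale-free networks with
exactly `|A| = 2·|V|` edges, random rules, trajectories of length
`T = |V| + 10` from i.i.d. Bernoulli(0.5) initial states.

Structure: preferential attachment (3-node star seed, each new node
attaching m = 2 edges to distinct existing nodes with
degree-proportional probability), each growth edge oriented old→new
then flipped with probability 1/2. Plain growth yields `2|V| − 4`
edges, so four further directed edges with degree-proportional
endpoints are added to land exactly on `2|V|`; the whole variant is
isolated behind `generate_ba_network` so it can be swapped. Across
replicates the in-degree distribution is right-skewed with mean exactly
2 (tested against a degree-matched Erdős–Rényi draw).

Rules: gate uniform on {AND, OR}; each regulator sign uniform on
{+1, −1}. All-positive rules are available (`signs="positive"`) but
are not the default: without negative literals random networks collapse
to a fixed point almost immediately and leave no dynamical signal.
Input-free nodes hold a fixed random bit; the bit is drawn from the
rule stream and the trajectory's initial state is set to it, so the
network object is independent of the trajectory seed while the
trajectory remains consistent with the generating network.

Seeding: structure, rules and initial states use independent
sub-streams spawned from one seed; every public entry point is
deterministic given its seed.

What the generator does *not* emulate: measurement noise, unequal
sampling intervals, continuous kinetics binarized after the fact, and
asynchronous or stochastic update — so perfect benchmark scores show
the search recovers networks of its own model class from clean
synchronous data, not that it is robust to real microarray noise. The
two built-in case-study datasets partially probe the mismatch: one adds
2% observation flips to a cascade's trajectory, the other is generated
by a *threshold* model outside the AND/OR class (both are synthetic
stand-ins constructed here, clearly labelled as such).

## Benchmark problem sizes

The bundled sweeps use `|V| ∈ {10–40}` with 6–10 replicates per size
(20–40 networks per quantity) — sizes at which per-class means are
already stable, chosen so the whole suite and the acceptance script
run in seconds. The per-gene records table scales to larger sweeps
unchanged.

## Numerical and degenerate-input choices

- Mutual information clamped at 0 against floating-point residue;
  comparisons of consistencies are exact (multiples of 1/(T−1)).
- Binarization: 1-D two-means with centroids initialised at the gene's
  min and max, Lloyd iterations, tol 1e-9, cap 100 — deterministic and
  optimal-equivalent for one-dimensional two-cluster problems at this
  scale. Constant genes (and exact mean ties, which only constants
  produce) map to all-off.
- All tie-breaks (MIFS argmax, rule enumeration, swap sweeps, best-k)
  are first-in-order/lowest-index, making every run reproducible
  bit-for-bit.

## Known limitations

- The rule class excludes mixed and parity logic; genes governed by
  such rules are approximated by the best signed AND/OR fit.
- Greedy MIFS+SWAP is a local search; the exhaustive searcher in
  `mibni.oracle` bounds it from above on small problems but is
  combinatorial and guarded against misuse.
- Structure is identifiable only up to dynamical equivalence on the
  observed trajectory; short or attractor-dominated time courses leave
  many regulator sets indistinguishable, and dynamics accuracy can be
  perfect while structural recall is low.
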