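# Methods

## Model

Events (copy-number aberrations or other binary somatic events) are the
vertices of a directed acyclic hypergraph: each event *v* carries exactly
one hyperedge whose child is *v* and whose parent set pa(v) has at most
k − 1 members. A joint distribution over the event indicators factorizes as
∏_v P(X_v | X_pa(v)) with one binary CPD per event. The hypergraph is
acyclic in the usual sense — some linear order places every parent before
its child — which is equivalent to acyclicity of the underlying simple
digraph containing one arc per (parent, child) pair; we check it there.

Progression constraints restrict the CPDs:

* **monotone (MPN):** P(X_v = 1 | u) ≤ ε for every parent configuration u
  except all-ones. With ε = 0 this is the conjunctive Bayesian network.
* **semi-monotone (SMPN):** the bound applies only to u = all-zeros.
* **general:** no constraint.

Events that select no real parents are attached to artificial *root
parents*. Root parents carry no event semantics: they are never children,
never appear in the underlying simple digraph, and a root-attached CPD (a
bare marginal) is exempt from ε-capping in both flavors — for an empty
parent set the sole CPD row is vacuously both "all parents on" and "no
parent on", and capping it would penalize every root event of the network.

## Scoring

Both supported scores decompose over hyperedges, so each candidate edge can
be weighted once, independently of the rest of the structure. With N(·) the
number of dataset rows matching a partial assignment, the ML estimate of a
conditional is θ̂(u) = N(child = 1, pa = u) / N(pa = u). Flavor constraints
are imposed by the constrained-ML projection θ̂ ↦ min(θ̂, ε) on the capped
rows (values already below ε are left alone — overwriting them with ε would
lower the likelihood without being required by the constraint). The edge
weight is

    w(e) = Σ_{u, x} N(c = x, pa(e) = u) · log θ̂_capped(x | u),

with the convention 0 · log 0 = 0; parent configurations never observed
contribute nothing and carry a flagged placeholder probability of 0. The
BIC weight subtracts (log m / 2) · 2^|pa(e)| (Schwarz penalty, natural log,
one independent parameter per CPD row of a binary child). Weights are
always ≤ 0, are finite for ε > 0, and ignore root parents entirely, so the
empty parent set represents every root-padded variant of an edge.

## Search

The selector hypergraph enumerates, for each child, all C(n−1, j) parent
sets of size j = 0..k−1 (the empty set standing for the root-parent edge).
The maximum-weight acyclic selection of one candidate per child is found by
a MILP with one binary variable x_e per candidate and one continuous order
variable o_v ∈ [0, n−1] per event:

* Σ_{e: child(e)=v} x_e = 1 for every v (exactly one parent set each);
* o_child(e) − o_u ≥ 1 − n(1 − x_e) for every candidate e and parent
  u ∈ pa(e).

Selecting an edge forces its child strictly above each parent in the order,
so no cycle can be selected; with x_e = 0 the big-M constant n makes the
row vacuous. Order variables need not be integral for this argument, and
leaving them continuous keeps the relaxation cheap. Constraints are emitted
per (edge, parent) pair rather than aggregated, which gives a tighter LP
relaxation. The solver is HiGHS through `scipy.optimize.milp`, behind a
thin backend function accepting a time limit and a relative MIP gap; when
the limit halts the search the best incumbent is returned with its gap
(status `incumbent`), and a run with no incumbent reports
`timeout-no-solution` rather than an empty network. HiGHS is deterministic
for a fixed program, so a fixed input reproduces the objective exactly; the
`seed` option is recorded for provenance only.

The always-feasible fallback (every child takes the root-parent candidate)
means valid inputs can never be infeasible.

### Tie-breaking

Exact score ties between structures are not a corner case here. Whenever an
edge's reversed orientation also keeps its escape probability under ε, the
capping is inactive both ways and the plug-in likelihood factorizes
identically in either direction — the two structures have *algebraically*
equal scores on every dataset. Left to the solver, such ties are resolved
by floating-point noise, which flips edge orientations between otherwise
comparable runs. The search objective therefore subtracts a tiny secondary
term, 1e-6 per unit of capped escape mass (the sum of the capped CPD rows'
retained probabilities), preferring among tied structures the one that
would stay optimal as ε shrinks toward the conjunctive limit. The constant
sits far above float noise in the weight sums (~1e-10 relative) and far
below any statistically meaningful score difference. Reported objectives
are always recomputed from the pure weights of the selected candidates, so
the tie-break never leaks into a score. The exhaustive oracle applies the
same rule.

### Exhaustive oracle

`brute_force_learn` maximizes over vertex permutations: for each of the n!
orders it independently picks, per child, the best candidate whose parents
all precede the child, and keeps the best order. Every DAG is consistent
with some order, so this is the exact optimum. It shares no machinery with
the MILP route and is guarded to n ≤ 8.

## Synthetic data generator

`random_hyperdag` samples a uniform permutation, then lets each vertex draw
a parent-set size uniformly from {0, …, min(k−1, #predecessors)} and that
many distinct predecessors uniformly — acyclic and k-bounded by
construction. CPDs separate signal from noise: enabled rows (all parents on
for MPN, ≥1 parent on for SMPN, and all root marginals) draw
P(child = 1) ~ U(0.5, 0.95); suppressed rows draw U(0, ε); the general
flavor draws U(0.05, 0.95) everywhere. Defaults: ε = 0.2, the benchmark
grid k ∈ {2, 3}, n ∈ {10, 20, 30}, m ∈ {500, 2000, 10000}, 50 replicates.
Forward sampling proceeds in topological order, vectorized across rows.

Within a benchmark replicate the datasets at increasing m are nested — each
larger sample extends the smaller one — so recovery comparisons across m
are paired rather than confounded by independent redraws. Replicate streams
derive from the base seed through `numpy.random.SeedSequence` spawn keys
(k, n, flavor, replicate), making every cell independently reproducible.

What the generator does *not* emulate: observation noise (no false
positive/negative aberration calls, unlike latent-variable schemes such as
H-CBN), missing data, within-tumor heterogeneity, or dependence of ε on the
event. Passing recovery benchmarks therefore demonstrates correctness of
the score-and-search machinery under the stated model, not robustness to
assay noise.

### Identifiability ceiling

Even with infinite data some true edges are unrecoverable in principle:
when the reversed orientation's escape probability also lands under ε, the
two orientations are score-equivalent (see Tie-breaking). At n = 10, k = 2
this puts mean recovered-edge percentages near, but not at, 100 — observed
means in the acceptance runs are ~96–100% depending on seed. The
conjunctive-limit tie-break resolves these ties toward the orientation with
the smaller escape mass, which is usually (not always) the generating one.

## Evaluation

Metrics compare underlying simple digraphs M (true) and L (learned):
recovered % = 100·|M∩L|/|M|, relative symmetric difference
F = |MΔL|/(|M|+|L|), FDR = |L∖M|/|L|, FNR = |M∖L|/|M|. Undefined cases
(empty truth; both sets empty for F) raise rather than return a sentinel.

Against a reference partial order, a learned edge u→v is *bad* iff v
strictly precedes u in the order's transitive closure; edges between
incomparable events are not bad. The denominator of the bad-edge percentage
counts the simple edges plus one per root-attached hyperedge (root edges
can never be bad; they only dilute). `calibrate_epsilon` learns one network
per grid value and returns the ε minimizing the bad-edge percentage, ties
going to the smallest ε (the most conservative monotonicity).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| k | 3 | max vertices per hyperedge (≤ k−1 parents per event) |
| flavor | monotone | CPD constraint family |
| ε | 0.2 | escape-probability bound of MPN/SMPN rows |
| criterion | bic | structure score (`bic` or `loglik`) |
| time_limit_s / mip_gap | none | solver limits; incumbent returned on limit |

ε = 0.2 is the package default for both learning and generation; it is the
regime in which the monotonicity constraint is active but not degenerate,
and it can be recalibrated per dataset against a reference order with
`calibrate_epsilon`. Raising ε toward 1 weakens the constraint until MPN
and SMPN weights coincide exactly with the general-BN weights.

The raw likelihood score grows with every added parent, so with k = n it
tends toward fully connected structures on dependent data; BIC is the
default for that reason.

## Problem sizes and numerics

The test suite and the acceptance script run the oracle-equivalence check
at n ∈ {3,4,5} (where n! enumeration is instant), the recovery benchmark at
n = 10, k = 2 with 10–20 replicates, and calibration over a 5-point ε grid
— sizes chosen so the whole pipeline re-runs from scratch in seconds to a
few minutes on one CPU while still exercising every code path at the
sample sizes of the benchmark grid. Weight computation is vectorized
(bincount over integer-coded parent configurations), so m = 10000 rows cost
microseconds per candidate. Degenerate inputs are rejected loudly:
non-binary cells (with row/column named), ε ∉ (0, 1], k outside [2, n],
empty truth sets in metrics.

## Known limitations

* Scores assume fully observed binary data; no missing-data EM, no priors.
* The MILP encoding enumerates all C(n−1, k−1) parent sets per child;
  practical up to roughly n = 30, k = 3 (≈13k binaries), beyond which
  candidate pruning (`prune=True`) and solver limits become relevant.
* Orientation of score-tied edges is a modeling convention (conjunctive
  limit), not evidence.
* ε is global; real progressions may warrant per-event escape rates.
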