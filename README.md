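# diprog

Exact score-based learning of **k-bounded Bayesian networks** and of
**cancer progression networks** from cross-sectional binary aberration data,
by reduction to mixed-integer linear programming (MILP).

## The problem

Tumor datasets are cross-sectional: each patient contributes one binary
vector recording which genetic events (e.g. chromosome-arm gains and losses
called from CGH) are present in the tumor. The temporal order in which the
events accumulated is not observed, yet progression — which aberrations
enable which — is exactly what one wants to infer. This package learns that
order as a directed acyclic hypergraph: each event *v* has one hyperedge
giving its parent set pa(v) (at most k−1 parents), and a conditional
probability table P(X_v = 1 | X_pa(v)).

Two constrained model families tailor the Bayesian network to progression:

* **Monotone progression network (MPN):** P(X_v = 1 | u) ≤ ε for every
  parent configuration u except all-ones — a child event is essentially
  blocked until *all* of its parents have occurred (the ε = 0 case is the
  conjunctive Bayesian network).
* **Semi-monotone (SMPN):** the ε bound applies only to the all-zeros
  configuration — *at least one* parent must have occurred.
* **General:** an unconstrained k-bounded Bayesian network.

## The method

Both the log-likelihood and the BIC score decompose over hyperedges. For an
edge e with child c and parents pa(e), with N(·) the matching row counts and
θ̂ the (ε-capped) maximum-likelihood conditionals,

    w(e)     = Σ_{u, x} N(c = x, pa(e) = u) · log θ̂(x | u)
    w_BIC(e) = w(e) − (log m / 2) · 2^|pa(e)|

Events that select no real parents attach to artificial *root parents* and
are scored by their marginal. The learner enumerates every candidate
(child, parent set) with |parent set| < k into a weighted *selector
hypergraph* and solves

    maximize   Σ_e w(e) x_e
    s.t.       Σ_{e: child(e)=v} x_e = 1          for every event v
               o_child(e) − o_u ≥ 1 − n(1 − x_e)  for every e, u ∈ pa(e)

with binary selection variables x_e and continuous order variables
o_v ∈ [0, n−1]; the order constraints make any selected structure acyclic.
The MILP is solved exactly by HiGHS (via `scipy.optimize.milp`). An
exhaustive permutation oracle (`diprog.milp.brute_force_learn`) provides an
independent check of the reduction for small n.

## Worked example

```python
from diprog import DiProgLearner, simulate
from diprog.hypercore import underlying_graph
from diprog.evaluate import recovered_edge_pct, relative_symmetric_difference

truth = simulate.random_network(n=10, k=2, flavor="monotone", epsilon=0.2, seed=7)
X = simulate.sample_data(truth, m=2000, seed=8)

est = DiProgLearner(k=2, flavor="monotone", epsilon=0.2, criterion="bic").fit(X)
print("status:   ", est.status_)
print("objective:", round(est.objective_, 2))

M = underlying_graph(truth.hyperdag)
L = underlying_graph(est.network_.hyperdag)
print("recovered %:", recovered_edge_pct(M, L))
print("F:          ", relative_symmetric_difference(M, L))
```

prints

```
status:    optimal
objective: -9642.8
recovered %: 100.0
F:           0.0
```

The objective is the BIC score of the selected structure (sum of per-edge
weights, natural log). `recovered %` is the percentage of true directed
(parent, child) edges present in the learned graph, and `F` is the relative
symmetric difference |M Δ L| / (|M| + |L|): 0 means the edge sets are
identical, 1 means they are disjoint.

The same pipeline is available from the shell:

```bash
diprog simulate -o sim --n 10 --k 2 --flavor monotone --m 2000 --seed 7
diprog learn sim/data.tsv -o fit --k 2 --flavor monotone
diprog evaluate --truth sim/true_edges.tsv --learned fit/edges.tsv
diprog benchmark -o bench --n 10 --k 2 --replicates 5
```

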