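"""MILP reduction for maximum-weight k-bounded acyclic subhypergraph.

The program has one binary variable x_e per candidate hyperedge and one
continuous order variable o_v in [0, n-1] per data variable, with

    maximize   sum_e w(e) x_e
    subject to (1) for every child v:  sum_{e: child(e)=v} x_e = 1
               (2) for every candidate e and parent u of e:
                   o_{child(e)} - o_u >= 1 - n (1 - x_e)

Selecting an edge forces its child strictly above each parent in the order,
so no directed cycle can be selected; with x_e = 0 the big-M constant n
makes the constraint vacuous.  Order variables need not be integral for the
argument to hold, which keeps the relaxation cheap.

The solver backend is SciPy's HiGHS interface (``scipy.optimize.milp``);
:func:`brute_force_learn` provides an exhaustive, structurally independent
oracle for small n by maximizing over vertex permutations.

Exact score ties are common in progression networks: when the reversed
orientation of an edge also keeps its escape probability under epsilon, the
plug-in likelihood factorizes identically both ways.  To break such ties
deterministically and in the spirit of the model, the search objective
subtracts a tiny penalty (``TIE_BREAK_DELTA`` per unit) proportional to each
candidate's capped escape mass, preferring among tied structures the one
that would remain optimal as epsilon shrinks toward the conjunctive limit.
Reported objectives are always recomputed from the pure weights of the
selected structure, so the tie-break never perturbs a reported score.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint
from scipy.optimize import milp as _scipy_milp

from .hypercore import HyperDAG, HyperEdge, is_acyclic
from .scoring import DataMatrix, ProgressionNetwork, fit_cpds
from .selector import Candidate, SelectorGraph, build_selector

__all__ = [
    "MilpProgram",
    "LearnResult",
    "build_milp",
    "solve",
    "learn",
    "brute_force_learn",
]


@dataclass(frozen=True)
class MilpProgram:
    """A built program: objective, constraints and variable layout.

    Variables are ordered candidates first (x_0..x_{E-1}) then order
    variables (o_0..o_{n-1}).
    """

    selector: SelectorGraph
    objective: np.ndarray          # maximization coefficients, length E + n
    integrality: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    A: sparse.csr_matrix
    con_lower: np.ndarray
    con_upper: np.ndarray

    @property
    def n_edge_vars(self) -> int:
        return len(self.selector.candidates)

    @property
    def n_order_vars(self) -> int:
        return self.selector.n


@dataclass(frozen=True)
class LearnResult:
    """Outcome of one structure-learning run."""

    network: ProgressionNetwork | None
    objective: float
    status: str                    # optimal | incumbent | infeasible | timeout-no-solution
    gap: float
    solve_seconds: float

    def __post_init__(self):
        if self.status == "optimal" and self.gap != 0.0:
            object.__setattr__(self, "gap", 0.0)


#: magnitude of the tie-breaking penalty per unit of capped escape mass;
#: far above float noise in weight sums (~1e-10) and far below any
#: statistically meaningful score difference.
TIE_BREAK_DELTA = 1e-6


def build_milp(S: SelectorGraph) -> MilpProgram:
    """Translate a selector graph into the ordering-based MILP."""
    E, n = len(S.candidates), S.n
    w = np.array(
        [c.weight(S.score) - TIE_BREAK_DELTA * c.cap_mass
         for c in S.candidates],
        dtype=float,
    )
    objective = np.concatenate([w, np.zeros(n)])
    integrality = np.concatenate([np.ones(E), np.zeros(n)])
    lower = np.zeros(E + n)
    upper = np.concatenate([np.ones(E), np.full(n, n - 1.0)])

    rows, cols, vals = [], [], []
    con_lower, con_upper = [], []
    # (1) exactly one candidate per child (row index = child)
    counts = np.zeros(n, dtype=int)
    for i, c in enumerate(S.candidates):
        rows.append(c.child)
        cols.append(i)
        vals.append(1.0)
        counts[c.child] += 1
    if (counts == 0).any():
        raise ValueError(
            f"no candidates for child {int(np.argmin(counts))}"
        )
    con_lower += [1.0] * n
    con_upper += [1.0] * n
    r = n
    # (2) order constraints, one per (candidate, parent) pair:
    #     o_c - o_u - n x_e >= 1 - n
    for i, c in enumerate(S.candidates):
        for u in c.parents:
            rows += [r, r, r]
            cols += [E + c.child, E + u, i]
            vals += [1.0, -1.0, -float(n)]
            con_lower.append(1.0 - n)
            con_upper.append(np.inf)
            r += 1
    A = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(r, E + n), dtype=float
    )
    return MilpProgram(
        S, objective, integrality, lower, upper, A,
        np.array(con_lower), np.array(con_upper),
    )


def _decode(S: SelectorGraph, x: np.ndarray) -> tuple[HyperDAG, float]:
    sel = [c for c, xi in zip(S.candidates, x) if xi > 0.5]
    obj = sum(c.weight(S.score) for c in sel)
    H = HyperDAG(S.n, [HyperEdge(c.child, c.parents) for c in sel],
                 S.event_names)
    return H, obj


def solve(
    prog: MilpProgram,
    D: DataMatrix | None = None,
    time_limit_s: float | None = None,
    mip_gap: float | None = None,
    seed: int = 0,
) -> LearnResult:
    """Solve the program with HiGHS and decode the selected network.

    HiGHS is deterministic for a fixed program, so ``seed`` is accepted for
    interface stability but does not perturb the search.  When the time
    limit halts the search with a feasible incumbent, that incumbent is
    returned with its relative gap; with no incumbent the status is
    ``timeout-no-solution``.  CPDs are fitted to ``D`` when provided.
    """
    if time_limit_s is not None and time_limit_s <= 0:
        raise ValueError("time limit must be positive")
    if mip_gap is not None and mip_gap < 0:
        raise ValueError("mip gap must be non-negative")
    options: dict = {}
    if time_limit_s is not None:
        options["time_limit"] = float(time_limit_s)
    if mip_gap is not None:
        options["mip_rel_gap"] = float(mip_gap)
    t0 = time.perf_counter()
    res = _scipy_milp(
        c=-prog.objective,
        integrality=prog.integrality,
        bounds=Bounds(prog.lower, prog.upper),
        constraints=LinearConstraint(prog.A, prog.con_lower, prog.con_upper),
        options=options,
    )
    elapsed = time.perf_counter() - t0
    S = prog.selector
    if res.x is None:
        status = "infeasible" if res.status == 2 else "timeout-no-solution"
        return LearnResult(None, float("nan"), status, float("inf"), elapsed)
    H, obj = _decode(S, res.x[: len(S.candidates)])
    if not is_acyclic(H):
        raise RuntimeError("solver returned a cyclic selection")  # pragma: no cover
    gap = float(getattr(res, "mip_gap", 0.0) or 0.0)
    status = "optimal" if res.status == 0 else "incumbent"
    if status == "optimal":
        gap = 0.0
    net = fit_cpds(D, H, S.flavor, S.epsilon) if D is not None else None
    return LearnResult(net, obj, status, gap, elapsed)


def learn(
    D: DataMatrix,
    k: int = 3,
    flavor: str = "monotone",
    epsilon: float = 0.2,
    score: str = "bic",
    time_limit_s: float | None = None,
    mip_gap: float | None = None,
    seed: int = 0,
    prune: bool = False,
) -> LearnResult:
    """Full pipeline: selector -> MILP -> solve -> constrained-ML CPDs."""
    from .selector import prune_dominated

    S = build_selector(D, k, flavor, epsilon, score)
    if prune:
        S = prune_dominated(S)
    prog = build_milp(S)
    return solve(prog, D, time_limit_s, mip_gap, seed)


def brute_force_learn(
    D: DataMatrix,
    k: int = 3,
    flavor: str = "monotone",
    epsilon: float = 0.2,
    score: str = "bic",
    max_n: int = 8,
) -> LearnResult:
    """Exhaustive exact optimum for small n (test oracle).

    For each of the n! vertex permutations, the best DAG consistent with
    that order picks, independently per child, the highest-weight candidate
    whose parents all precede the child; every DAG is consistent with some
    permutation, so the max over permutations is the global optimum.  This
    never touches the MILP machinery.
    """
    if D.n > max_n:
        raise ValueError(f"brute force limited to n <= {max_n}, got n={D.n}")
    S = build_selector(D, k, flavor, epsilon, score)
    by_child = S.by_child()
    t0 = time.perf_counter()
    best_obj = -np.inf
    best_sel: list[Candidate] | None = None
    for perm in permutations(range(S.n)):
        pos = {v: i for i, v in enumerate(perm)}
        total = 0.0
        sel: list[Candidate] = []
        ok = True
        for v in range(S.n):
            best_c, best_w = None, -np.inf
            for c in by_child[v]:
                if all(pos[u] < pos[v] for u in c.parents):
                    w = c.weight(score) - TIE_BREAK_DELTA * c.cap_mass
                    if w > best_w:
                        best_c, best_w = c, w
            if best_c is None:  # cannot happen: empty set always present
                ok = False
                break
            total += best_w
            sel.append(best_c)
        if ok and total > best_obj:
            best_obj = total
            best_sel = sel
    H = HyperDAG(
        S.n, [HyperEdge(c.child, c.parents) for c in best_sel], S.event_names
    )
    net = fit_cpds(D, H, flavor, epsilon)
    pure = sum(c.weight(score) for c in best_sel)  # without tie-break term
    return LearnResult(net, float(pure), "optimal", 0.0,
                       time.perf_counter() - t0)
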