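"""The weighted k-bounded selector hypergraph.

For each data variable v the selector enumerates every candidate hyperedge
(v, P) with P a subset of the other variables of size 0..k-1, and scores it
with the decomposable weight from :mod:`diprog.scoring`.  The empty parent
set stands for the edge whose parents are all root parents; since weights
ignore root parents, mixed root/non-root candidates are redundant and never
materialized.  Structure search then reduces to picking exactly one
candidate per child such that the union is acyclic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

from .hypercore import HyperEdge
from .scoring import DataMatrix, _check_flavor, edge_weight

__all__ = ["Candidate", "SelectorGraph", "build_selector", "prune_dominated"]


@dataclass(frozen=True)
class Candidate:
    """One candidate hyperedge with both score variants.

    ``cap_mass`` is the escape probability retained on epsilon-capped CPD
    rows, used only to break exact score ties toward the structure that
    stays optimal as epsilon shrinks (the conjunctive limit).
    """

    child: int
    parents: tuple[int, ...]
    loglik: float
    bic: float
    cap_mass: float = 0.0

    def weight(self, score: str) -> float:
        if score == "loglik":
            return self.loglik
        if score == "bic":
            return self.bic
        raise ValueError(f"score must be 'loglik' or 'bic', got {score!r}")

    @property
    def edge(self) -> HyperEdge:
        return HyperEdge(self.child, self.parents)


@dataclass(frozen=True)
class SelectorGraph:
    """All scored candidate hyperedges for one dataset and one k."""

    n: int
    k: int
    flavor: str
    epsilon: float
    score: str
    candidates: tuple[Candidate, ...]
    event_names: tuple[str, ...]

    def by_child(self) -> list[list[Candidate]]:
        out: list[list[Candidate]] = [[] for _ in range(self.n)]
        for c in self.candidates:
            out[c.child].append(c)
        return out

    def expected_count(self) -> int:
        """n * sum_{j<k} C(n-1, j): the unpruned candidate count."""
        return self.n * sum(comb(self.n - 1, j) for j in range(self.k))


def build_selector(
    D: DataMatrix,
    k: int,
    flavor: str = "monotone",
    epsilon: float = 0.2,
    score: str = "bic",
) -> SelectorGraph:
    """Enumerate and weight every k-bounded candidate hyperedge.

    Candidates are ordered by child, then parent-set size, then
    lexicographically, giving a reproducible MILP variable order.
    """
    _check_flavor(flavor)
    if score not in ("loglik", "bic"):
        raise ValueError(f"score must be 'loglik' or 'bic', got {score!r}")
    n = D.n
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    cands: list[Candidate] = []
    for child in range(n):
        others = [v for v in range(n) if v != child]
        for size in range(k):
            for parents in combinations(others, size):
                ew = edge_weight(D, HyperEdge(child, parents), flavor, epsilon)
                cands.append(
                    Candidate(child, parents, ew.loglik, ew.bic, ew.cap_mass)
                )
    return SelectorGraph(
        n, k, flavor, epsilon, score, tuple(cands), D.event_names
    )


def prune_dominated(S: SelectorGraph) -> SelectorGraph:
    """Drop candidates dominated by a proper subset of their parents.

    A candidate (v, P) is removed when some P' strictly contained in P has
    weight (under S.score) at least as large: replacing P by P' keeps any
    DAG acyclic, so (v, P) can never be part of a strictly better solution.
    Empty-parent candidates are never removed, preserving feasibility.
    """
    kept: list[Candidate] = []
    for child_cands in S.by_child():
        wmap = {c.parents: c.weight(S.score) for c in child_cands}
        for c in child_cands:
            if not c.parents:
                kept.append(c)
                continue
            dominated = any(
                sub in wmap and wmap[sub] >= c.weight(S.score)
                for size in range(len(c.parents))
                for sub in combinations(c.parents, size)
            )
            if not dominated:
                kept.append(c)
    return SelectorGraph(
        S.n, S.k, S.flavor, S.epsilon, S.score, tuple(kept), S.event_names
    )


def write_selector_tsv(S: SelectorGraph, path) -> None:
    """Debug dump: child, comma-joined parents, loglik and BIC weights."""
    with open(path, "w") as fh:
        fh.write("child\tparents\tloglik\tbic\n")
        for c in S.candidates:
            pa = ",".join(S.event_names[p] for p in c.parents)
            fh.write(
                f"{S.event_names[c.child]}\t{pa}\t{c.loglik:.10g}\t{c.bic:.10g}\n"
            )
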