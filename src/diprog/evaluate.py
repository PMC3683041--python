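"""Structure-recovery metrics and reference-order evaluation.

All edge-set metrics compare the underlying simple digraphs of the true (M)
and learned (L) networks:

* recovered-edge percentage: 100 |M ∩ L| / |M|,
* relative symmetric difference: F = (|M∖L| + |L∖M|) / (|M| + |L|),
* false discovery rate |L∖M| / |L| and false negative rate |M∖L| / |M|.

Against a reference partial order of events, a learned edge u -> v is *bad*
when v strictly precedes u in the order's transitive closure; edges between
incomparable events are not bad.  The bad-edge percentage counts
root-parent-attached hyperedges in its denominator (they can never be bad).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .hypercore import HyperDAG, SimpleDigraph, underlying_graph
from .scoring import DataMatrix, ProgressionNetwork

__all__ = [
    "PartialOrder",
    "recovered_edge_pct",
    "relative_symmetric_difference",
    "fdr_fnr",
    "bad_edge_pct",
    "calibrate_epsilon",
]


def _edge_set(g) -> frozenset:
    if isinstance(g, SimpleDigraph):
        return g.edges
    return frozenset((u, v) for u, v in g)


def recovered_edge_pct(truth, learned) -> float:
    """Percentage of true directed edges present in the learned graph."""
    M, L = _edge_set(truth), _edge_set(learned)
    if not M:
        raise ValueError("recovered-edge percentage undefined for empty truth")
    return 100.0 * len(M & L) / len(M)


def relative_symmetric_difference(M, L) -> float:
    """F = |M Δ L| / (|M| + |L|); 0 iff equal, 1 iff disjoint."""
    M, L = _edge_set(M), _edge_set(L)
    if not M and not L:
        raise ValueError("relative symmetric difference undefined: both empty")
    return (len(M - L) + len(L - M)) / (len(M) + len(L))


def fdr_fnr(M, L) -> tuple[float, float]:
    """False discovery and false negative rates of the learned edge set."""
    M, L = _edge_set(M), _edge_set(L)
    if not M:
        raise ValueError("FNR undefined for empty truth")
    fdr = len(L - M) / len(L) if L else 0.0
    fnr = len(M - L) / len(M)
    return fdr, fnr


@dataclass(frozen=True)
class PartialOrder:
    """A strict partial order over event names, closed under transitivity."""

    pairs: frozenset[tuple[str, str]]
    closure: frozenset[tuple[str, str]]
    events: frozenset[str]

    def __init__(
        self,
        pairs: Iterable[tuple[str, str]],
        events: Iterable[str] | None = None,
    ) -> None:
        """``events`` widens the universe beyond the names in ``pairs``;
        events mentioned in no pair are incomparable to everything."""
        pairs = frozenset((str(a), str(b)) for a, b in pairs)
        g = nx.DiGraph(pairs)
        if events is not None:
            g.add_nodes_from(str(e) for e in events)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("precedence pairs contain a cycle; not a partial order")
        closure = frozenset(nx.transitive_closure(g).edges())
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "closure", closure)
        object.__setattr__(self, "events", frozenset(g.nodes))

    def precedes(self, a: str, b: str) -> bool:
        """True iff a strictly precedes b."""
        return (a, b) in self.closure

    @classmethod
    def read_tsv(cls, path) -> "PartialOrder":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two tab-separated columns")
        return cls(zip(df.iloc[:, 0], df.iloc[:, 1]))


def bad_edge_pct(
    learned: ProgressionNetwork | HyperDAG, ref: PartialOrder
) -> float:
    """Percentage of learned edges contradicting a reference order.

    The denominator counts every simple (parent, child) edge plus one edge
    per root-parent-attached hyperedge (empty parent set); root edges never
    contradict the order, so they only dilute the percentage.
    """
    H = learned.hyperdag if isinstance(learned, ProgressionNetwork) else learned
    simple = underlying_graph(H)
    names = H.names
    unmapped = sorted(
        {names[x] for u, v in simple for x in (u, v)} - ref.events
    )
    if unmapped:
        raise ValueError(f"events absent from the reference order: {unmapped}")
    n_root = sum(1 for e in H.edges if not e.parents)
    total = len(simple) + n_root
    if total == 0:
        raise ValueError("network has no edges at all")
    bad = sum(1 for u, v in simple if ref.precedes(names[v], names[u]))
    return 100.0 * bad / total


def calibrate_epsilon(
    D: DataMatrix,
    ref: PartialOrder,
    k: int = 3,
    flavor: str = "monotone",
    epsilon_grid: Sequence[float] = (0.05, 0.1, 0.2, 0.4, 0.8),
    score: str = "bic",
    time_limit_s: float | None = None,
) -> tuple[float, pd.DataFrame]:
    """Pick the epsilon whose learned network has fewest bad edges.

    Learns one network per grid value and returns the epsilon minimizing
    the bad-edge percentage (ties broken toward the smallest epsilon),
    along with the full (epsilon, bad_pct) curve.
    """
    from .milp import learn

    grid = sorted(float(e) for e in epsilon_grid)
    if not grid:
        raise ValueError("epsilon grid is empty")
    if any(not 0 < e < 1 for e in grid):
        raise ValueError("grid epsilons must lie in (0, 1)")
    rows = []
    for eps in grid:
        res = learn(D, k=k, flavor=flavor, epsilon=eps, score=score,
                    time_limit_s=time_limit_s)
        pct = (
            bad_edge_pct(res.network, ref)
            if res.network is not None else np.nan
        )
        rows.append({"epsilon": eps, "bad_pct": pct, "status": res.status,
                     "objective": res.objective})
    curve = pd.DataFrame(rows)
    valid = curve.dropna(subset=["bad_pct"])
    if valid.empty:
        raise RuntimeError("no grid value produced a network")
    best = float(valid.loc[valid["bad_pct"].idxmin(), "epsilon"])
    return best, curve
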