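"""Directed hypergraph data structures and structural predicates.

A directed hypergraph is a set of hyperedges, each with a unique *child*
vertex and a set of *parent* vertices (possibly empty).  A hyperDAG is a
directed hypergraph admitting a linear order on its vertices in which every
parent precedes its child; equivalently, its underlying simple digraph
(one arc per (parent, child) pair) is acyclic.  A hypergraph is *k-bounded*
when every hyperedge contains at most k vertices, i.e. at most k-1 parents.

Vertices are integers 0..n-1; human-readable names live in a parallel list
on :class:`HyperDAG`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import networkx as nx

__all__ = [
    "HyperEdge",
    "HyperDAG",
    "SimpleDigraph",
    "CycleError",
    "is_acyclic",
    "is_k_bounded",
    "underlying_graph",
    "topological_order",
    "read_hyperedge_list",
    "write_hyperedge_list",
    "to_dot",
]


class CycleError(ValueError):
    """Raised when a directed cycle prevents a topological order."""


@dataclass(frozen=True)
class HyperEdge:
    """One hyperedge: a child vertex and a (possibly empty) parent set.

    Parents are stored as a sorted tuple so the edge hashes and compares
    deterministically.
    """

    child: int
    parents: tuple[int, ...]

    def __init__(self, child: int, parents: Iterable[int] = ()) -> None:
        parents = tuple(sorted(set(parents)))
        if child in parents:
            raise ValueError(f"child {child} cannot be its own parent")
        object.__setattr__(self, "child", int(child))
        object.__setattr__(self, "parents", parents)

    @property
    def size(self) -> int:
        """Number of vertices in the edge (child + parents)."""
        return 1 + len(self.parents)


@dataclass(frozen=True)
class SimpleDigraph:
    """A set of directed (parent, child) arcs with no self-loops."""

    edges: frozenset[tuple[int, int]]

    def __init__(self, edges: Iterable[tuple] = ()) -> None:
        edges = frozenset((u, v) for u, v in edges)
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
        object.__setattr__(self, "edges", edges)

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(self.edges)

    def __contains__(self, arc) -> bool:
        return arc in self.edges


@dataclass(frozen=True)
class HyperDAG:
    """A directed hypergraph over vertices 0..n-1 with optional names.

    The container itself accepts any edge set referencing known vertices;
    acyclicity is a predicate (:func:`is_acyclic`) so that candidate
    structures can be represented and rejected.
    """

    n: int
    edges: frozenset[HyperEdge]
    names: tuple[str, ...] = field(default=())

    def __init__(
        self,
        n: int,
        edges: Iterable[HyperEdge] = (),
        names: Sequence[str] | None = None,
    ) -> None:
        if n < 1:
            raise ValueError("need at least one vertex")
        edges = frozenset(edges)
        for e in edges:
            for v in (e.child, *e.parents):
                if not 0 <= v < n:
                    raise ValueError(f"edge references unknown vertex {v}")
        if names is None:
            names = tuple(f"v{i}" for i in range(n))
        else:
            names = tuple(names)
            if len(names) != n or len(set(names)) != n:
                raise ValueError("names must be unique, one per vertex")
        object.__setattr__(self, "n", int(n))
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "names", names)

    def parent_sets(self) -> dict[int, tuple[int, ...]]:
        """Map child -> parent tuple; requires at most one edge per child."""
        out: dict[int, tuple[int, ...]] = {}
        for e in self.edges:
            if e.child in out:
                raise ValueError(f"vertex {e.child} has multiple hyperedges")
            out[e.child] = e.parents
        return out


def _as_nx(H: HyperDAG) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(range(H.n))
    for e in H.edges:
        for u in e.parents:
            g.add_edge(u, e.child)
    return g


def is_acyclic(H: HyperDAG) -> bool:
    """True iff some vertex order places every parent before its child."""
    return nx.is_directed_acyclic_graph(_as_nx(H))


def is_k_bounded(H: HyperDAG, k: int) -> bool:
    """True iff every hyperedge has at most k vertices (child + parents)."""
    if k < 2:
        raise ValueError("k must be at least 2")
    return all(e.size <= k for e in H.edges)


def underlying_graph(H: HyperDAG) -> SimpleDigraph:
    """The simple digraph with one arc per (parent, child) pair.

    Hyperedges with empty parent sets (root-parent edges) contribute no
    arcs: root parents are an artificial vertex class, not events.
    """
    return SimpleDigraph(
        (u, e.child) for e in H.edges for u in e.parents
    )


def topological_order(H: HyperDAG) -> list[int]:
    """A parent-before-child vertex order, ties broken by vertex index.

    Raises :class:`CycleError` (naming an offending edge) on cyclic input.
    """
    g = _as_nx(H)
    try:
        return list(nx.lexicographical_topological_sort(g))
    except nx.NetworkXUnfeasible:
        cyc = nx.find_cycle(g)
        u, v = cyc[0][:2]
        raise CycleError(
            f"no topological order: arc {u}->{v} lies on a directed cycle"
        ) from None


# ---------------------------------------------------------------------------
# text I/O: one line per hyperedge, "child<TAB>parent1,parent2,..."

def write_hyperedge_list(H: HyperDAG, path) -> None:
    with open(path, "w") as fh:
        for e in sorted(H.edges, key=lambda e: (e.child, e.parents)):
            pa = ",".join(H.names[u] for u in e.parents)
            fh.write(f"{H.names[e.child]}\t{pa}\n")


def read_hyperedge_list(path, names: Sequence[str] | None = None) -> HyperDAG:
    """Read a hyperedge list; vertex universe is inferred unless given."""
    rows: list[tuple[str, list[str]]] = []
    seen: list[str] = []

    def note(nm: str) -> None:
        if nm not in seen:
            seen.append(nm)

    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {ln}: expected 2 tab-separated fields")
            child, pa_field = parts
            parents = [p for p in pa_field.split(",") if p]
            rows.append((child, parents))
            note(child)
            for p in parents:
                note(p)
    names = list(names) if names is not None else seen
    idx = {nm: i for i, nm in enumerate(names)}
    missing = [nm for nm, _ in rows if nm not in idx] + [
        p for _, ps in rows for p in ps if p not in idx
    ]
    if missing:
        raise ValueError(f"{path}: unknown vertex names: {sorted(set(missing))}")
    edges = [HyperEdge(idx[c], [idx[p] for p in ps]) for c, ps in rows]
    return HyperDAG(len(names), edges, names)


def to_dot(H: HyperDAG) -> str:
    """GraphViz DOT rendering of the underlying simple digraph."""
    lines = ["digraph G {"]
    for i in range(H.n):
        lines.append(f'  "{H.names[i]}";')
    for u, v in sorted(underlying_graph(H).edges):
        lines.append(f'  "{H.names[u]}" -> "{H.names[v]}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
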