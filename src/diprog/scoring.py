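"""Sufficient statistics, ML conditional probabilities and hyperedge weights.

The decomposable score of a Bayesian network over binary events is a sum of
per-hyperedge weights.  For a hyperedge e with child c and non-root parents
pa(e), the log-likelihood weight is

    w(e) = sum over parent assignments u and child values x of
           N(c = x, pa(e) = u) * log P_hat(x | u)

with P_hat the maximum-likelihood conditional (optionally epsilon-capped to
enforce a progression-network flavor), and the convention 0 * log 0 = 0.
A parentless (root-parent) edge uses the marginal estimate N(c=1)/m.  The
BIC weight subtracts (log m / 2) * 2^|pa(e)| (natural log).

Progression-network flavors constrain the CPD:

* ``monotone``:      P(child=1 | u) <= epsilon for every u except all-ones,
* ``semimonotone``:  P(child=1 | u) <= epsilon for u = all-zeros only,
* ``general``:       unconstrained.

Capping is the constrained-ML projection min(theta_hat, epsilon).  Edges
with an empty parent set are exempt (their parents are the artificial root
parents, which carry no event semantics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .hypercore import HyperDAG, HyperEdge

__all__ = [
    "FLAVORS",
    "DataMatrix",
    "CPDTable",
    "EdgeWeight",
    "ProgressionNetwork",
    "count",
    "ml_cpd",
    "constrain_cpd",
    "edge_loglik_weight",
    "edge_bic_weight",
    "network_score",
]

FLAVORS = ("monotone", "semimonotone", "general")


def _check_flavor(flavor: str) -> str:
    if flavor not in FLAVORS:
        raise ValueError(f"flavor must be one of {FLAVORS}, got {flavor!r}")
    return flavor


@dataclass(frozen=True)
class DataMatrix:
    """An m x n binary observation matrix with unique event names."""

    values: np.ndarray
    event_names: tuple[str, ...]

    def __init__(self, values, event_names: Sequence[str] | None = None) -> None:
        arr = np.asarray(values)
        if arr.ndim != 2 or arr.shape[0] < 1:
            raise ValueError("need a 2-D matrix with at least one row")
        bad = ~np.isin(arr, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary entry {arr[r, c]!r} at row {r}, column {c}"
            )
        arr = arr.astype(np.uint8)
        arr.setflags(write=False)
        if event_names is None:
            event_names = tuple(f"v{i}" for i in range(arr.shape[1]))
        else:
            event_names = tuple(str(s) for s in event_names)
        if len(event_names) != arr.shape[1]:
            raise ValueError("one event name per column required")
        if len(set(event_names)) != len(event_names):
            raise ValueError("event names must be unique")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "event_names", event_names)

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def column(self, name_or_index) -> int:
        if isinstance(name_or_index, str):
            try:
                return self.event_names.index(name_or_index)
            except ValueError:
                raise KeyError(f"unknown event {name_or_index!r}") from None
        i = int(name_or_index)
        if not 0 <= i < self.n:
            raise KeyError(f"unknown variable index {i}")
        return i

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.event_names))


@dataclass(frozen=True)
class CPDTable:
    """P(child = 1 | parent assignment) for every assignment of the parents.

    Row ``u`` of ``prob`` corresponds to the parent assignment whose bit i
    (value ``(u >> i) & 1``) assigns parents[i]; row ``2**p - 1`` is the
    all-ones assignment.  ``observed[u]`` is False when the assignment never
    occurs in the data (the probability is then a 0 placeholder and the
    row contributes nothing to any weight).
    """

    child: int
    parents: tuple[int, ...]
    prob: np.ndarray
    observed: np.ndarray

    def __init__(self, child, parents, prob, observed=None) -> None:
        parents = tuple(parents)
        prob = np.asarray(prob, dtype=float)
        if prob.shape != (1 << len(parents),):
            raise ValueError("CPD needs exactly 2^|parents| rows")
        if ((prob < 0) | (prob > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")
        if observed is None:
            observed = np.ones(prob.shape, dtype=bool)
        else:
            observed = np.asarray(observed, dtype=bool)
            if observed.shape != prob.shape:
                raise ValueError("observed mask must match prob shape")
        prob.setflags(write=False)
        observed.setflags(write=False)
        object.__setattr__(self, "child", int(child))
        object.__setattr__(self, "parents", parents)
        object.__setattr__(self, "prob", prob)
        object.__setattr__(self, "observed", observed)

    @property
    def n_rows(self) -> int:
        return self.prob.shape[0]

    def row_bits(self, u: int) -> str:
        """Assignment bitstring for row u, ordered like ``parents``."""
        return "".join(str((u >> i) & 1) for i in range(len(self.parents)))


@dataclass(frozen=True)
class EdgeWeight:
    """Per-hyperedge score contributions under both supported scores.

    ``cap_mass`` is the total escape probability retained on the
    epsilon-capped CPD rows; it is 0 for the general flavor and for
    root-parent edges, and serves as a structure tie-breaker (see
    :mod:`diprog.milp`).
    """

    edge: HyperEdge
    loglik: float
    bic: float
    n_params: int
    cap_mass: float = 0.0

    def by_score(self, score: str) -> float:
        if score == "loglik":
            return self.loglik
        if score == "bic":
            return self.bic
        raise ValueError(f"score must be 'loglik' or 'bic', got {score!r}")


@dataclass(frozen=True)
class ProgressionNetwork:
    """A hyperDAG with one CPD per vertex, a flavor and its epsilon bound."""

    hyperdag: HyperDAG
    cpds: tuple[CPDTable, ...]
    flavor: str
    epsilon: float

    def __init__(self, hyperdag: HyperDAG, cpds: Iterable[CPDTable],
                 flavor: str = "general", epsilon: float = 0.2) -> None:
        cpds = tuple(sorted(cpds, key=lambda c: c.child))
        ps = hyperdag.parent_sets()
        if [c.child for c in cpds] != list(range(hyperdag.n)):
            raise ValueError("need exactly one CPD per vertex")
        for c in cpds:
            if c.parents != ps.get(c.child, ()):
                raise ValueError(
                    f"CPD parents {c.parents} disagree with hyperedge "
                    f"parents {ps.get(c.child, ())} for vertex {c.child}"
                )
        object.__setattr__(self, "hyperdag", hyperdag)
        object.__setattr__(self, "cpds", cpds)
        object.__setattr__(self, "flavor", _check_flavor(flavor))
        object.__setattr__(self, "epsilon", float(epsilon))

    @property
    def n(self) -> int:
        return self.hyperdag.n

    def loglik(self, data: "DataMatrix") -> float:
        """Direct joint log-likelihood of the data, row by row.

        Evaluates log P(x) = sum_v log P(x_v | x_pa(v)) per observation and
        sums over observations, using the stored CPDs; rows that hit an
        unobserved (placeholder) CPD entry contribute 0 for that vertex,
        mirroring the 0*log 0 convention of the decomposed weights.
        """
        X = data.values
        total = 0.0
        for cpd in self.cpds:
            u = _parent_codes(X, cpd.parents)
            p1 = cpd.prob[u]
            x = X[:, cpd.child].astype(float)
            p = np.where(x == 1, p1, 1.0 - p1)
            with np.errstate(divide="ignore"):
                lp = np.log(p)  # -inf where p == 0: a truly impossible row
            lp = np.where(cpd.observed[u], lp, 0.0)
            total += float(lp.sum())
        return total


# ---------------------------------------------------------------------------
# sufficient statistics

def _parent_codes(X: np.ndarray, parents: Sequence[int]) -> np.ndarray:
    """Encode each row's parent assignment as an integer in [0, 2^p)."""
    code = np.zeros(X.shape[0], dtype=np.int64)
    for i, p in enumerate(parents):
        code |= X[:, p].astype(np.int64) << i
    return code


def count(D: DataMatrix, assignment: Mapping) -> int:
    """Number of rows matching a partial 0/1 assignment.

    Keys may be column indices or event names; an empty assignment counts
    every row.
    """
    mask = np.ones(D.m, dtype=bool)
    for key, val in assignment.items():
        j = D.column(key)
        if val not in (0, 1):
            raise ValueError(f"assignment value for {key!r} must be 0 or 1")
        mask &= D.values[:, j] == val
    return int(mask.sum())


def _counts(D: DataMatrix, child: int, parents: Sequence[int]):
    """Per parent-assignment totals and child=1 counts."""
    codes = _parent_codes(D.values, parents)
    n_cfg = 1 << len(parents)
    tot = np.bincount(codes, minlength=n_cfg).astype(np.int64)
    ones = np.bincount(
        codes, weights=D.values[:, child].astype(float), minlength=n_cfg
    ).astype(np.int64)
    return tot, ones


def ml_cpd(D: DataMatrix, child, parents=()) -> CPDTable:
    """Maximum-likelihood CPD of a child given its (non-root) parents.

    Unobserved parent assignments get a flagged 0 placeholder: their data
    contribution to any weight is zero regardless of the value.
    """
    child = D.column(child)
    parents = tuple(D.column(p) for p in parents)
    if child in parents:
        raise ValueError("child cannot be its own parent")
    tot, ones = _counts(D, child, parents)
    with np.errstate(invalid="ignore"):
        theta = np.where(tot > 0, ones / np.maximum(tot, 1), 0.0)
    return CPDTable(child, parents, theta, observed=tot > 0)


def constrain_cpd(cpd: CPDTable, flavor: str, epsilon: float) -> CPDTable:
    """Project a CPD onto the flavor's constraint set by epsilon-capping.

    Parentless CPDs (root-parent edges) are returned unchanged for every
    flavor: the root parents are artificial and the marginal estimate is
    used as-is.
    """
    _check_flavor(flavor)
    if not 0 < epsilon <= 1:
        raise ValueError("epsilon must lie in (0, 1]")
    if flavor == "general" or not cpd.parents:
        return cpd
    prob = np.array(cpd.prob)
    if flavor == "monotone":
        prob[:-1] = np.minimum(prob[:-1], epsilon)  # all rows but all-ones
    else:  # semimonotone: only the no-parent-on row is capped
        prob[0] = min(prob[0], epsilon)
    return CPDTable(cpd.child, cpd.parents, prob, cpd.observed)


def _weight_from_counts(tot, ones, prob) -> float:
    zeros = tot - ones
    with np.errstate(divide="ignore"):
        l1 = np.where(ones > 0, np.log(np.where(prob > 0, prob, 1.0)), 0.0)
        l0 = np.where(zeros > 0, np.log(np.where(prob < 1, 1.0 - prob, 1.0)), 0.0)
    # a positive count against a zero-probability row cannot arise from
    # ML estimates; guard with -inf so misuse is loud rather than silent
    l1 = np.where((ones > 0) & (prob == 0), -np.inf, l1)
    l0 = np.where((zeros > 0) & (prob == 1), -np.inf, l0)
    return float(np.sum(ones * l1) + np.sum(zeros * l0))


def edge_loglik_weight(
    D: DataMatrix, edge: HyperEdge, flavor: str = "general",
    epsilon: float = 0.2,
) -> float:
    """Log-likelihood contribution of one hyperedge (root parents ignored)."""
    cpd = constrain_cpd(ml_cpd(D, edge.child, edge.parents), flavor, epsilon)
    tot, ones = _counts(D, cpd.child, cpd.parents)
    return _weight_from_counts(tot, ones, cpd.prob)


def edge_bic_weight(
    D: DataMatrix, edge: HyperEdge, flavor: str = "general",
    epsilon: float = 0.2,
) -> float:
    """BIC weight: log-likelihood minus (log m / 2) * 2^|parents|."""
    w = edge_loglik_weight(D, edge, flavor, epsilon)
    return w - 0.5 * np.log(D.m) * (1 << len(edge.parents))


def edge_weight(
    D: DataMatrix, edge: HyperEdge, flavor: str = "general",
    epsilon: float = 0.2,
) -> EdgeWeight:
    """Both score variants (and the capped escape mass) for one hyperedge."""
    cpd = constrain_cpd(ml_cpd(D, edge.child, edge.parents), flavor, epsilon)
    tot, ones = _counts(D, cpd.child, cpd.parents)
    w = _weight_from_counts(tot, ones, cpd.prob)
    dim = 1 << len(edge.parents)
    if flavor == "monotone" and cpd.parents:
        cap_mass = float(cpd.prob[:-1][cpd.observed[:-1]].sum())
    elif flavor == "semimonotone" and cpd.parents:
        cap_mass = float(cpd.prob[0]) if cpd.observed[0] else 0.0
    else:
        cap_mass = 0.0
    return EdgeWeight(edge, w, w - 0.5 * np.log(D.m) * dim, dim, cap_mass)


def network_score(
    D: DataMatrix, network: HyperDAG | ProgressionNetwork,
    score: str = "bic", flavor: str | None = None, epsilon: float | None = None,
) -> float:
    """Decomposable score of a network: the sum of its per-edge weights.

    When given a :class:`ProgressionNetwork`, its flavor and epsilon are
    used unless overridden.  With ``score='loglik'`` and constrained-ML
    CPDs this equals the direct joint log-likelihood of the data.
    """
    if isinstance(network, ProgressionNetwork):
        H = network.hyperdag
        flavor = network.flavor if flavor is None else flavor
        epsilon = network.epsilon if epsilon is None else epsilon
    else:
        H = network
        flavor = "general" if flavor is None else flavor
        epsilon = 0.2 if epsilon is None else epsilon
    if score not in ("loglik", "bic"):
        raise ValueError(f"score must be 'loglik' or 'bic', got {score!r}")
    fn = edge_loglik_weight if score == "loglik" else edge_bic_weight
    parent_sets = H.parent_sets()
    total = 0.0
    for v in range(H.n):
        e = HyperEdge(v, parent_sets.get(v, ()))
        total += fn(D, e, flavor, epsilon)
    return total


def fit_cpds(
    D: DataMatrix, H: HyperDAG, flavor: str = "general", epsilon: float = 0.2,
) -> ProgressionNetwork:
    """Constrained-ML CPDs for every vertex of a one-edge-per-vertex DAG."""
    parent_sets = H.parent_sets()
    cpds = [
        constrain_cpd(ml_cpd(D, v, parent_sets.get(v, ())), flavor, epsilon)
        for v in range(H.n)
    ]
    return ProgressionNetwork(H, cpds, flavor, epsilon)
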