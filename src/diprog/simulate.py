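"""Random progression networks and forward-sampled cross-sectional data.

The generator mirrors the synthetic benchmark design: random k-bounded
hyperDAGs over n vertices with monotone, semi-monotone or general CPDs,
forward-sampled to m binary observations.  Signal rows (the fully enabled
parent configuration for monotone networks, any enabled parent for
semi-monotone ones, and root vertices) draw their success probability from
U(0.5, 0.95); suppressed rows draw from U(0, epsilon); general networks use
U(0.05, 0.95) throughout.  Defaults follow the benchmark grid:
k in {2, 3}, n in {10, 20, 30}, m in {500, 2000, 10000}, 50 replicates and
epsilon = 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .hypercore import HyperDAG, HyperEdge, topological_order, underlying_graph
from .scoring import (
    CPDTable,
    DataMatrix,
    ProgressionNetwork,
    _check_flavor,
)

__all__ = [
    "BenchmarkConfig",
    "random_hyperdag",
    "random_cpds",
    "random_network",
    "sample_data",
    "run_benchmark",
]


def random_hyperdag(n: int, k: int, seed=None) -> HyperDAG:
    """A random k-bounded hyperDAG with one hyperedge per vertex.

    A uniform vertex permutation fixes a topological order; each vertex
    draws a parent-set size uniformly from 0..min(k-1, #predecessors) and
    that many distinct parents uniformly among its predecessors.  Acyclic
    and k-bounded by construction.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    edges = []
    for i, v in enumerate(perm):
        max_size = min(k - 1, i)
        size = int(rng.integers(0, max_size + 1))
        parents = rng.choice(perm[:i], size=size, replace=False) if size else []
        edges.append(HyperEdge(int(v), [int(u) for u in parents]))
    return HyperDAG(n, edges)


def random_cpds(
    H: HyperDAG, flavor: str = "monotone", epsilon: float = 0.2, seed=None
) -> ProgressionNetwork:
    """Draw flavor-consistent CPDs for every vertex of a hyperDAG."""
    _check_flavor(flavor)
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    parent_sets = H.parent_sets()
    cpds = []
    for v in range(H.n):
        parents = parent_sets.get(v, ())
        n_rows = 1 << len(parents)
        if flavor == "general":
            prob = rng.uniform(0.05, 0.95, size=n_rows)
        elif not parents:
            # roots fire often enough for progressions to start
            prob = rng.uniform(0.5, 0.95, size=1)
        elif flavor == "monotone":
            prob = rng.uniform(0.0, epsilon, size=n_rows)
            prob[-1] = rng.uniform(0.5, 0.95)
        else:  # semimonotone
            prob = rng.uniform(0.5, 0.95, size=n_rows)
            prob[0] = rng.uniform(0.0, epsilon)
        cpds.append(CPDTable(v, parents, prob))
    return ProgressionNetwork(H, cpds, flavor, epsilon)


def random_network(
    n: int, k: int, flavor: str = "monotone", epsilon: float = 0.2, seed=None
) -> ProgressionNetwork:
    """Random structure plus random flavor-consistent CPDs."""
    rng = np.random.default_rng(seed)
    H = random_hyperdag(n, k, rng)
    return random_cpds(H, flavor, epsilon, rng)


def sample_data(net: ProgressionNetwork, m: int, seed=None) -> DataMatrix:
    """Forward-sample m observations in topological order."""
    if m < 1:
        raise ValueError("need m >= 1")
    rng = np.random.default_rng(seed)
    H = net.hyperdag
    cpd_of = {c.child: c for c in net.cpds}
    X = np.zeros((m, H.n), dtype=np.uint8)
    for v in topological_order(H):
        cpd = cpd_of[v]
        code = np.zeros(m, dtype=np.int64)
        for i, p in enumerate(cpd.parents):
            code |= X[:, p].astype(np.int64) << i
        theta = cpd.prob[code]
        X[:, v] = rng.random(m) < theta
    return DataMatrix(X, H.names)


@dataclass(frozen=True)
class BenchmarkConfig:
    """Grid for the synthetic structure-recovery benchmark."""

    k_values: tuple[int, ...] = (2, 3)
    n_values: tuple[int, ...] = (10, 20, 30)
    flavors: tuple[str, ...] = ("monotone", "semimonotone", "general")
    sample_sizes: tuple[int, ...] = (500, 2000, 10000)
    replicates: int = 50
    epsilon: float = 0.2
    score: str = "bic"
    seed: int = 0
    learn_flavors: tuple[str, ...] | None = None  # default: all three
    time_limit_s: float | None = None


def run_benchmark(config: BenchmarkConfig) -> pd.DataFrame:
    """Generate, sample, learn and evaluate over the whole grid.

    Returns a tidy frame with one row per (k, n, generating flavor, m,
    replicate, learning flavor) carrying the structure-recovery metrics of
    :mod:`diprog.evaluate`.  Within a replicate the datasets are nested:
    each larger sample extends the smaller one, so comparisons across m are
    paired rather than confounded by independent redraws.  Solver failures
    on a cell are recorded as a row with ``status`` set and metrics NaN
    rather than raised.
    """
    from .evaluate import fdr_fnr, recovered_edge_pct, relative_symmetric_difference
    from .milp import learn

    learn_flavors = config.learn_flavors or ("monotone", "semimonotone", "general")
    records = []
    base = np.random.SeedSequence(config.seed)
    for k in config.k_values:
        for n in config.n_values:
            for gen_flavor in config.flavors:
                for rep in range(config.replicates):
                    child = np.random.SeedSequence(
                        entropy=base.entropy,
                        spawn_key=(k, n, config.flavors.index(gen_flavor), rep),
                    )
                    rng = np.random.default_rng(child)
                    truth = random_network(
                        n, k, gen_flavor, config.epsilon, rng
                    )
                    true_edges = underlying_graph(truth.hyperdag)
                    D_full = sample_data(truth, max(config.sample_sizes), rng)
                    for m in config.sample_sizes:
                        D = DataMatrix(D_full.values[:m], D_full.event_names)
                        for lf in learn_flavors:
                            res = learn(
                                D, k=k, flavor=lf, epsilon=config.epsilon,
                                score=config.score,
                                time_limit_s=config.time_limit_s,
                            )
                            row = {
                                "k": k, "n": n, "gen_flavor": gen_flavor,
                                "m": m, "replicate": rep, "learn_flavor": lf,
                                "status": res.status,
                                "objective": res.objective,
                                "recovered_pct": np.nan, "F": np.nan,
                                "fdr": np.nan, "fnr": np.nan,
                            }
                            if res.network is not None:
                                learned = underlying_graph(res.network.hyperdag)
                                if len(true_edges):
                                    row["recovered_pct"] = recovered_edge_pct(
                                        true_edges, learned
                                    )
                                    f, fn = fdr_fnr(true_edges, learned)
                                    row["fdr"], row["fnr"] = f, fn
                                if len(true_edges) or len(learned):
                                    row["F"] = relative_symmetric_difference(
                                        true_edges, learned
                                    )
                            records.append(row)
    return pd.DataFrame.from_records(records)


def summarize_benchmark(results: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean and standard deviation of every metric."""
    keys = ["k", "n", "gen_flavor", "m", "learn_flavor"]
    metrics = ["recovered_pct", "F", "fdr", "fnr"]
    g = results.groupby(keys)[metrics]
    out = g.agg(["mean", "std"])
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    return out.reset_index()
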