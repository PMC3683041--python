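"""Readers and writers for the package's plain-text formats.

Formats: binary data matrix (TSV/CSV, header row of event names), hyperedge
lists (``child<TAB>parent1,parent2,...``), simple edge lists (two columns),
network JSON (structure, CPDs keyed by parent-assignment bitstrings, edge
weights) and run manifests.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .hypercore import HyperDAG, HyperEdge, SimpleDigraph
from .scoring import CPDTable, DataMatrix, ProgressionNetwork

__all__ = [
    "read_data_matrix",
    "write_data_matrix",
    "read_simple_edges",
    "write_simple_edges",
    "network_to_json",
    "network_from_json",
    "write_manifest",
]


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_data_matrix(path) -> DataMatrix:
    """Read a TSV/CSV binary matrix with a header of event names.

    Non-binary cells are rejected with the offending row and column named.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    arr = df.to_numpy()
    bad = ~np.isin(arr, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-binary value {arr[r, c]!r} in data row {r + 1}, "
            f"column {df.columns[c]!r}"
        )
    return DataMatrix(arr, list(df.columns))


def write_data_matrix(D: DataMatrix, path) -> None:
    D.to_frame().to_csv(path, sep=_sep_for(path), index=False)


def read_simple_edges(path) -> SimpleDigraph:
    """Two-column TSV of (parent, child) name pairs."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    return SimpleDigraph(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_simple_edges(g: SimpleDigraph, path, names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(g.edges):
            if names is not None:
                u, v = names[u], names[v]
            fh.write(f"{u}\t{v}\n")


def network_to_json(net: ProgressionNetwork, weights: dict | None = None) -> dict:
    """JSON-serializable form of a network.

    CPD rows are keyed by parent-assignment bitstrings ordered like the
    stored parent list, so '01' assigns 0 to the first listed parent and 1
    to the second.
    """
    H = net.hyperdag
    vertices = []
    for cpd in net.cpds:
        entry = {
            "name": H.names[cpd.child],
            "parents": [H.names[p] for p in cpd.parents],
            "cpd": {
                cpd.row_bits(u): float(cpd.prob[u])
                for u in range(cpd.n_rows)
                if cpd.observed[u]
            },
        }
        if weights and cpd.child in weights:
            entry["weight"] = weights[cpd.child]
        vertices.append(entry)
    return {
        "n": H.n,
        "flavor": net.flavor,
        "epsilon": net.epsilon,
        "vertices": vertices,
    }


def network_from_json(obj: dict) -> ProgressionNetwork:
    names = [v["name"] for v in obj["vertices"]]
    idx = {nm: i for i, nm in enumerate(names)}
    edges, cpds = [], []
    for i, v in enumerate(obj["vertices"]):
        parents = tuple(idx[p] for p in v["parents"])
        edges.append(HyperEdge(i, parents))
        n_rows = 1 << len(parents)
        prob = np.zeros(n_rows)
        observed = np.zeros(n_rows, dtype=bool)
        for bits, p in v["cpd"].items():
            u = sum(int(b) << j for j, b in enumerate(bits))
            prob[u] = p
            observed[u] = True
        cpds.append(CPDTable(i, parents, prob, observed))
    H = HyperDAG(len(names), edges, names)
    return ProgressionNetwork(H, cpds, obj["flavor"], obj["epsilon"])


def write_manifest(path, config: dict, **extra) -> None:
    """Record everything needed to reproduce a run."""
    payload = {"software": "diprog", "version": _version,
               "config": config, **extra}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
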